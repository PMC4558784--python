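"""Library-size and TMM normalization, log2-CPM signals, noise floor.

TMM (trimmed mean of M-values) computes one positive scaling factor per
sample against a reference sample. For sample k vs reference r, over
genes positive in both:

    M_g = log2((y_gk/N_k) / (y_gr/N_r))
    A_g = 1/2 * log2((y_gk/N_k) * (y_gr/N_r))
    w_g = (N_k - y_gk)/(N_k * y_gk) + (N_r - y_gr)/(N_r * y_gr)

the top and bottom ``trim_m`` fraction of genes by M and ``trim_a`` by A
are dropped, and the factor is ``2 ** (sum(w*M)/sum(w))`` over the
surviving genes, finally rescaled so factors have geometric mean 1.
Signals are log2 counts-per-million against the effective library size
``N_k * f_k`` with a small pseudo-value; raw zeros are re-expressed at a
global noise floor (a low percentile of the nonzero values) and flagged
so downstream plots can mark them with a cross.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io_formats import ExpressionTable

logger = logging.getLogger("trex")

__all__ = [
    "NormalizationResult",
    "TMMNormalizer",
    "compute_library_sizes",
    "tmm_factors",
    "log2cpm",
    "normalize",
]

MIN_TRIMMED_GENES = 10


@dataclass
class NormalizationResult:
    """Per-sample normalization state plus the signal matrix."""

    lib_size: pd.Series          # N_k, raw per-sample totals
    tmm_factor: pd.Series        # f_k, geometric mean 1
    effective_lib: pd.Series     # N_k * f_k
    signal: pd.DataFrame         # genes x samples log2 CPM, zeros at noise floor
    noise_floor: float           # raw-value units
    zero_flag: pd.DataFrame      # True exactly where the raw value was 0
    prior: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.lib_size.index)


def compute_library_sizes(values: pd.DataFrame | ExpressionTable) -> pd.Series:
    """Per-sample totals N_k; a sample summing to zero is a hard error."""
    df = values.values if isinstance(values, ExpressionTable) else values
    totals = df.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has library size 0")
    return totals.astype(float)


def _choose_reference(df: pd.DataFrame, lib: pd.Series) -> str:
    # standard TMM convention: sample whose upper quartile of scaled values
    # is closest to the mean upper quartile
    scaled = df.to_numpy() / lib.to_numpy()
    q75 = np.quantile(scaled, 0.75, axis=0)
    return str(df.columns[int(np.argmin(np.abs(q75 - q75.mean())))])


def _trim_keep(values: np.ndarray, trim: float) -> np.ndarray:
    """Boolean mask keeping ranks [n_cut, n - n_cut) by value (stable order)."""
    n = values.size
    n_cut = int(np.floor(trim * n))
    order = np.argsort(values, kind="stable")
    keep = np.zeros(n, dtype=bool)
    keep[order[n_cut : n - n_cut]] = True
    return keep


def _pair_factor(
    y_k: np.ndarray,
    y_r: np.ndarray,
    n_k: float,
    n_r: float,
    trim_m: float,
    trim_a: float,
) -> float:
    both = (y_k > 0) & (y_r > 0)
    y_k, y_r = y_k[both], y_r[both]
    if y_k.size == 0:
        logger.warning("no genes positive in both sample and reference; TMM factor 1")
        return 1.0
    m = np.log2((y_k / n_k) / (y_r / n_r))
    a = 0.5 * np.log2((y_k / n_k) * (y_r / n_r))
    w = (n_k - y_k) / (n_k * y_k) + (n_r - y_r) / (n_r * y_r)
    keep = _trim_keep(m, trim_m) & _trim_keep(a, trim_a)
    if keep.sum() < MIN_TRIMMED_GENES:
        logger.warning(
            "only %d genes survive TMM trimming (<%d); factor set to 1",
            int(keep.sum()),
            MIN_TRIMMED_GENES,
        )
        return 1.0
    w_kept, m_kept = w[keep], m[keep]
    if w_kept.sum() <= 0:
        return 1.0
    return float(2.0 ** (np.sum(w_kept * m_kept) / np.sum(w_kept)))


def tmm_factors(
    values: pd.DataFrame | ExpressionTable,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """TMM scaling factor per sample, rescaled to geometric mean 1."""
    df = values.values if isinstance(values, ExpressionTable) else values
    lib = compute_library_sizes(df)
    ref = ref_sample if ref_sample is not None else _choose_reference(df, lib)
    if ref not in df.columns:
        raise ValueError(f"reference sample {ref!r} not in data")
    y_r = df[ref].to_numpy(dtype=float)
    n_r = float(lib[ref])
    factors = {}
    for s in df.columns:
        if s == ref:
            factors[s] = 1.0
        else:
            factors[s] = _pair_factor(
                df[s].to_numpy(dtype=float), y_r, float(lib[s]), n_r, trim_m, trim_a
            )
    f = pd.Series(factors, dtype=float).reindex(df.columns)
    f /= np.exp(np.mean(np.log(f)))
    return f


def log2cpm(
    values: pd.DataFrame,
    effective_lib: pd.Series,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2((y + prior) / (efflib + 2*prior) * 1e6), strictly increasing in y."""
    lib = effective_lib.reindex(values.columns).to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValueError("effective library sizes must be positive")
    y = values.to_numpy(dtype=float)
    sig = np.log2((y + prior) / (lib + 2.0 * prior) * 1e6)
    return pd.DataFrame(sig, index=values.index, columns=values.columns)


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """TMM + log2-CPM normalizer with zero-to-noise-floor scaling.

    Parameters
    ----------
    trim_m, trim_a : float
        Trim fractions applied to the M- and A-value tails.
    prior : float
        Pseudo-value (raw units) added in the log2-CPM transform.
    noise_percentile : float
        Percentile of the nonzero raw values (matrix-wide) used as the
        noise floor to which raw zeros are scaled.
    ref_sample : str, optional
        Override the automatic reference-sample choice.

    Attributes (after ``fit``)
    --------------------------
    lib_size_, tmm_factor_, effective_lib_ : pd.Series per sample
    noise_floor_ : float
    """

    def __init__(
        self,
        trim_m: float = 0.30,
        trim_a: float = 0.05,
        prior: float = 0.5,
        noise_percentile: float = 1.0,
        ref_sample: str | None = None,
    ):
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.prior = prior
        self.noise_percentile = noise_percentile
        self.ref_sample = ref_sample

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, ExpressionTable):
            return X.values
        if isinstance(X, pd.DataFrame):
            return X
        raise TypeError("X must be an ExpressionTable or genes x samples DataFrame")

    def fit(self, X, y=None) -> "TMMNormalizer":
        df = self._as_frame(X)
        self.lib_size_ = compute_library_sizes(df)
        self.tmm_factor_ = tmm_factors(df, self.ref_sample, self.trim_m, self.trim_a)
        self.effective_lib_ = self.lib_size_ * self.tmm_factor_
        nonzero = df.to_numpy(dtype=float)
        nonzero = nonzero[nonzero > 0]
        if nonzero.size == 0:
            raise ValueError("expression table has no nonzero values")
        self.noise_floor_ = float(np.percentile(nonzero, self.noise_percentile))
        return self

    def transform(self, X) -> pd.DataFrame:
        """log2-CPM signals with raw zeros re-expressed at the noise floor."""
        df = self._as_frame(X)
        sig = log2cpm(df, self.effective_lib_, self.prior)
        zero = df.to_numpy(dtype=float) == 0
        if zero.any():
            floored = log2cpm(
                pd.DataFrame(
                    np.full(df.shape, self.noise_floor_),
                    index=df.index,
                    columns=df.columns,
                ),
                self.effective_lib_,
                self.prior,
            )
            sig = sig.where(~zero, floored)
        return sig

    def zero_flags(self, X) -> pd.DataFrame:
        df = self._as_frame(X)
        return pd.DataFrame(
            df.to_numpy(dtype=float) == 0, index=df.index, columns=df.columns
        )

    def result(self, X) -> NormalizationResult:
        """Bundle everything downstream modules need, for the fitted data."""
        df = self._as_frame(X)
        sig = self.transform(df)
        flags = self.zero_flags(df)
        gmean = float(np.exp(np.mean(np.log(self.tmm_factor_))))
        assert abs(gmean - 1.0) < 1e-9, "TMM factors must have geometric mean 1"
        return NormalizationResult(
            lib_size=self.lib_size_,
            tmm_factor=self.tmm_factor_,
            effective_lib=self.effective_lib_,
            signal=sig,
            noise_floor=self.noise_floor_,
            zero_flag=flags,
            prior=self.prior,
        )


def normalize(data: ExpressionTable, **params) -> NormalizationResult:
    """One-call convenience: fit a :class:`TMMNormalizer` and bundle results."""
    norm = TMMNormalizer(**params).fit(data)
    return norm.result(data)
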