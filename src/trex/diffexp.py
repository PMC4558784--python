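"""Negative-binomial differential expression for pairwise contrasts.

The model is a one-way NB generalized linear model with log link and
per-sample offsets ``log(effective library size)``: for gene g and
sample k in condition group j, ``y_gk ~ NB(mu_gk, phi_g)`` with
``log mu_gk = beta_gj + o_k`` and variance ``mu + phi * mu^2``.

Dispersion is estimated in two stages. A common dispersion maximizes
the sum over genes of the Cox-Reid adjusted NB profile log-likelihood
(the adjustment is -1/2 log det of the Fisher information of the group
means, which is diagonal for a one-way layout). Tagwise dispersions
then maximize each gene's adjusted profile likelihood plus a
``prior_df``-weighted shared likelihood anchored at the common value
(weighted-likelihood empirical Bayes); as ``prior_df`` grows, all
tagwise values shrink onto the common one.

Each contrast ``target-control`` is tested by a likelihood-ratio test:
the alternative fits separate means for the two groups, the null one
pooled mean (other condition levels cancel from the ratio), and the
statistic is referred to chi-squared with 1 df. P-values are adjusted
by Benjamini-Hochberg within each contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import CubicSpline
from scipy.special import gammaln
from scipy.stats import chi2
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("trex")

__all__ = [
    "DispersionEstimate",
    "ContrastResult",
    "NBDiffExp",
    "estimate_common_dispersion",
    "estimate_tagwise_dispersion",
    "test_contrast",
    "adjust_fdr",
]

_BETA_MIN = -100.0
_POISSON_PHI = 1e-8
COMMON_GRID = (1e-4, 4.0)
TAGWISE_BOUNDS = (1e-6, 10.0)


@dataclass
class DispersionEstimate:
    common: float
    tagwise: pd.Series
    prior_df: float


@dataclass
class ContrastResult:
    """Per-gene statistics for one ``target-control`` comparison.

    ``table`` is indexed by gene with columns ``logFC`` (log2
    target/control), ``avg_signal`` (mean log2 CPM over the two groups'
    samples), ``p_value``, ``fdr`` and ``zero_flag`` (any raw zero among
    the samples involved).
    """

    name: str
    target: str
    control: str
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# NB likelihood machinery (vectorized across genes)
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood, up to the additive constant
    -gammaln(y+1) (independent of mu and phi, so it cancels in every
    likelihood ratio and profile-likelihood argmax).

    ``phi`` broadcasts per gene; falls back to the Poisson limit below
    ``_POISSON_PHI``.
    """
    mu = np.maximum(mu, 1e-300)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],))[:, None]
    pois = phi[:, 0] < _POISSON_PHI

    out = np.empty(y.shape[0])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        yy, mm = y[~pois], mu[~pois]
        term = np.where(yy > 0, yy * np.log(mm / (r + mm)), 0.0)
        ll = gammaln(yy + r) - gammaln(r) + term - r * np.log1p(mm / r)
        out[~pois] = ll.sum(axis=1)
    if pois.any():
        yy, mm = y[pois], mu[pois]
        term = np.where(yy > 0, yy * np.log(mm), 0.0)
        out[pois] = (term - mm).sum(axis=1)
    return out


def _fit_group(
    y: np.ndarray, offsets: np.ndarray, phi: np.ndarray, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MLE of the per-gene intercept for one group.

    Newton iterations with step halving; the log-likelihood never
    decreases (asserted), which is equivalent to the deviance never
    increasing. Returns (beta, loglik, converged).
    """
    G = y.shape[0]
    phi_full = np.broadcast_to(np.asarray(phi, dtype=float), (G,)).copy()
    eo = np.exp(offsets)[None, :]
    tot = y.sum(axis=1)
    beta = np.where(tot > 0, np.log((tot + 0.1) / eo.sum()), _BETA_MIN)

    ll = _nb_loglik(y, np.exp(beta[:, None]) * eo, phi_full)
    converged = np.zeros(G, dtype=bool)
    last_step = np.zeros(G)
    idx = np.arange(G)
    for _ in range(30):
        # work only on the still-active subset
        y_a, phi_a, b_a, ll_a = y[idx], phi_full[idx], beta[idx], ll[idx]
        mu = np.exp(b_a[:, None]) * eo
        denom = 1.0 + phi_a[:, None] * mu
        score = ((y_a - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-12), -10.0, 10.0)
        last_step[idx] = step
        done = np.abs(step) <= tol
        converged[idx[done]] = True
        keep = ~done
        idx = idx[keep]
        if idx.size == 0:
            break
        y_a, phi_a, b_a, ll_a, cur = y_a[keep], phi_a[keep], b_a[keep], ll_a[keep], step[keep]
        # step halving: accept only non-decreasing log-likelihood
        b_new = np.maximum(b_a + cur, _BETA_MIN)
        ll_new = _nb_loglik(y_a, np.exp(b_new[:, None]) * eo, phi_a)
        for _half in range(40):
            worse = ll_new < ll_a - 1e-12
            if not worse.any():
                break
            cur = np.where(worse, cur / 2.0, cur)
            w = np.flatnonzero(worse)
            b_new_w = np.maximum(b_a[w] + cur[w], _BETA_MIN)
            ll_new[w] = _nb_loglik(y_a[w], np.exp(b_new_w[:, None]) * eo, phi_a[w])
            b_new[w] = b_new_w
        assert np.all(ll_new >= ll_a - 1e-9), "log-likelihood decreased"
        improve = ll_new >= ll_a
        beta[idx] = np.where(improve, b_new, b_a)
        ll[idx] = np.where(improve, ll_new, ll_a)
    converged |= np.abs(last_step) <= 1e-6  # loose check after the loop
    return beta, ll, converged


def _group_info(y: np.ndarray, beta: np.ndarray, offsets: np.ndarray, phi) -> np.ndarray:
    mu = np.exp(beta[:, None] + offsets[None, :])
    phi_col = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],))[:, None]
    return (mu / (1.0 + phi_col * mu)).sum(axis=1)


def _adjusted_profile_loglik(
    y: np.ndarray,
    groups: list[np.ndarray],
    offsets: np.ndarray,
    phi,
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at dispersion phi."""
    apl = np.zeros(y.shape[0])
    for idx in groups:
        beta, ll, _ = _fit_group(y[:, idx], offsets[idx], phi)
        info = _group_info(y[:, idx], beta, offsets[idx], phi)
        apl += ll - 0.5 * np.log(np.maximum(info, 1e-300))
    return apl


def _apl_at_phis(
    y: np.ndarray, groups: list[np.ndarray], offsets: np.ndarray, phis: np.ndarray
) -> np.ndarray:
    """APL evaluated at several dispersions at once; returns (genes, len(phis)).

    The gene block is tiled once per phi so the Newton fits run as a
    single large vectorized call instead of one call per grid point.
    """
    G, K = y.shape[0], len(phis)
    y_t = np.tile(y, (K, 1))
    phi_vec = np.repeat(np.asarray(phis, dtype=float), G)
    return _adjusted_profile_loglik(y_t, groups, offsets, phi_vec).reshape(K, G).T


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class NBDiffExp(BaseEstimator):
    """One-way NB GLM differential-expression tester.

    Fit with a genes x samples count DataFrame ``X`` and per-sample
    condition labels ``y``; then call :meth:`test_contrast` per
    comparison. Non-integer inputs (RPKM/FPKM/TPM) are rounded to the
    nearest integer for the NB likelihood, with a logged warning.

    Parameters
    ----------
    prior_df : float
        Shrinkage weight of the tagwise dispersions toward the common
        value (weighted-likelihood empirical Bayes).
    dispersion : float, optional
        Fixed dispersion; skips estimation (required for designs with
        no replicated condition).
    use_tagwise : bool
        Test with tagwise dispersions (default) or the common one.

    Attributes
    ----------
    common_dispersion_ : float
    tagwise_dispersion_ : pd.Series per gene
    noise_floor_ : float, raw-count units (used to keep logFC finite)
    """

    def __init__(
        self,
        prior_df: float = 10.0,
        dispersion: float | None = None,
        use_tagwise: bool = True,
        signal_prior: float = 0.5,
    ):
        self.prior_df = prior_df
        self.dispersion = dispersion
        self.use_tagwise = use_tagwise
        self.signal_prior = signal_prior

    # -- fitting ------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y, effective_lib: pd.Series | None = None):
        counts = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        arr = counts.to_numpy(dtype=float)
        if not np.allclose(arr, np.round(arr)):
            logger.warning(
                "non-integer expression values rounded to integers for the NB "
                "likelihood"
            )
        arr = np.round(arr)
        self.counts_ = pd.DataFrame(arr, index=counts.index, columns=counts.columns)
        cond = pd.Series(np.asarray(y, dtype=object), index=counts.columns)
        self.conditions_ = cond
        if effective_lib is None:
            effective_lib = self.counts_.sum(axis=0).astype(float)
        self.effective_lib_ = effective_lib.reindex(counts.columns).astype(float)
        if (self.effective_lib_ <= 0).any():
            raise ValueError("effective library sizes must be positive")
        self.offsets_ = np.log(self.effective_lib_.to_numpy())

        levels = list(dict.fromkeys(cond))
        self.groups_ = {
            lvl: np.flatnonzero((cond == lvl).to_numpy()) for lvl in levels
        }
        nonzero = arr[arr > 0]
        self.noise_floor_ = float(np.percentile(nonzero, 1.0)) if nonzero.size else 1.0

        if self.dispersion is not None:
            self.common_dispersion_ = float(self.dispersion)
            self.tagwise_dispersion_ = pd.Series(
                self.common_dispersion_, index=counts.index
            )
            return self

        if not any(len(ix) >= 2 for ix in self.groups_.values()):
            raise ValueError(
                "dispersion cannot be estimated without replicates; supply a "
                "fixed dispersion via the `dispersion` parameter"
            )
        self.common_dispersion_ = self._estimate_common()
        self.tagwise_dispersion_ = self._estimate_tagwise(self.common_dispersion_)
        return self

    def _estimation_rows(self) -> np.ndarray:
        return self.counts_.to_numpy().sum(axis=1) > 0

    def _estimate_common(self) -> float:
        y = self.counts_.to_numpy()[self._estimation_rows()]
        groups = list(self.groups_.values())
        off = self.offsets_

        def neg_total(logphi: float) -> float:
            return -float(
                _adjusted_profile_loglik(y, groups, off, np.exp(logphi)).sum()
            )

        lo, hi = COMMON_GRID
        grid = np.linspace(np.log(lo), np.log(hi), 25)
        vals = -_apl_at_phis(y, groups, off, np.exp(grid)).sum(axis=0)
        j = int(np.argmin(vals))
        if j == 0 or j == len(grid) - 1:
            res = optimize.minimize_scalar(
                neg_total,
                bounds=(grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]),
                method="bounded",
                options={"xatol": 1e-8},
            )
        else:
            res = optimize.minimize_scalar(
                neg_total,
                bracket=(grid[j - 1], grid[j], grid[j + 1]),
                method="golden",
                options={"xtol": 1e-8},
            )
        phi = float(np.exp(res.x))
        return float(np.clip(phi, lo, hi))

    def _estimate_tagwise(self, common: float) -> pd.Series:
        rows = self._estimation_rows()
        y = self.counts_.to_numpy()[rows]
        groups = list(self.groups_.values())
        off = self.offsets_
        lo, hi = TAGWISE_BOUNDS

        log_grid = np.linspace(np.log(lo), np.log(hi), 61)
        apl = _apl_at_phis(y, groups, off, np.exp(log_grid))
        shared = CubicSpline(log_grid, apl.mean(axis=0))

        obj_grid = apl + self.prior_df * shared(log_grid)[None, :]
        j = np.clip(np.argmax(obj_grid, axis=1), 1, len(log_grid) - 2)
        lo_v = log_grid[j - 1]
        hi_v = log_grid[j + 1]

        G = y.shape[0]

        def obj_pair(m1: np.ndarray, m2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            both = _adjusted_profile_loglik(
                np.tile(y, (2, 1)), groups, off, np.exp(np.concatenate([m1, m2]))
            )
            prior = self.prior_df * shared(np.concatenate([m1, m2]))
            both = both + prior
            return both[:G], both[G:]

        inv = 2.0 - 1.6180339887498949  # 1 - 1/golden ratio
        for _ in range(40):
            m1 = lo_v + inv * (hi_v - lo_v)
            m2 = hi_v - inv * (hi_v - lo_v)
            f1, f2 = obj_pair(m1, m2)
            take_right = f1 < f2
            lo_v = np.where(take_right, m1, lo_v)
            hi_v = np.where(take_right, hi_v, m2)
        phi = np.exp((lo_v + hi_v) / 2.0)
        out = pd.Series(common, index=self.counts_.index, dtype=float)
        out.iloc[np.flatnonzero(rows)] = np.clip(phi, lo, hi)
        return out

    # -- testing ------------------------------------------------------------

    def _phi_vector(self) -> np.ndarray:
        if self.use_tagwise:
            return self.tagwise_dispersion_.to_numpy()
        return np.full(self.counts_.shape[0], self.common_dispersion_)

    def test_contrast(
        self,
        target: str,
        control: str,
        name: str | None = None,
        zero_flag: pd.DataFrame | None = None,
    ) -> ContrastResult:
        """LRT of target vs control; returns per-gene logFC, p, FDR."""
        for lvl in (target, control):
            if lvl not in self.groups_:
                raise ValueError(
                    f"contrast level {lvl!r} absent from the design "
                    f"(levels: {list(self.groups_)})"
                )
        it, ic = self.groups_[target], self.groups_[control]
        pooled = np.concatenate([it, ic])
        y = self.counts_.to_numpy()
        phi = self._phi_vector()

        beta_t, ll_t, conv_t = _fit_group(y[:, it], self.offsets_[it], phi)
        beta_c, ll_c, conv_c = _fit_group(y[:, ic], self.offsets_[ic], phi)
        _, ll_0, conv_0 = _fit_group(y[:, pooled], self.offsets_[pooled], phi)

        lr = np.maximum(2.0 * (ll_t + ll_c - ll_0), 0.0)
        p = chi2.sf(lr, df=1)
        bad = ~(conv_t & conv_c & conv_0)
        if bad.any():
            logger.warning(
                "%d gene(s) did not converge in contrast %s-%s; p set to 1",
                int(bad.sum()),
                target,
                control,
            )
            p = np.where(bad, 1.0, p)

        # zero values are scaled to noise level so logFC stays finite
        floor_prop = self.noise_floor_ / float(self.effective_lib_.mean())
        cpm_t = np.maximum(np.exp(beta_t), floor_prop) * 1e6
        cpm_c = np.maximum(np.exp(beta_c), floor_prop) * 1e6
        logfc = np.log2(cpm_t / cpm_c)

        lib = self.effective_lib_.to_numpy()[pooled]
        pr = self.signal_prior
        sig = np.log2((y[:, pooled] + pr) / (lib + 2 * pr)[None, :] * 1e6)
        avg_signal = sig.mean(axis=1)

        if zero_flag is not None:
            zf = zero_flag.iloc[:, pooled].to_numpy().any(axis=1)
        else:
            zf = (y[:, pooled] == 0).any(axis=1)

        table = pd.DataFrame(
            {
                "logFC": logfc,
                "avg_signal": avg_signal,
                "p_value": p,
                "fdr": adjust_fdr(p),
                "zero_flag": zf,
            },
            index=self.counts_.index,
        )
        return ContrastResult(name or f"{target}-{control}", target, control, table)

    def test_all(self, contrasts, zero_flag: pd.DataFrame | None = None):
        """Run :meth:`test_contrast` for every contrast in a ContrastSet."""
        return {
            c.name: self.test_contrast(c.target, c.control, c.name, zero_flag)
            for c in contrasts
        }


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_common_dispersion(
    counts: pd.DataFrame, conditions, effective_lib: pd.Series | None = None
) -> float:
    est = NBDiffExp().fit(counts, conditions, effective_lib)
    return est.common_dispersion_


def estimate_tagwise_dispersion(
    counts: pd.DataFrame,
    conditions,
    common: float | None = None,
    prior_df: float = 10.0,
    effective_lib: pd.Series | None = None,
) -> pd.Series:
    est = NBDiffExp(prior_df=prior_df)
    est.fit(counts, conditions, effective_lib)
    if common is not None:
        # re-anchor the shrinkage at the supplied common value
        est.common_dispersion_ = float(common)
        est.tagwise_dispersion_ = est._estimate_tagwise(float(common))
    return est.tagwise_dispersion_


def test_contrast(
    counts: pd.DataFrame,
    conditions,
    target: str,
    control: str,
    dispersion: float | pd.Series | None = None,
    effective_lib: pd.Series | None = None,
    prior_df: float = 10.0,
) -> ContrastResult:
    if isinstance(dispersion, (int, float)):
        est = NBDiffExp(prior_df=prior_df, dispersion=float(dispersion))
        est.fit(counts, conditions, effective_lib)
    else:
        est = NBDiffExp(prior_df=prior_df)
        est.fit(counts, conditions, effective_lib)
        if dispersion is not None:
            est.tagwise_dispersion_ = pd.Series(dispersion, index=counts.index)
    return est.test_contrast(target, control)
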