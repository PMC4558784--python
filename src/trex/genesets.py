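"""Gene-set filters over the per-contrast results and up/down counts.

Three derived sets, each defined over *all* contrasts jointly:

* TopHits     — absolute fold change >= 2 and p <= 0.05 in at least one contrast;
* HighFold    — absolute fold change >= 5 and p <= 0.01 in at least one contrast;
* no_background — every gene except those with absolute fold change <= 1.4
  and p >= 0.25 in *every* contrast (i.e. the flat background is removed).

"Fold change" is absolute (max of the ratio and its reciprocal), so
down-regulation qualifies symmetrically; all comparisons are inclusive.
By construction HighFold is a subset of TopHits is a subset of
no_background, and that containment is asserted on every run. Filters
read the raw p-value by default, switchable to the BH FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .diffexp import ContrastResult

__all__ = [
    "GeneSetBundle",
    "select_tophits",
    "select_highfold",
    "drop_background",
    "count_up_down",
    "build_genesets",
]

TOPHITS_FC, TOPHITS_P = 2.0, 0.05
HIGHFOLD_FC, HIGHFOLD_P = 5.0, 0.01
BACKGROUND_FC, BACKGROUND_P = 1.4, 0.25


@dataclass
class GeneSetBundle:
    tophits: set[str]
    highfold: set[str]
    no_background: set[str]
    updown: pd.DataFrame  # per contrast: n_up, n_down, fc_cutoff, p_cutoff

    def __post_init__(self) -> None:
        assert self.highfold <= self.tophits <= self.no_background, (
            "gene-set containment HighFold <= TopHits <= no_background violated"
        )


_EPS = 1e-12  # boundary comparisons are inclusive; compare on the log2 scale


def _pcol(use_fdr: bool) -> str:
    return "fdr" if use_fdr else "p_value"


def fc_pass(table: pd.DataFrame, fc: float) -> np.ndarray:
    """Absolute fold change >= fc, evaluated as |logFC| >= log2(fc)."""
    return np.abs(table["logFC"].to_numpy()) >= np.log2(fc) - _EPS


def fc_flat(table: pd.DataFrame, fc: float) -> np.ndarray:
    """Absolute fold change <= fc."""
    return np.abs(table["logFC"].to_numpy()) <= np.log2(fc) + _EPS


def select_tophits(
    results: Mapping[str, ContrastResult],
    fc: float = TOPHITS_FC,
    p: float = TOPHITS_P,
    use_fdr: bool = False,
) -> set[str]:
    """Genes passing |FC| >= fc and p <= p in at least one contrast."""
    hits: set[str] = set()
    for res in results.values():
        t = res.table
        mask = fc_pass(t, fc) & (t[_pcol(use_fdr)].to_numpy() <= p)
        hits.update(t.index[mask])
    return hits


def select_highfold(
    results: Mapping[str, ContrastResult],
    fc: float = HIGHFOLD_FC,
    p: float = HIGHFOLD_P,
    use_fdr: bool = False,
) -> set[str]:
    return select_tophits(results, fc=fc, p=p, use_fdr=use_fdr)


def drop_background(
    results: Mapping[str, ContrastResult],
    fc: float = BACKGROUND_FC,
    p: float = BACKGROUND_P,
    use_fdr: bool = False,
) -> set[str]:
    """All genes except those flat (|FC| <= fc and p >= p) in every contrast."""
    flat: pd.Series | None = None
    genes: pd.Index | None = None
    for res in results.values():
        t = res.table
        this = pd.Series(
            fc_flat(t, fc) & (t[_pcol(use_fdr)].to_numpy() >= p), index=t.index
        )
        flat = this if flat is None else (flat & this)
        genes = t.index if genes is None else genes
    if flat is None or genes is None:
        return set()
    return set(genes[~flat.reindex(genes).fillna(False)])


def count_up_down(
    result: ContrastResult,
    fc: float = TOPHITS_FC,
    p: float = TOPHITS_P,
    use_fdr: bool = False,
) -> tuple[int, int]:
    """(n_up, n_down) at the cutoffs; logFC exactly 0 counts to neither."""
    t = result.table
    passing = fc_pass(t, fc) & (t[_pcol(use_fdr)].to_numpy() <= p)
    lfc = t["logFC"].to_numpy()
    return int(np.sum(passing & (lfc > 0))), int(np.sum(passing & (lfc < 0)))


def build_genesets(
    results: Mapping[str, ContrastResult],
    tophits_fc: float = TOPHITS_FC,
    tophits_p: float = TOPHITS_P,
    highfold_fc: float = HIGHFOLD_FC,
    highfold_p: float = HIGHFOLD_P,
    background_fc: float = BACKGROUND_FC,
    background_p: float = BACKGROUND_P,
    use_fdr: bool = False,
) -> GeneSetBundle:
    """Apply the three filters and tabulate per-contrast up/down counts."""
    tophits = select_tophits(results, tophits_fc, tophits_p, use_fdr)
    highfold = select_highfold(results, highfold_fc, highfold_p, use_fdr)
    no_bg = drop_background(results, background_fc, background_p, use_fdr)
    rows = []
    for name, res in results.items():
        n_up, n_down = count_up_down(res, tophits_fc, tophits_p, use_fdr)
        rows.append(
            {
                "contrast": name,
                "total_genes": len(res.table),
                "n_up": n_up,
                "n_down": n_down,
                "fc_cutoff": tophits_fc,
                "p_cutoff": tophits_p,
            }
        )
    updown = pd.DataFrame(
        rows, columns=["contrast", "total_genes", "n_up", "n_down", "fc_cutoff", "p_cutoff"]
    )
    return GeneSetBundle(tophits, highfold, no_bg, updown)
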