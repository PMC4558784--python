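"""Synthetic RNA-seq count generator with known ground truth.

Emulates a small factorial prokaryotic RNA-seq experiment: a wild type
plus a series of mutants, duplicate libraries per condition, negative-
binomially distributed counts over a log-normal baseline, a minority of
genes spiked at known log2 fold changes, and regulon-style class labels
covering subsets of the spiked genes. Every stage of the pipeline is
testable against the returned :class:`GroundTruth` without any external
download.

Counts are drawn as ``y_gk ~ NB(mean = p_g * 2^trueFC_g(cond_k) * L_k,
dispersion = phi)`` where ``p_g`` are baseline relative abundances and
``L_k`` the drawn library size (per-sample proportions are renormalized
so each library's expected total is L_k). ``phi = 0`` falls back to
Poisson. Everything is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ClassMap,
    Contrast,
    ContrastSet,
    ExpressionTable,
    FactorDesign,
    write_table,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "graded_regulon",
    "write_input_files",
]

DEFAULT_CONDITIONS = ("WT", "A_F71Y", "B_R61K", "C_R61H", "Null")

_CLASS_COLORS = ("green", "red", "blue", "orange", "purple")
_CLASS_NAMES = ("CodY", "CcpA", "ArgR", "MalR", "Complex")


@dataclass
class SyntheticSpec:
    """Parameters of the generator; defaults are the desk-scale study design.

    The reference condition is the first listed; contrasts run
    target-reference for every non-reference condition. ``de_fraction``
    of genes are differentially expressed per non-reference condition at
    signed log2 fold changes drawn from ``de_log2fc``. When ``gradient``
    is set (see :func:`graded_regulon`), a single shared regulon of
    ``n_regulon`` genes is up-regulated with |log2FC| increasing along
    the condition order instead.
    """

    n_genes: int = 2000
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_reps: int = 2
    lib_size_mean: float = 2_000_000.0
    lib_size_cv: float = 0.15
    baseline_log_mean: float = 4.0   # ln-scale location of the log-normal baseline
    baseline_log_sd: float = 1.5
    dispersion: float = 0.1
    de_fraction: float = 0.10
    de_log2fc: tuple[float, ...] = (2.0, -2.0)
    class_fraction: float = 0.5      # fraction of each condition's DE genes put in a class
    gradient: tuple[float, ...] | None = None
    n_regulon: int = 200
    seed: int = 20150903

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must be in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if len(self.conditions) < 2:
            raise ValueError("need a reference plus at least one other condition")
        if self.gradient is not None and len(self.gradient) != len(self.conditions) - 1:
            raise ValueError(
                "gradient must give one |log2FC| per non-reference condition"
            )


@dataclass
class GroundTruth:
    """True per-condition log2 fold changes vs the reference, plus classes.

    ``log2fc`` is a genes x non-reference-conditions DataFrame; non-DE
    genes are exactly 0 everywhere.
    """

    log2fc: pd.DataFrame
    class_members: dict[str, list[str]] = field(default_factory=dict)

    def de_genes(self, condition: str) -> list[str]:
        col = self.log2fc[condition]
        return list(col.index[col != 0.0])


def graded_regulon(
    spec: SyntheticSpec,
    gradient: tuple[float, ...] = (1.2, 1.6, 2.2, 3.0),
    n_regulon: int = 200,
) -> SyntheticSpec:
    """Spec variant with a shared regulon of monotonically growing effect."""
    if len(spec.conditions) - 1 < 3:
        raise ValueError("graded_regulon needs at least 3 non-reference conditions")
    from dataclasses import replace

    return replace(
        spec,
        de_fraction=0.0,
        gradient=tuple(float(g) for g in gradient),
        n_regulon=n_regulon,
    )


def _true_log2fc(
    spec: SyntheticSpec, genes: list[str], others: list[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    fc = pd.DataFrame(0.0, index=genes, columns=others)
    pools: dict[str, list[str]] = {}
    if spec.gradient is not None:
        idx = np.sort(rng.choice(spec.n_genes, size=spec.n_regulon, replace=False))
        for j, g in enumerate(spec.gradient):
            fc.iloc[idx, j] = g
        pools["Regulon"] = [genes[i] for i in idx]
        return fc, pools
    n_de = int(round(spec.de_fraction * spec.n_genes))
    for j, cond in enumerate(others):
        if n_de == 0:
            continue
        idx = rng.choice(spec.n_genes, size=n_de, replace=False)
        fcs = rng.choice(np.asarray(spec.de_log2fc, dtype=float), size=n_de)
        n_cls = int(round(spec.class_fraction * n_de))
        # class members emulate a regulon: co-regulated, shared direction
        fcs[:n_cls] = np.abs(fcs[:n_cls])
        fc.iloc[idx, j] = fcs
        name = _CLASS_NAMES[j % len(_CLASS_NAMES)]
        pools[name] = [genes[i] for i in np.sort(idx[:n_cls])]
    return fc, pools


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionTable, FactorDesign, ContrastSet, ClassMap, GroundTruth]:
    """Draw one synthetic dataset: counts, design files and ground truth."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"GENE{i:05d}" for i in range(spec.n_genes)]
    ref, *others = spec.conditions

    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    p = baseline / baseline.sum()
    fc, pools = _true_log2fc(spec, genes, others, rng)

    samples, cond_of = [], []
    for cond in spec.conditions:
        for r in range(1, spec.n_reps + 1):
            samples.append(f"{cond}_{r}")
            cond_of.append(cond)

    sigma = np.sqrt(np.log1p(spec.lib_size_cv**2))
    lib = rng.lognormal(np.log(spec.lib_size_mean) - sigma**2 / 2, sigma, len(samples))

    counts = np.empty((spec.n_genes, len(samples)), dtype=np.int64)
    for k, cond in enumerate(cond_of):
        mult = np.ones(spec.n_genes) if cond == ref else 2.0 ** fc[cond].to_numpy()
        prop = p * mult
        mu = prop / prop.sum() * lib[k]
        if spec.dispersion == 0:
            counts[:, k] = rng.poisson(mu)
        else:
            r_nb = 1.0 / spec.dispersion
            counts[:, k] = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))

    table = ExpressionTable(pd.DataFrame(counts, index=genes, columns=samples))
    factors = FactorDesign(
        pd.DataFrame({"Condition": cond_of}, index=pd.Index(samples, name="Experiment")),
        "Condition",
    )
    contrasts = ContrastSet([Contrast(f"{c}-{ref}", c, ref) for c in others])

    if spec.gradient is not None:
        entries = [(g, "green", "Regulon") for g in pools.get("Regulon", [])]
    else:
        entries = []
        for j, cond in enumerate(others):
            name = _CLASS_NAMES[j % len(_CLASS_NAMES)]
            color = _CLASS_COLORS[j % len(_CLASS_COLORS)]
            entries.extend((g, color, name) for g in pools.get(name, []))
    classes = ClassMap(entries)

    return table, factors, contrasts, classes, GroundTruth(fc, pools)


def write_input_files(
    out_dir: str | Path,
    spec: SyntheticSpec | None = None,
) -> dict[str, Path]:
    """Write the four input files plus ``truth.tsv`` for a synthetic dataset."""
    spec = spec or SyntheticSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, factors, contrasts, classes, truth = generate(spec)
    paths = {
        "data": out / "expression.tsv",
        "factors": out / "factors.tsv",
        "contrasts": out / "contrasts.tsv",
        "classes": out / "classes.tsv",
        "truth": out / "truth.tsv",
    }
    write_table(table.values, paths["data"], index_label="gene")
    write_table(factors.table, paths["factors"], index_label="Experiment")
    with open(paths["contrasts"], "w", encoding="utf-8", newline="\n") as fh:
        for c in contrasts:
            fh.write(c.name + "\n")
    with open(paths["classes"], "w", encoding="utf-8", newline="\n") as fh:
        for gene, color, cls in classes.entries:
            fh.write(f"{gene}\t{color}\t{cls}\n")
    write_table(truth.log2fc, paths["truth"], index_label="gene")
    return paths
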