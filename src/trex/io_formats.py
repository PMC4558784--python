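"""Readers, validators and writers for the four pipeline input files.

The pipeline consumes a tab-delimited expression table (genes x samples,
in counts, RPKM, FPKM, TPM or CPM), a Factors file mapping samples to
experimental condition levels, a Contrasts file of ``Target-Control``
comparisons, and an optional Classes file assigning genes of interest to
named, colored groups (e.g. regulons). All outputs are tab-delimited.

Conventions: UTF-8, decimal point ".", lines starting with "#" ignored.
Condition levels may not contain "-" so that contrast expressions such as
``A_F71Y-WT`` split unambiguously.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from matplotlib.colors import is_color_like

logger = logging.getLogger("trex")

_HEX_RE = re.compile(r"^#[0-9a-fA-F]{6}$")

__all__ = [
    "ExpressionTable",
    "FactorDesign",
    "Contrast",
    "ContrastSet",
    "ClassMap",
    "read_expression_table",
    "read_factors",
    "read_contrasts",
    "read_classes",
    "parse_contrast",
    "write_table",
]


class InputFormatError(ValueError):
    """A hard validation error in one of the four input files."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTable:
    """Genes x samples matrix of non-negative expression values.

    ``values`` is a DataFrame indexed by gene id with one column per
    sample. Identifiers must be unique, values non-negative and complete
    (missing cells are an error, never imputed).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise InputFormatError(
                f"expression table needs at least 2 genes and 2 samples, "
                f"got {df.shape[0]} x {df.shape[1]}"
            )
        _check_unique(df.index, "gene id")
        _check_unique(df.columns, "sample id")
        arr = df.to_numpy()
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise InputFormatError(
                f"missing value at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise InputFormatError(
                f"negative value {arr[g, s]} at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class FactorDesign:
    """Sample-to-condition mapping plus any extra annotation factors.

    ``table`` is indexed by sample id with one column per factor;
    ``condition_factor`` names the column whose levels the contrasts
    reference. Extra factor columns are carried as annotations only: the
    statistical model is one-way on the contrast factor.
    """

    table: pd.DataFrame
    condition_factor: str

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample id")
        if self.condition_factor not in self.table.columns:
            raise InputFormatError(
                f"condition factor {self.condition_factor!r} not a column of the "
                f"Factors file (columns: {list(self.table.columns)})"
            )
        bad = [lvl for lvl in self.levels if "-" in lvl]
        if bad:
            raise InputFormatError(
                f"condition levels may not contain '-' (reserved as the contrast "
                f"separator): {bad}"
            )
        counts = self.condition.value_counts()
        for lvl, n in counts.items():
            if n == 1:
                logger.warning("condition level %r has no replicates (1 sample)", lvl)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def condition(self) -> pd.Series:
        """Series mapping sample id -> condition level."""
        return self.table[self.condition_factor]

    @property
    def levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lvl in self.condition:
            seen.setdefault(lvl, None)
        return list(seen)

    def samples_of(self, level: str) -> list[str]:
        return list(self.condition.index[self.condition == level])


@dataclass(frozen=True)
class Contrast:
    name: str
    target: str
    control: str


@dataclass
class ContrastSet:
    contrasts: list[Contrast]

    def __post_init__(self) -> None:
        names = [c.name for c in self.contrasts]
        _check_unique(pd.Index(names), "contrast name")
        for c in self.contrasts:
            if c.target == c.control:
                raise InputFormatError(
                    f"contrast {c.name!r}: target equals control ({c.target!r})"
                )

    def __iter__(self):
        return iter(self.contrasts)

    def __len__(self) -> int:
        return len(self.contrasts)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.contrasts]


@dataclass
class ClassMap:
    """User-defined gene groups (e.g. regulons) with display colors.

    A gene may belong to several classes; for coloring, the first class
    listed in the file wins. ``entries`` preserves file order.
    """

    entries: list[tuple[str, str, str]] = field(default_factory=list)  # gene, color, class

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        deduped = []
        for gene, color, cls in self.entries:
            if not cls:
                raise InputFormatError(f"empty class name for gene {gene!r}")
            if not _valid_color(color):
                raise InputFormatError(
                    f"unrecognized color {color!r} for gene {gene!r} "
                    "(use a named color or #RRGGBB)"
                )
            key = (gene, cls)
            if key in seen:
                logger.warning("duplicate class entry (%s, %s) collapsed", gene, cls)
                continue
            seen.add(key)
            deduped.append((gene, color, cls))
        self.entries = deduped

    @property
    def class_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, _, cls in self.entries:
            seen.setdefault(cls, None)
        return list(seen)

    def members(self, class_name: str) -> list[str]:
        return [g for g, _, c in self.entries if c == class_name]

    def color_of_class(self, class_name: str) -> str:
        for _, color, c in self.entries:
            if c == class_name:
                return color
        raise KeyError(class_name)

    def color_of_gene(self, gene: str) -> str | None:
        """Display color: first class listed in the file wins; None if unclassed."""
        for g, color, _ in self.entries:
            if g == gene:
                return color
        return None

    def classes_of_gene(self, gene: str) -> list[str]:
        return [c for g, _, c in self.entries if g == gene]

    def restrict_to(self, genes: Iterable[str]) -> "ClassMap":
        """Drop entries for genes absent from the data, with a warning each."""
        genes = set(genes)
        kept = []
        for gene, color, cls in self.entries:
            if gene in genes:
                kept.append((gene, color, cls))
            else:
                logger.warning(
                    "class %r member %r absent from expression table; excluded "
                    "from computation",
                    cls,
                    gene,
                )
        return ClassMap(kept)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise InputFormatError(f"duplicate {what}: {dup!r}")


def _valid_color(color: str) -> bool:
    return bool(_HEX_RE.match(color)) or is_color_like(color)


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t", comment="#", encoding="utf-8", **kwargs)


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a tab-delimited genes x samples expression table.

    First row is the sample header, first column the gene ids. Any
    non-numeric cell, negative value or duplicate identifier is a hard
    error naming the offender.
    """
    # check the raw header before pandas mangles duplicate column names
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                _check_unique(pd.Index(line.rstrip("\n").split("\t")[1:]), "sample id")
                break
    raw = _read_tsv(path, dtype=str, keep_default_na=False, na_values=[])
    if raw.shape[1] < 3:
        raise InputFormatError(
            f"{path}: expected gene-id column plus >=2 sample columns"
        )
    raw = raw.set_index(raw.columns[0])
    raw.index = raw.index.astype(str)
    try:
        values = raw.astype(float)
    except ValueError:
        # locate the first offending cell for the error message
        for s in raw.columns:
            col = pd.to_numeric(raw[s], errors="coerce")
            bad = col.isna() & raw[s].notna()
            if bad.any():
                g = bad.idxmax()
                raise InputFormatError(
                    f"non-numeric cell {raw.loc[g, s]!r} at gene {g!r}, sample {s!r}"
                ) from None
        raise
    table = ExpressionTable(values)
    logger.info(
        "read expression table %s: %d genes x %d samples",
        path,
        table.n_genes,
        table.n_samples,
    )
    return table


def parse_contrast(expr: str, levels: Iterable[str]) -> tuple[str, str]:
    """Split a ``Target-Control`` contrast expression into its two levels.

    The token before "-" is the target (numerator of the fold change),
    the token after is the control. Exactly one "-" is required and both
    tokens must be known condition levels.
    """
    levels = set(levels)
    if expr.count("-") != 1:
        raise InputFormatError(
            f"contrast {expr!r} must contain exactly one '-' separating two "
            f"condition levels; valid levels: {sorted(levels)}"
        )
    target, control = expr.split("-")
    for tok in (target, control):
        if tok not in levels:
            raise InputFormatError(
                f"contrast {expr!r}: {tok!r} is not a condition level; "
                f"valid levels: {sorted(levels)}"
            )
    if target == control:
        raise InputFormatError(f"contrast {expr!r}: target equals control")
    return target, control


def read_factors(path: str | Path, data: ExpressionTable,
                 contrast_tokens: Sequence[str] | None = None) -> FactorDesign:
    """Read the Factors file: first column sample id, remaining columns factors.

    Sample ids must match the expression table's sample set exactly. The
    contrast-defining factor column is the first column whose level set
    covers every token used in the Contrasts file; with no contrast
    tokens given, the first factor column is used.
    """
    df = _read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise InputFormatError(f"{path}: Factors file needs sample id + >=1 factor column")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    _check_unique(df.index, "sample id")

    data_samples = set(data.sample_ids)
    extra = [s for s in df.index if s not in data_samples]
    if extra:
        raise InputFormatError(
            f"Factors file lists sample(s) absent from the expression table: {extra}"
        )
    missing = [s for s in data.sample_ids if s not in set(df.index)]
    if missing:
        raise InputFormatError(
            f"expression table sample(s) missing from the Factors file: {missing}"
        )
    # align to data column order
    df = df.loc[data.sample_ids]

    if contrast_tokens:
        tokens = set(contrast_tokens)
        candidates = [c for c in df.columns if tokens <= set(df[c])]
        if not candidates:
            raise InputFormatError(
                f"no factor column covers the contrast levels {sorted(tokens)}"
            )
        if len(candidates) > 1:
            logger.info(
                "several factor columns cover the contrast levels; using the "
                "first: %r",
                candidates[0],
            )
        factor = candidates[0]
    else:
        factor = df.columns[0]
    return FactorDesign(df, factor)


def read_contrasts(path: str | Path, levels: Iterable[str]) -> ContrastSet:
    """Read the Contrasts file: one ``Target-Control`` expression per line."""
    df = _read_tsv(path, header=None, dtype=str)
    exprs = [str(v).strip() for v in df.iloc[:, 0] if str(v).strip()]
    contrasts = []
    for expr in exprs:
        target, control = parse_contrast(expr, levels)
        contrasts.append(Contrast(expr, target, control))
    return ContrastSet(contrasts)


def contrast_tokens(path: str | Path) -> list[str]:
    """Levels referenced by the Contrasts file, used to pick the factor column."""
    df = _read_tsv(path, header=None, dtype=str)
    tokens: list[str] = []
    for v in df.iloc[:, 0]:
        expr = str(v).strip()
        if expr and expr.count("-") == 1:
            tokens.extend(expr.split("-"))
    return tokens


def read_classes(path: str | Path) -> ClassMap:
    """Read the Classes file: three columns gene id, color, class name."""
    df = _read_tsv(path, header=None, dtype=str)
    if df.shape[1] < 3:
        raise InputFormatError(f"{path}: Classes file needs 3 columns gene/color/class")
    entries = [
        (str(g).strip(), str(col).strip(), str(cls).strip())
        for g, col, cls in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])
    ]
    return ClassMap(entries)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _format_cell(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "True" if v else "False"
    if isinstance(v, (float, np.floating)):
        return f"{v:.6g}"
    return str(v)


def write_table(obj, path: str | Path, index_label: str | None = None) -> Path:
    """Write a tabular result as TSV: header row, tab-delimited, floats at
    6 significant digits, deterministic column order (as given)."""
    path = Path(path)
    if isinstance(obj, pd.Series):
        obj = obj.to_frame()
    if not isinstance(obj, pd.DataFrame):
        raise TypeError(f"cannot write object of type {type(obj).__name__} as a table")
    df = obj
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            cols = list(map(str, df.columns))
            if index_label is not None:
                fh.write("\t".join([index_label] + cols) + "\n")
                for idx, row in zip(df.index, df.itertuples(index=False)):
                    fh.write("\t".join([str(idx)] + [_format_cell(v) for v in row]) + "\n")
            else:
                fh.write("\t".join(cols) + "\n")
                for row in df.itertuples(index=False):
                    fh.write("\t".join(_format_cell(v) for v in row) + "\n")
    except OSError as exc:
        raise InputFormatError(f"cannot write table to {path}: {exc}") from exc
    return path


def write_expression_table(table: ExpressionTable, path: str | Path) -> Path:
    return write_table(table.values, path, index_label="gene")
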