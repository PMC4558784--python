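"""End-to-end orchestration: inputs -> normalization -> contrasts ->
gene sets -> global structure -> classes/network -> report directory.

``run_pipeline`` executes the whole analysis deterministically for a
given seed, writes every module's tab-delimited outputs plus static
images and a small HTML index into the output directory, records a
MANIFEST with a checksum per file, and zips the lot. Any hard error
leaves the partial outputs in place with the MANIFEST marked
incomplete.
"""

from __future__ import annotations

import hashlib
import logging
import sys
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, classnet, genesets, io_formats, plots, structure
from .diffexp import NBDiffExp
from .io_formats import ClassMap, write_table
from .normalization import TMMNormalizer

logger = logging.getLogger("trex")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

DEFAULT_SEED = 20150903


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults mirror the printed cutoffs."""

    data: Path
    factors: Path
    contrasts: Path
    classes: Path | None = None
    out_dir: Path = Path("trex_out")
    project: str = "trex"
    tophits_fc: float = 2.0
    tophits_p: float = 0.05
    highfold_fc: float = 5.0
    highfold_p: float = 0.01
    background_fc: float = 1.4
    background_p: float = 0.25
    use_fdr: bool = False
    prior_df: float = 10.0
    fixed_dispersion: float | None = None
    seed: int = DEFAULT_SEED
    k_min: int = 2
    k_max: int = 12
    mds_top_n: int = 500
    make_plots: bool = True
    make_zip: bool = True

    def __post_init__(self) -> None:
        for name in ("tophits_fc", "tophits_p", "highfold_fc", "highfold_p",
                     "background_fc", "background_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class PipelineResult:
    out_dir: Path
    files: list[Path] = field(default_factory=list)
    complete: bool = False


def _safe(name: str) -> str:
    return "".join(ch if ch.isalnum() or ch in "._" else "_" for ch in name)


class _Emitter:
    def __init__(self, out: Path):
        self.out = out
        self.files: list[Path] = []

    def table(self, df, name: str, index_label: str | None = None) -> Path:
        path = write_table(df, self.out / name, index_label=index_label)
        self.files.append(path)
        return path

    def record(self, path: Path) -> Path:
        self.files.append(path)
        return path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; returns the output tree description."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    em = _Emitter(out)
    result = PipelineResult(out, em.files, complete=False)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        _run(config, em)
        result.complete = True
    finally:
        logger.removeHandler(handler)
        handler.close()
        em.record(log_path)
        _write_manifest(out, em.files, result.complete)
        if result.complete and config.make_zip:
            _write_zip(out, config.project)
    return result


def _run(config: RunConfig, em: _Emitter) -> None:
    logger.info("pipeline %s seed=%d version=%s", config.project, config.seed, __version__)
    data = io_formats.read_expression_table(config.data)
    tokens = io_formats.contrast_tokens(config.contrasts)
    factors = io_formats.read_factors(config.factors, data, tokens)
    contrasts = io_formats.read_contrasts(config.contrasts, factors.levels)
    if config.classes is not None:
        classes = io_formats.read_classes(config.classes).restrict_to(data.gene_ids)
    else:
        logger.info("no Classes file: all dots will be black, class outputs skipped")
        classes = ClassMap([])

    # normalization ---------------------------------------------------------
    norm = TMMNormalizer().fit(data)
    nres = norm.result(data)
    em.table(nres.lib_size.rename("lib_size"), "library_sizes.tsv", index_label="sample")
    em.table(nres.tmm_factor.rename("tmm_factor"), "tmm_factors.tsv", index_label="sample")
    em.table(nres.signal, "normalized_signals.tsv", index_label="gene")

    # differential expression ----------------------------------------------
    de = NBDiffExp(
        prior_df=config.prior_df, dispersion=config.fixed_dispersion
    ).fit(data.values, factors.condition.to_numpy(), nres.effective_lib)
    results = de.test_all(contrasts, zero_flag=nres.zero_flag)
    for name, res in results.items():
        tbl = res.table.copy()
        tbl["class"] = [";".join(classes.classes_of_gene(g)) for g in tbl.index]
        tbl["color"] = [classes.color_of_gene(g) or "black" for g in tbl.index]
        em.table(tbl, f"{_safe(name)}_results.tsv", index_label="gene")

    # gene sets -------------------------------------------------------------
    sets = genesets.build_genesets(
        results,
        config.tophits_fc,
        config.tophits_p,
        config.highfold_fc,
        config.highfold_p,
        config.background_fc,
        config.background_p,
        config.use_fdr,
    )
    for name, members in (
        ("tophits", sets.tophits),
        ("highfold", sets.highfold),
        ("no_background", sets.no_background),
    ):
        em.table(pd.DataFrame({"gene": sorted(members)}), f"{name}.tsv")
    em.table(sets.updown, "updown_counts.tsv")

    # global structure ------------------------------------------------------
    tophit_genes = sorted(sets.tophits)
    corr_signal = nres.signal.loc[tophit_genes] if len(tophit_genes) >= 3 else nres.signal
    corr = structure.experiment_correlation(corr_signal)
    em.table(corr.matrix, "correlation_experiments.tsv", index_label="sample")
    mds = structure.mds_coordinates(nres.signal, config.mds_top_n)
    em.table(mds.coords, "mds_coordinates.tsv", index_label="sample")

    spaces = {
        "signal": structure.signal_space(nres.signal, factors.condition),
        "ratio": structure.ratio_space(results),
    }
    scopes: dict[str, list[str]] = {"all": tophit_genes}
    for cls_name in classes.class_names:
        scopes[_safe(cls_name)] = [
            g for g in classes.members(cls_name) if g in data.gene_ids
        ]
    cluster_results: dict[tuple[str, str], structure.KMeansResult] = {}
    for space_name, mat in spaces.items():
        for scope_name, genes in scopes.items():
            sub = mat.loc[[g for g in genes if g in mat.index]]
            if sub.shape[0] < 2:
                logger.info(
                    "skipping clustering of %s/%s: fewer than 2 genes", space_name, scope_name
                )
                continue
            km = structure.AutoKMeans(
                k_min=config.k_min, k_max=config.k_max, seed=config.seed
            ).fit(sub)
            cluster_results[(space_name, scope_name)] = structure.KMeansResult(
                km.k_, km.assignment_, km.centroids_, km.inertia_, km.silhouette_,
                config.seed,
            )
            em.table(
                km.assignment_.to_frame().assign(k=km.k_, silhouette=f"{km.silhouette_:.6g}"),
                f"kmeans_{space_name}_{scope_name}.tsv",
                index_label="gene",
            )
            tree = structure.hclust(sub)
            em.table(
                pd.DataFrame({"gene": tree.leaf_order, "order": range(len(tree.leaf_order))}),
                f"hclust_{space_name}_{scope_name}.tsv",
            )

    # classes and network ---------------------------------------------------
    plot_tables = classnet.build_plot_tables(results, classes, config.use_fdr)
    for name, tbls in plot_tables.items():
        em.table(tbls["ma"], f"ma_{_safe(name)}.tsv")
        em.table(tbls["volcano"], f"volcano_{_safe(name)}.tsv")

    reports = {}
    for cls_name in classes.class_names:
        members = [g for g in classes.members(cls_name) if g in data.gene_ids]
        if not members:
            continue
        rep = classnet.class_report(cls_name, classes, nres.signal, factors.condition)
        reports[cls_name] = rep
        em.table(rep.profile, f"class_{_safe(cls_name)}_profile.tsv", index_label="gene")
        em.table(
            rep.correlation, f"class_{_safe(cls_name)}_correlation.tsv", index_label="gene"
        )

    net = classnet.build_gene_network(
        results, classes, config.tophits_fc, config.tophits_p, config.use_fdr
    )
    node_df, edge_df = classnet.export_cytoscape(net)
    em.table(node_df, "nodes.tsv")
    em.table(edge_df, "edges.tsv")

    # figures ---------------------------------------------------------------
    if config.make_plots:
        em.record(plots.library_sizes(nres.lib_size, em.out / "library_sizes.png"))
        em.record(plots.signal_boxplot(nres.signal, em.out / "signal_boxplot.png"))
        em.record(plots.mds_plot(mds.coords, em.out / "mds.png"))
        em.record(plots.updown_bars(sets.updown, em.out / "updown_counts.png"))
        em.record(
            plots.heatmap(corr.matrix, em.out / "correlation_experiments.png")
        )
        for name, tbls in plot_tables.items():
            em.record(
                plots.scatter_table(
                    tbls["ma"], "mean log2 CPM", "log2 FC", em.out / f"ma_{_safe(name)}.png"
                )
            )
            em.record(
                plots.scatter_table(
                    tbls["volcano"],
                    "log2 FC",
                    "-log10 p",
                    em.out / f"volcano_{_safe(name)}.png",
                )
            )
        for (space_name, scope_name), km in cluster_results.items():
            mat = spaces[space_name]
            sub = mat.loc[km.assignment.index]
            em.record(
                plots.cluster_profiles(
                    sub, km.assignment, em.out / f"kmeans_{space_name}_{scope_name}.png"
                )
            )
        for cls_name, rep in reports.items():
            em.record(
                plots.heatmap(
                    rep.profile.loc[rep.heatmap_order],
                    em.out / f"class_{_safe(cls_name)}_heatmap.png",
                )
            )
            em.record(
                plots.heatmap(
                    rep.correlation.loc[rep.heatmap_order, rep.heatmap_order],
                    em.out / f"class_{_safe(cls_name)}_correlation.png",
                )
            )
        kinds = {n: d["kind"] for n, d in net.graph.nodes(data=True)}
        colors = {n: d.get("color", "black") for n, d in net.graph.nodes(data=True)}
        em.record(
            plots.network_plot(
                net.layout, kinds, colors, list(net.graph.edges), em.out / "network.png"
            )
        )

    _write_index(em, config, sets)


def _write_index(em: _Emitter, config: RunConfig, sets) -> None:
    rows = "\n".join(
        f"<tr><td>{r.contrast}</td><td>{r.total_genes}</td>"
        f"<td>{r.n_up}</td><td>{r.n_down}</td></tr>"
        for r in sets.updown.itertuples(index=False)
    )
    links = "\n".join(
        f'<li><a href="{p.name}">{p.name}</a></li>'
        for p in sorted(em.files, key=lambda p: p.name)
    )
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{config.project}</title></head>
<body>
<h1>{config.project}</h1>
<p>Seed {config.seed}; cutoffs: TopHits FC&ge;{config.tophits_fc},
p&le;{config.tophits_p}; HighFold FC&ge;{config.highfold_fc},
p&le;{config.highfold_p}; background FC&le;{config.background_fc},
p&ge;{config.background_p}; {"FDR" if config.use_fdr else "raw p"} filtering.</p>
<h2>Up/down regulated genes per contrast</h2>
<table border="1"><tr><th>contrast</th><th>total</th><th>up</th><th>down</th></tr>
{rows}
</table>
<h2>Output files</h2>
<ul>
{links}
</ul>
</body></html>
"""
    path = em.out / "index.html"
    path.write_text(html, encoding="utf-8")
    em.record(path)


def _write_manifest(out: Path, files: list[Path], complete: bool) -> None:
    lines = ["file\tsha256"]
    for p in sorted(set(files), key=lambda p: p.name):
        if p.exists():
            digest = hashlib.sha256(p.read_bytes()).hexdigest()
            lines.append(f"{p.name}\t{digest}")
    lines.append(f"#STATUS\t{'complete' if complete else 'INCOMPLETE'}")
    (out / "MANIFEST.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_zip(out: Path, project: str) -> None:
    zip_path = out / f"{_safe(project)}.zip"
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for p in sorted(out.iterdir()):
            if p.is_file() and p != zip_path:
                # fixed timestamp keeps archives byte-stable across runs
                info = zipfile.ZipInfo(p.name, date_time=(2015, 9, 3, 0, 0, 0))
                info.compress_type = zipfile.ZIP_DEFLATED
                zf.writestr(info, p.read_bytes())
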