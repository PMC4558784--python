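"""Class-focused analyses and the gene-contrast overlap network.

MA and volcano plot tables color each gene by its user-defined class
(first class listed wins; unclassed genes are black) and mark genes that
had a raw zero in the compared samples with a cross.

The overlap network replaces multi-set Venn diagrams: one node per
contrast, one node per TopHits gene, an edge (gene, contrast) exactly
when the gene passes the TopHits cutoffs in that contrast, annotated
with the logFC sign. A gene shared by n contrasts has degree n. For
drawing, genes with an identical contrast-membership signature are
grouped under an invisible signature node beneath the first contrast of
the signature, and the resulting tree is laid out with the
Reingold-Tilford tidy-tree algorithm (x from subtree contours with unit
minimum sibling gap, y = depth, each parent centered on its extreme
children). Nodes and edges export as Cytoscape-importable TSV tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .diffexp import ContrastResult
from .genesets import fc_pass
from .io_formats import ClassMap
from .structure import hclust, signal_space

logger = logging.getLogger("trex")

__all__ = [
    "ClassReport",
    "GeneNetwork",
    "build_plot_tables",
    "class_report",
    "build_gene_network",
    "layout_reingold_tilford",
    "export_cytoscape",
]

P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# MA / volcano plot tables
# ---------------------------------------------------------------------------


def build_plot_tables(
    results: Mapping[str, ContrastResult],
    classes: ClassMap | None = None,
    use_fdr: bool = False,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per contrast: {"ma": ..., "volcano": ...} coordinate tables.

    MA: x = avg_signal, y = logFC. Volcano: x = logFC, y = -log10 p
    (p floored at 1e-300 with a warning). Columns: gene, x, y, color,
    marker, class.
    """
    classes = classes or ClassMap([])
    color = {g: c for g, c, _ in reversed(classes.entries)}  # first listed wins
    first_class: dict[str, str] = {}
    for g, _, cls in reversed(classes.entries):
        first_class[g] = cls
    pcol = "fdr" if use_fdr else "p_value"
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for name, res in results.items():
        t = res.table
        genes = list(t.index)
        colors = [color.get(g, "black") for g in genes]
        cls = [first_class.get(g, "") for g in genes]
        marker = np.where(t["zero_flag"].to_numpy(), "cross", "dot")
        p = t[pcol].to_numpy()
        if (p < P_FLOOR).any():
            logger.warning(
                "%d p-value(s) below %g floored for -log10 in contrast %s",
                int((p < P_FLOOR).sum()),
                P_FLOOR,
                name,
            )
        ma = pd.DataFrame(
            {
                "gene": genes,
                "x": t["avg_signal"].to_numpy(),
                "y": t["logFC"].to_numpy(),
                "color": colors,
                "marker": marker,
                "class": cls,
            }
        )
        volcano = pd.DataFrame(
            {
                "gene": genes,
                "x": t["logFC"].to_numpy(),
                "y": -np.log10(np.maximum(p, P_FLOOR)),
                "color": colors,
                "marker": marker,
                "class": cls,
            }
        )
        out[name] = {"ma": ma, "volcano": volcano}
    return out


# ---------------------------------------------------------------------------
# class reports
# ---------------------------------------------------------------------------


@dataclass
class ClassReport:
    class_name: str
    color: str
    members: list[str]
    profile: pd.DataFrame       # members x conditions, signal space
    correlation: pd.DataFrame   # member x member Pearson over condition means
    heatmap_order: list[str]


def class_report(
    class_name: str,
    classes: ClassMap,
    signal: pd.DataFrame,
    conditions: pd.Series,
) -> ClassReport:
    """Expression profile and member-member correlation for one class."""
    members = [g for g in classes.members(class_name) if g in signal.index]
    if not members:
        raise ValueError(f"class {class_name!r} has no members present in the data")
    profile = signal_space(signal.loc[members], conditions)
    X = profile.to_numpy(dtype=float)
    if len(members) == 1:
        corr = pd.DataFrame([[1.0]], index=members, columns=members)
        order = list(members)
    else:
        sd = X.std(axis=1)
        Xs = (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)[:, None]
        r = Xs @ Xs.T / X.shape[1]
        r[sd == 0, :] = 0.0
        r[:, sd == 0] = 0.0
        np.fill_diagonal(r, 1.0)
        corr = pd.DataFrame(np.clip(r, -1, 1), index=members, columns=members)
        order = hclust(profile).leaf_order
    return ClassReport(
        class_name=class_name,
        color=classes.color_of_class(class_name),
        members=members,
        profile=profile,
        correlation=corr,
        heatmap_order=order,
    )


# ---------------------------------------------------------------------------
# gene-contrast overlap network
# ---------------------------------------------------------------------------


@dataclass
class GeneNetwork:
    graph: nx.Graph                       # bipartite: gene and contrast nodes
    layout: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def gene_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene"]

    @property
    def contrast_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "contrast"]

    def assert_bipartite(self) -> None:
        for u, v in self.graph.edges:
            kinds = {self.graph.nodes[u]["kind"], self.graph.nodes[v]["kind"]}
            assert kinds == {"gene", "contrast"}, f"non-bipartite edge {u}-{v}"


def build_gene_network(
    results: Mapping[str, ContrastResult],
    classes: ClassMap | None = None,
    fc: float = 2.0,
    p: float = 0.05,
    use_fdr: bool = False,
) -> GeneNetwork:
    """Bipartite overlap network of TopHits genes vs contrasts."""
    classes = classes or ClassMap([])
    pcol = "fdr" if use_fdr else "p_value"
    g = nx.Graph()
    contrast_names = list(results)
    # contrast node ids are prefixed to avoid collision with gene ids
    for name in contrast_names:
        g.add_node(name, kind="contrast", color="grey", cls="")
    any_edge = False
    for name, res in results.items():
        t = res.table
        passing = fc_pass(t, fc) & (t[pcol].to_numpy() <= p)
        for gene, lfc in zip(t.index[passing], t["logFC"].to_numpy()[passing]):
            if gene not in g:
                g.add_node(
                    gene,
                    kind="gene",
                    color=classes.color_of_gene(gene) or "black",
                    cls=";".join(classes.classes_of_gene(gene)),
                )
            g.add_edge(gene, name, logFC=float(lfc), direction="up" if lfc > 0 else "down")
            any_edge = True
    if not any_edge:
        logger.warning("gene network is empty (no genes pass the cutoffs)")
    net = GeneNetwork(g)
    net.assert_bipartite()
    net.layout = layout_reingold_tilford(net, contrast_order=contrast_names)
    return net


# ---------------------------------------------------------------------------
# Reingold-Tilford tidy-tree layout
# ---------------------------------------------------------------------------


@dataclass
class _TreeNode:
    id: str
    children: list["_TreeNode"] = field(default_factory=list)


def _tidy_layout(
    node: _TreeNode, gap: float = 1.0
) -> tuple[dict[str, float], dict[int, tuple[float, float]]]:
    """Relative x positions for a subtree plus its per-depth contour.

    Positions are relative to this subtree's root (root at x=0). The
    contour maps depth -> (leftmost x, rightmost x). Children blocks are
    shifted so their contours keep at least ``gap`` horizontal
    separation at every shared depth, then the root is centered on the
    midpoint of its extreme children.
    """
    if not node.children:
        return {node.id: 0.0}, {0: (0.0, 0.0)}

    positions: dict[str, float] = {}
    contour: dict[int, tuple[float, float]] = {}
    child_x: list[float] = []
    for child in node.children:
        cpos, ccont = _tidy_layout(child, gap)
        if not contour:
            shift = 0.0
        else:
            shift = -np.inf
            for d, (cmin, _cmax) in ccont.items():
                if d + 1 in contour:
                    shift = max(shift, contour[d + 1][1] - cmin + gap)
            if shift == -np.inf:
                shift = 0.0
        for nid, x in cpos.items():
            positions[nid] = x + shift
        for d, (cmin, cmax) in ccont.items():
            if d + 1 in contour:
                pmin, pmax = contour[d + 1]
                contour[d + 1] = (min(pmin, cmin + shift), max(pmax, cmax + shift))
            else:
                contour[d + 1] = (cmin + shift, cmax + shift)
        child_x.append(shift)  # child root sits at x=0 relative to itself

    mid = (child_x[0] + child_x[-1]) / 2.0
    positions = {nid: x - mid for nid, x in positions.items()}
    contour = {d: (lo - mid, hi - mid) for d, (lo, hi) in contour.items()}
    positions[node.id] = 0.0
    contour[0] = (0.0, 0.0)
    return positions, contour


def _signature_tree(
    net: GeneNetwork, contrast_order: Sequence[str]
) -> _TreeNode:
    g = net.graph
    root = _TreeNode("__root__")
    contrast_nodes = {c: _TreeNode(c) for c in contrast_order}
    root.children = [contrast_nodes[c] for c in contrast_order]
    order_idx = {c: i for i, c in enumerate(contrast_order)}
    sig_nodes: dict[tuple[str, ...], _TreeNode] = {}
    for gene in sorted(net.gene_nodes):
        sig = tuple(sorted(g.neighbors(gene), key=order_idx.get))
        if sig not in sig_nodes:
            node = _TreeNode("__sig__" + "|".join(sig))
            sig_nodes[sig] = node
            contrast_nodes[sig[0]].children.append(node)
        sig_nodes[sig].children.append(_TreeNode(gene))
    return root


def layout_reingold_tilford(
    net: GeneNetwork, contrast_order: Sequence[str] | None = None, gap: float = 1.0
) -> dict[str, tuple[float, float]]:
    """Tidy-tree coordinates for the network's contrast-signature tree.

    Returns visible-node coordinates only (virtual root and signature
    group nodes are dropped); y is tree depth, x from the contour-based
    first pass.
    """
    if net.graph.number_of_nodes() == 0:
        return {}
    contrast_order = list(contrast_order or net.contrast_nodes)
    root = _signature_tree(net, contrast_order)
    positions, _ = _tidy_layout(root, gap)

    depths: dict[str, int] = {}

    def walk(node: _TreeNode, d: int) -> None:
        depths[node.id] = d
        for c in node.children:
            walk(c, d + 1)

    walk(root, 0)
    return {
        nid: (x, float(depths[nid]))
        for nid, x in positions.items()
        if not nid.startswith("__")
    }


def export_cytoscape(
    net: GeneNetwork,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables importable via Cytoscape's delimited importer."""
    g = net.graph
    nodes = []
    for nid in sorted(net.contrast_nodes) + sorted(net.gene_nodes):
        d = g.nodes[nid]
        x, y = net.layout.get(nid, (0.0, 0.0))
        nodes.append(
            {
                "id": nid,
                "kind": d["kind"],
                "class": d.get("cls", ""),
                "color": d.get("color", "black"),
                "x": x,
                "y": y,
            }
        )
    edges = []
    for u, v, d in sorted(g.edges(data=True)):
        gene, contrast = (u, v) if g.nodes[u]["kind"] == "gene" else (v, u)
        edges.append(
            {
                "source": gene,
                "target": contrast,
                "logFC": d["logFC"],
                "direction": d["direction"],
            }
        )
    node_df = pd.DataFrame(nodes, columns=["id", "kind", "class", "color", "x", "y"])
    edge_df = pd.DataFrame(edges, columns=["source", "target", "logFC", "direction"])
    return node_df, edge_df
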