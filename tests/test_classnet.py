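"""Plot tables, class reports, the overlap network and its tidy-tree layout."""

import numpy as np
import pandas as pd
import pytest

from trex.classnet import (
    GeneNetwork,
    _TreeNode,
    _tidy_layout,
    build_gene_network,
    build_plot_tables,
    class_report,
    export_cytoscape,
    layout_reingold_tilford,
)
from trex.diffexp import ContrastResult
from trex.genesets import count_up_down
from trex.io_formats import ClassMap

SEED = 20150903


def _result(name, genes, logfc, p, zero=None):
    zero = zero or [False] * len(genes)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "avg_signal": np.linspace(1, 10, len(genes)),
            "p_value": p,
            "fdr": p,
            "zero_flag": zero,
        },
        index=genes,
    )
    return ContrastResult(name, "t", "c", table)


def _random_results(rng, n_genes=40, n_contrasts=3):
    genes = [f"g{i}" for i in range(n_genes)]
    return {
        f"c{j}": _result(
            f"c{j}", genes, rng.normal(0, 2, n_genes), rng.uniform(size=n_genes)
        )
        for j in range(n_contrasts)
    }


class TestPlotTables:
    def test_unclassed_gene_black_classed_gets_class_color(self):
        res = {"c": _result("c", ["g1", "g2"], [1.0, 2.0], [0.01, 0.01])}
        classes = ClassMap([("g1", "green", "CodY")])
        tbl = build_plot_tables(res, classes)["c"]["ma"]
        assert tbl.set_index("gene").loc["g1", "color"] == "green"
        assert tbl.set_index("gene").loc["g2", "color"] == "black"

    def test_zero_flagged_gene_marked_cross(self):
        res = {"c": _result("c", ["g1", "g2"], [1.0, 2.0], [0.1, 0.1], [True, False])}
        tbl = build_plot_tables(res)["c"]["volcano"].set_index("gene")
        assert tbl.loc["g1", "marker"] == "cross"
        assert tbl.loc["g2", "marker"] == "dot"

    def test_multiclass_gene_takes_first_listed_class(self):
        res = {"c": _result("c", ["g1"], [1.0], [0.1])}
        classes = ClassMap([("g1", "green", "CodY"), ("g1", "red", "CcpA")])
        tbl = build_plot_tables(res, classes)["c"]["ma"]
        assert tbl.loc[0, "color"] == "green"
        assert tbl.loc[0, "class"] == "CodY"

    def test_volcano_axes_and_p_floor(self, caplog):
        res = {"c": _result("c", ["g1", "g2"], [1.5, -1.0], [0.0, 0.01])}
        with caplog.at_level("WARNING", logger="trex"):
            tbl = build_plot_tables(res)["c"]["volcano"]
        assert tbl.loc[1, "x"] == -1.0
        assert tbl.loc[1, "y"] == pytest.approx(2.0)
        assert tbl.loc[0, "y"] == pytest.approx(300.0)  # floored at 1e-300
        assert "floored" in caplog.text


class TestClassReport:
    def test_identical_profiles_correlate_perfectly(self):
        sig = pd.DataFrame(
            np.array([[1.0, 2.0, 5.0, 6.0], [1.0, 2.0, 5.0, 6.0], [9.0, 1.0, 1.0, 9.0]]),
            index=["g1", "g2", "g3"],
            columns=["a1", "a2", "b1", "b2"],
        )
        cond = pd.Series(["a", "a", "b", "b"], index=sig.columns)
        classes = ClassMap([("g1", "green", "C"), ("g2", "green", "C")])
        rep = class_report("C", classes, sig, cond)
        assert rep.correlation.loc["g1", "g2"] == pytest.approx(1.0)
        assert rep.profile.shape == (2, 2)

    def test_singleton_class_still_reports(self):
        sig = pd.DataFrame(
            np.arange(8.0).reshape(2, 4),
            index=["g1", "g2"],
            columns=["a1", "a2", "b1", "b2"],
        )
        cond = pd.Series(["a", "a", "b", "b"], index=sig.columns)
        rep = class_report("C", ClassMap([("g1", "green", "C")]), sig, cond)
        assert rep.correlation.shape == (1, 1)
        assert rep.members == ["g1"]

    def test_coregulated_class_correlates_above_random(self, default_dataset):
        table, factors, contrasts, classes, truth = default_dataset
        from trex.normalization import normalize

        sig = normalize(table).signal
        name = classes.class_names[0]
        rep = class_report(name, classes, sig, factors.condition)
        r = rep.correlation.to_numpy()
        class_r = np.median(r[np.triu_indices_from(r, 1)])
        rng = np.random.default_rng(SEED)
        genes = list(sig.index)
        rand = []
        for _ in range(300):
            a, b = rng.choice(len(genes), 2, replace=False)
            prof = sig.iloc[[a, b]].T.groupby(factors.condition).mean().T.to_numpy()
            rand.append(np.corrcoef(prof)[0, 1])
        assert class_r > np.median(rand)


class TestGeneNetwork:
    def test_degree_counts_contrast_memberships(self):
        genes = ["g1", "g2"]
        res = {
            f"c{j}": _result(f"c{j}", genes, [2.0, 2.0 if j == 0 else 0.1], [0.01, 0.01])
            for j in range(4)
        }
        net = build_gene_network(res)
        assert net.graph.degree["g1"] == 4
        assert net.graph.degree["g2"] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_edge_count_identity(self, seed):
        rng = np.random.default_rng(seed)
        res = _random_results(rng)
        net = build_gene_network(res)
        expected = sum(sum(count_up_down(r)) for r in res.values())
        assert net.graph.number_of_edges() == expected
        net.assert_bipartite()

    def test_empty_network_warned_and_exported(self, caplog):
        res = {"c": _result("c", ["g"], [0.1], [0.9])}
        with caplog.at_level("WARNING", logger="trex"):
            net = build_gene_network(res)
        nodes, edges = export_cytoscape(net)
        assert len(edges) == 0
        assert list(nodes["kind"]) == ["contrast"]
        assert "empty" in caplog.text

    def test_cytoscape_tables_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        res = _random_results(rng, n_genes=20, n_contrasts=2)
        net = build_gene_network(res)
        nodes, edges = export_cytoscape(net)
        from trex.io_formats import write_table

        np_, ep_ = tmp_path / "nodes.tsv", tmp_path / "edges.tsv"
        write_table(nodes, np_)
        write_table(edges, ep_)
        nodes2 = pd.read_csv(np_, sep="\t")
        edges2 = pd.read_csv(ep_, sep="\t")
        assert set(nodes2["id"]) == set(nodes["id"])
        assert set(zip(edges2["source"], edges2["target"])) == set(
            zip(edges["source"], edges["target"])
        )

    def test_node_and_edge_counts_in_export(self):
        # 2 contrasts, 3 genes, 4 significant (gene, contrast) pairs
        res = {
            "c0": _result("c0", ["g1", "g2", "g3"], [2.0, 2.0, 2.0], [0.01, 0.01, 0.9]),
            "c1": _result("c1", ["g1", "g2", "g3"], [2.0, 0.1, -2.0], [0.01, 0.9, 0.01]),
        }
        net = build_gene_network(res)
        nodes, edges = export_cytoscape(net)
        assert len(nodes) == 5
        assert len(edges) == 4
        assert set(edges["direction"]) == {"up", "down"}


class TestTidyTreeLayout:
    def test_star_leaves_evenly_spaced(self):
        res = {"c": _result("c", ["g1", "g2", "g3"], [2.0] * 3, [0.01] * 3)}
        net = build_gene_network(res)
        xs = sorted(net.layout[g][0] for g in ["g1", "g2", "g3"])
        gaps = np.diff(xs)
        assert np.allclose(gaps, gaps[0])
        assert net.layout["c"][1] == 1.0  # contrast depth
        assert all(net.layout[g][1] == 3.0 for g in ["g1", "g2", "g3"])

    def test_parent_centered_on_extreme_children(self):
        root = _TreeNode("r", [
            _TreeNode("a", [_TreeNode("a1"), _TreeNode("a2")]),
            _TreeNode("b", [_TreeNode("b1"), _TreeNode("b2"), _TreeNode("b3")]),
        ])
        pos, _ = _tidy_layout(root)
        assert pos["a"] == pytest.approx((pos["a1"] + pos["a2"]) / 2)
        assert pos["b"] == pytest.approx((pos["b1"] + pos["b3"]) / 2)
        assert pos["r"] == pytest.approx((pos["a"] + pos["b"]) / 2)

    def test_mirror_symmetric_siblings(self):
        left = _TreeNode("l", [_TreeNode("l1"), _TreeNode("l2")])
        right = _TreeNode("r", [_TreeNode("r1"), _TreeNode("r2")])
        pos, _ = _tidy_layout(_TreeNode("root", [left, right]))
        assert pos["root"] == pytest.approx((pos["l"] + pos["r"]) / 2)
        assert pos["l2"] - pos["l1"] == pytest.approx(pos["r2"] - pos["r1"])

    @pytest.mark.parametrize("seed", range(6))
    def test_random_tree_properties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        nodes = [_TreeNode(f"n{i}") for i in range(n)]
        for i in range(1, n):
            parent = nodes[int(rng.integers(0, i))]
            parent.children.append(nodes[i])
        pos, _ = _tidy_layout(nodes[0])

        depths = {}

        def walk(node, d):
            depths[node.id] = d
            for c in node.children:
                walk(c, d + 1)

        walk(nodes[0], 0)
        by_depth = {}
        for nid, x in pos.items():
            by_depth.setdefault(depths[nid], []).append(x)
        for xs in by_depth.values():
            xs = sorted(xs)
            assert all(b - a >= 1.0 - 1e-9 for a, b in zip(xs, xs[1:]))
        for node in nodes:
            if node.children:
                cx = [pos[c.id] for c in node.children]
                assert pos[node.id] == pytest.approx((min(cx) + max(cx)) / 2)

    def test_empty_network_gives_empty_layout(self):
        import networkx as nx

        net = GeneNetwork(nx.Graph())
        assert layout_reingold_tilford(net) == {}
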