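import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rfinet import network as N
from rfinet.datatypes import ValidationError


def make_edges(pairs, accepted=True):
    return pd.DataFrame({
        "gene_a": [a for a, _ in pairs],
        "gene_b": [b for _, b in pairs],
        "r": [0.9] * len(pairs),
        "z": [2.5] * len(pairs),
        "accepted": [accepted] * len(pairs),
    })


def star_network(center_is_tf=True):
    pairs = [("hub", f"leaf{i}") for i in range(4)]
    tissue = pd.Series("muscle", index=["hub"] + [f"leaf{i}" for i in range(4)])
    return N.build_network(
        make_edges(pairs),
        de_genes=[f"leaf{i}" for i in range(4)],
        ts_genes=[],
        tf_genes=["hub"] if center_is_tf else [],
        snp_genes=[] if center_is_tf else ["hub"],
        tissue_of_max=tissue,
    )


class TestBuildNetwork:
    def test_empty_edges_preserves_nodes(self):
        net = N.build_network(
            make_edges([]), ["a"], ["b"], ["c"], ["d"],
            tissue_of_max=pd.Series("liver", index=list("abcd")),
        )
        assert net.n_edges == 0 and net.n_nodes == 4

    def test_nonexclusive_flags(self):
        net = N.build_network(
            make_edges([]), ["a"], ["a"], ["a"], [],
            tissue_of_max=pd.Series("liver", index=["a"]),
        )
        row = net.nodes.loc["a"]
        assert row["is_de"] and row["is_ts"] and row["is_tf"] and not row["is_snp"]

    def test_only_accepted_edges_kept(self):
        edges = pd.concat([make_edges([("a", "b")]), make_edges([("a", "c")], accepted=False)])
        net = N.build_network(
            edges, ["a", "b", "c"], [], [], [],
            tissue_of_max=pd.Series("liver", index=list("abc")),
        )
        assert net.n_edges == 1

    def test_planted_class_counts(self, small_sim):
        _, _, (cm, meta, annotation, truth) = small_sim
        de = list(truth.true_de)
        ts = list(truth.true_ts)
        tissue = pd.Series("muscle", index=cm.genes)
        net = N.build_network(make_edges([]), de, ts, annotation.tf_genes,
                              annotation.snp_genes, tissue)
        assert int(net.nodes["is_de"].sum()) == len(de)
        assert int(net.nodes["is_ts"].sum()) == len(ts)
        assert int(net.nodes["is_tf"].sum()) == len(annotation.tf_genes)
        assert int(net.nodes["is_snp"].sum()) == len(annotation.snp_genes)

    def test_missing_endpoint_annotation_raises(self):
        with pytest.raises(ValidationError):
            N.GeneNetwork(
                nodes=pd.DataFrame(index=["a"]),
                edges=make_edges([("a", "zzz")]),
            )


class TestDegreeTable:
    def test_isolated_node(self):
        net = N.build_network(make_edges([]), ["a"], [], [], [],
                              pd.Series("liver", index=["a"]))
        assert N.degree_table(net).loc["a", "degree"] == 0

    def test_star(self):
        table = N.degree_table(star_network())
        assert table.loc["hub", "degree"] == 4
        assert (table.drop("hub")["degree"] == 1).all()
        assert table.index[0] == "hub"

    def test_degree_sum_is_twice_edges(self, small_sim):
        rng = np.random.default_rng(0)
        genes = [f"n{i}" for i in range(30)]
        pairs = {tuple(sorted(rng.choice(genes, 2, replace=False))) for _ in range(60)}
        net = N.build_network(make_edges(sorted(pairs)), genes, [], [], [],
                              pd.Series("liver", index=genes))
        assert N.degree_table(net)["degree"].sum() == 2 * net.n_edges


class TestTissueEdgeSummary:
    def test_all_within(self):
        net = star_network()
        assert N.tissue_edge_summary(net)["within_fraction"] == pytest.approx(1.0)

    def test_bipartite_zero(self):
        genes = ["m1", "m2", "l1", "l2"]
        tissue = pd.Series(["muscle", "muscle", "liver", "liver"], index=genes)
        net = N.build_network(make_edges([("m1", "l1"), ("m2", "l2")]),
                              genes, [], [], [], tissue)
        assert N.tissue_edge_summary(net)["within_fraction"] == pytest.approx(0.0)

    def test_relabeling_invariance(self):
        genes = [f"x{i}" for i in range(6)]
        tissue = pd.Series(["a", "a", "b", "b", "c", "c"], index=genes)
        pairs = [("x0", "x1"), ("x0", "x2"), ("x3", "x4"), ("x4", "x5")]
        net1 = N.build_network(make_edges(pairs), genes, [], [], [], tissue)
        renamed = {g: f"y{i}" for i, g in enumerate(genes)}
        pairs2 = [(renamed[a], renamed[b]) for a, b in pairs]
        tissue2 = pd.Series(tissue.to_numpy(), index=[renamed[g] for g in genes])
        net2 = N.build_network(make_edges(pairs2), list(renamed.values()), [], [], [], tissue2)
        s1, s2 = N.tissue_edge_summary(net1), N.tissue_edge_summary(net2)
        assert s1["within_fraction"] == pytest.approx(s2["within_fraction"])

    def test_inter_edge_r2_perfect_proportionality(self):
        # 3 tissues with inter-tissue edge counts exactly proportional to nodes
        genes = [f"a{i}" for i in range(2)] + [f"b{i}" for i in range(4)] + [f"c{i}" for i in range(6)]
        tissue = pd.Series(["ta"] * 2 + ["tb"] * 4 + ["tc"] * 6, index=genes)
        pairs = [("a0", "b0"), ("a1", "c0"), ("b1", "c1"), ("b2", "c2"), ("b3", "c3")]
        # node counts 2/4/6 -> inter-degree 2/4/6? a:2 edges, b:4, c:5... craft:
        pairs = [("a0", "b0"), ("a1", "c0"),              # ta: 2
                 ("b1", "c1"), ("b2", "c2"), ("b3", "c3")]  # tb: 4, tc: 5
        net = N.build_network(make_edges(pairs), genes, [], [], [], tissue)
        summary = N.tissue_edge_summary(net)
        assert 0.0 <= summary["inter_edge_r2"] <= 1.0


def test_within_tissue_fraction_dominates_without_modules():
    """Pooled-tissue simulation (no hub modules): tissue signal dominates,
    so more than half of accepted edges join genes of the same dominant
    tissue."""
    from rfinet import expression as E
    from rfinet import pcit
    from rfinet.simulate import ExperimentDesign, SimParams, simulate_expression

    design = ExperimentDesign(seed=31, n_genes=500, n_tf=25, n_snp_genes=50,
                              animals_per_sire=4)
    params = SimParams(n_hub_tf=0, ts_fraction=0.2, depth_mean=5e5)
    cm, meta, annotation, truth = simulate_expression(design, params)
    em = E.compute_rpkm(cm, meta=meta)
    shares = E.tissue_share(em)
    ts_calls = E.classify_tissue_specific(shares)
    Y = E.log2_transform(em)
    nodes = ts_calls.index[ts_calls["is_ts"]].union(annotation.tf_genes).union(
        annotation.snp_genes
    )
    edges = pcit.infer_network(Y.loc[nodes])
    net = N.build_network(edges, [], ts_calls.index[ts_calls["is_ts"]],
                          annotation.tf_genes, annotation.snp_genes,
                          shares.idxmax(axis=1))
    summary = N.tissue_edge_summary(net)
    assert net.n_edges > 0
    assert summary["within_fraction"] > 0.5, summary["within_fraction"]


class TestTfSubnetwork:
    def test_star_with_tf_center_identical(self):
        net = star_network(center_is_tf=True)
        sub = N.extract_tf_subnetwork(net)
        assert set(sub.nodes.index) == set(net.nodes.index)
        assert sub.n_edges == net.n_edges

    def test_tf_without_edges(self):
        net = N.build_network(make_edges([("a", "b")]), ["a", "b"], [], ["tf_lonely"], [],
                              pd.Series("liver", index=["a", "b", "tf_lonely"]))
        sub = N.extract_tf_subnetwork(net)
        assert sub.n_edges == 0
        assert list(sub.nodes.index) == ["tf_lonely"]

    def test_edge_bound(self, small_sim):
        rng = np.random.default_rng(1)
        genes = [f"n{i}" for i in range(20)]
        pairs = sorted({tuple(sorted(rng.choice(genes, 2, replace=False))) for _ in range(50)})
        tfs = genes[:4]
        net = N.build_network(make_edges(pairs), genes, [], tfs, [],
                              pd.Series("liver", index=genes))
        sub = N.extract_tf_subnetwork(net)
        tf_degree_sum = N.degree_table(net).loc[tfs, "degree"].sum()
        assert sub.n_edges <= tf_degree_sum

    def test_no_tf_empty(self):
        net = star_network(center_is_tf=False)
        sub = N.extract_tf_subnetwork(net)
        assert sub.n_nodes == 0 and sub.n_edges == 0


class TestFisherEnrichment:
    def test_set_equals_universe(self):
        universe = [f"g{i}" for i in range(10)]
        term_map = {g: ["T1"] for g in universe[:4]}
        res = N.fisher_enrichment(universe, universe, term_map)
        assert (res["p_value"] == 1.0).all()

    def test_closed_form_value(self):
        universe = [f"g{i}" for i in range(20)]
        term_map = {g: ["T1"] for g in universe[:5]}
        res = N.fisher_enrichment(universe[:5], universe, term_map)
        assert res.loc[res["term"] == "T1", "p_value"].iloc[0] == pytest.approx(
            1 / math.comb(20, 5), rel=1e-9
        )

    def test_term_absent_from_set(self):
        universe = [f"g{i}" for i in range(20)]
        term_map = {g: ["T1"] for g in universe[10:]}
        res = N.fisher_enrichment(universe[:10], universe, term_map)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_scipy_fisher_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n_univ = int(rng.integers(8, 40))
            universe = [f"g{i}" for i in range(n_univ)]
            in_term = rng.random(n_univ) < 0.4
            term_map = {g: ["T"] for g, f in zip(universe, in_term) if f}
            n_set = int(rng.integers(1, n_univ))
            gene_set = list(rng.choice(universe, n_set, replace=False))
            res = N.fisher_enrichment(gene_set, universe, term_map)
            if not len(res):
                continue
            row = res.iloc[0]
            table = [[row["set_in_term"], row["set_not_in_term"]],
                     [row["universe_in_term"] - row["set_in_term"],
                      row["universe_not_in_term"] - row["set_not_in_term"]]]
            _, p = stats.fisher_exact(table, alternative="greater")
            assert row["p_value"] == pytest.approx(p, abs=1e-10)

    def test_empty_universe_raises(self):
        with pytest.raises(ValidationError):
            N.fisher_enrichment([], [], {})

    def test_set_outside_universe_raises(self):
        with pytest.raises(ValidationError):
            N.fisher_enrichment(["x"], ["a", "b"], {})


class TestExport:
    def test_empty_network_files(self, tmp_path):
        net = N.build_network(make_edges([]), ["a"], [], [], [],
                              pd.Series("liver", index=["a"]))
        for fmt, name in (("sif", "n.sif"), ("tsv", "n.tsv"), ("graphml", "n.graphml")):
            path = N.export_network(net, tmp_path / name, fmt=fmt)
            assert path.exists()

    def test_sif_line_count(self, tmp_path):
        genes = ["a", "b", "c", "d"]
        net = N.build_network(make_edges([("a", "b"), ("b", "c"), ("c", "d")]),
                              genes, [], [], [], pd.Series("liver", index=genes))
        path = N.export_network(net, tmp_path / "net.sif", fmt="sif")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3 and all("\tco\t" in ln for ln in lines)

    def test_tsv_round_trip(self, tmp_path):
        genes = ["a", "b", "c"]
        net = N.build_network(make_edges([("a", "b"), ("b", "c")]), genes, ["a"],
                              ["b"], ["c"], pd.Series("muscle", index=genes))
        N.export_network(net, tmp_path / "net_edges.tsv", fmt="tsv")
        back = N.read_network_tsv(tmp_path / "net_edges.tsv")
        pd.testing.assert_frame_equal(back.edges, net.edges)
        pd.testing.assert_frame_equal(back.nodes, net.nodes, check_names=False)

    def test_unknown_format(self, tmp_path):
        net = star_network()
        with pytest.raises(ValueError):
            N.export_network(net, tmp_path / "x", fmt="dot")
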