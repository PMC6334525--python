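"""Association measures, per-condition network inference and differential
edge classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from pluristate import (
    GeneNetwork,
    binary_association,
    build_network,
    classify_edges,
    compare_noise,
    concat_conditions,
    correlation_association,
    edge_cv_gain_comparison,
    simulate_expression_matrix,
    target_subnetwork_degrees,
)
from pluristate.network import Edge
from conftest import make_panel


def fisher_p_enumeration(table):
    """Independent two-sided Fisher p: sum of hypergeometric point
    probabilities no larger than the observed table's."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmfs = hypergeom.pmf(support, n, col1, row1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    return float(pmfs[pmfs <= p_obs * (1 + 1e-9)].sum())


def make_edge(a, b, condition="A"):
    a, b = sorted((a, b))
    return Edge(
        gene_a=a, gene_b=b, condition=condition,
        spearman_rho=0.5, spearman_p=0.01, spearman_q=0.02, n_codetected=30,
        odds_ratio=2.0, or_p=0.01, or_q=0.02, significant_by=("correlation",),
    )


def make_net(pairs, nodes, condition="A", targets=()):
    node_df = pd.DataFrame({"is_h3k9ac_target": [n in targets for n in nodes]}, index=list(nodes))
    return GeneNetwork(
        condition=condition,
        nodes=node_df,
        edges=[make_edge(a, b, condition) for a, b in pairs],
    )


class TestBinaryAssociation:
    def test_independence_table(self):
        det_a = np.repeat([True, True, False, False], 10)
        det_b = np.tile(np.repeat([True, False], 10), 2)
        r = binary_association(det_a, det_b)
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)
        assert np.array_equal(r.table, [[10, 10], [10, 10]])

    def test_strong_association_or16_and_enumerated_p(self):
        det_a = np.array([True] * 25 + [False] * 25)
        det_b = np.array([True] * 20 + [False] * 5 + [True] * 5 + [False] * 20)
        r = binary_association(det_a, det_b)
        assert r.odds_ratio == pytest.approx(16.0)
        assert r.p == pytest.approx(fisher_p_enumeration(r.table), abs=1e-12)

    def test_haldane_correction_on_zero_cell(self):
        det_a = np.array([True] * 10 + [False] * 10)
        det_b = np.array([True] * 10 + [True] * 5 + [False] * 5)
        r = binary_association(det_a, det_b)
        assert np.array_equal(r.table, [[10, 0], [5, 5]])
        assert r.corrected
        assert r.odds_ratio == pytest.approx((10.5 * 5.5) / (0.5 * 5.5))

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        det_a, det_b = rng.random(60) < 0.6, rng.random(60) < 0.4
        r1, r2 = binary_association(det_a, det_b), binary_association(det_b, det_a)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio)
        assert r1.p == pytest.approx(r2.p)

    def test_marginal_degenerate_flagged_not_error(self):
        r = binary_association(np.ones(20, bool), np.random.default_rng(1).random(20) < 0.5)
        assert not r.defined

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10), st.integers(0, 10))
    def test_fisher_p_matches_enumeration_small_tables(self, a, b, c, d):
        """All 2x2 tables with n <= 40: p equals full enumeration to 1e-12."""
        n = a + b + c + d
        if n < 10:
            return
        det_a = np.array([True] * (a + b) + [False] * (c + d))
        det_b = np.array([True] * a + [False] * b + [True] * c + [False] * d)
        r = binary_association(det_a, det_b)
        assert r.p == pytest.approx(fisher_p_enumeration([[a, b], [c, d]]), abs=1e-12)


class TestCorrelationAssociation:
    def test_perfect_monotone(self):
        x = np.arange(1.0, 11.0)
        assert correlation_association(x, x**2).rho == pytest.approx(1.0)
        assert correlation_association(x, x[::-1]).rho == pytest.approx(-1.0)

    def test_below_min_codetect_flagged(self):
        x = np.array([1.0, 2, 3, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan])
        r = correlation_association(x, x, min_codetect=10)
        assert not r.defined and r.n_codetected == 3

    def test_constant_vector_flagged(self):
        x = np.arange(12.0)
        r = correlation_association(np.full(12, 2.0), x)
        assert not r.defined

    def test_planted_copula_rho_recovered(self):
        panel = make_panel(n_genes=4, planted=[("g1", "g2", 0.6)], p_detect=1.0)
        m = simulate_expression_matrix(panel, 500, "A", seed=5)
        r = correlation_association(m.values["g1"].to_numpy(), m.values["g2"].to_numpy())
        assert r.rho == pytest.approx(0.6, abs=0.1)


class TestBuildNetwork:
    def test_planted_pairs_recovered_null_pairs_quiet(self):
        planted = [("g1", "g2", 0.6), ("g3", "g4", 0.6), ("g5", "g6", 0.6)]
        panel = make_panel(n_genes=12, planted=planted, p_detect=0.9, seed=6)
        m = simulate_expression_matrix(panel, 100, "A", seed=7)
        net = build_network(m, "A", alpha=0.05)
        found = net.edge_pairs
        hits = sum(frozenset((a, b)) in found for a, b, _ in planted)
        assert hits >= 2
        false_edges = [p for p in found if p not in {frozenset((a, b)) for a, b, _ in planted}]
        assert len(false_edges) <= 2

    def test_no_self_loops_or_duplicates(self):
        panel = make_panel(n_genes=8, planted=[("g1", "g2", 0.7)], seed=8)
        m = simulate_expression_matrix(panel, 80, "A", seed=9)
        net = build_network(m, "A")
        pairs = [e.pair for e in net.edges]
        assert len(pairs) == len(set(pairs))
        assert all(e.gene_a != e.gene_b for e in net.edges)

    def test_spikeins_excluded_from_pairs(self):
        panel = make_panel(n_genes=5, seed=10)
        m = simulate_expression_matrix(panel, 60, "A", seed=11)
        net = build_network(m, "A")
        assert not any(g.startswith("spike") for n in net.edges for g in (n.gene_a, n.gene_b))

    def test_conjunctive_rule_is_stricter(self):
        panel = make_panel(n_genes=10, planted=[("g1", "g2", 0.7)], seed=12)
        m = simulate_expression_matrix(panel, 100, "A", seed=13)
        either = build_network(m, "A", edge_rule="either")
        both = build_network(m, "A", edge_rule="both")
        assert both.edge_pairs <= either.edge_pairs


class TestClassifyEdges:
    def test_identical_sets_all_common(self):
        nodes = list("abcd")
        net = make_net([("a", "b"), ("c", "d")], nodes)
        cmp = classify_edges(net, make_net([("a", "b"), ("c", "d")], nodes, "B"))
        assert len(cmp.common) == 2 and not cmp.only_a and not cmp.only_b

    def test_disjoint_sets_no_common(self):
        nodes = list("abcd")
        cmp = classify_edges(
            make_net([("a", "b")], nodes), make_net([("c", "d")], nodes, "B")
        )
        assert not cmp.common and len(cmp.only_a) == 1 and len(cmp.only_b) == 1

    def test_set_algebra_example(self):
        nodes = list("abcd")
        cmp = classify_edges(
            make_net([("a", "b"), ("b", "c")], nodes),
            make_net([("b", "c"), ("c", "d")], nodes, "B"),
        )
        assert cmp.common == {frozenset("bc")}
        assert cmp.only_a == {frozenset("ab")}
        assert cmp.only_b == {frozenset("cd")}

    def test_mismatched_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            classify_edges(make_net([], list("abc")), make_net([], list("abd"), "B"))

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_partition_property(self, data):
        """|common| + |only_A| + |only_B| = |union| on random networks."""
        nodes = list("abcdefgh")
        all_pairs = [(x, y) for i, x in enumerate(nodes) for y in nodes[i + 1:]]
        pa = data.draw(st.sets(st.sampled_from(all_pairs), max_size=12))
        pb = data.draw(st.sets(st.sampled_from(all_pairs), max_size=12))
        cmp = classify_edges(make_net(pa, nodes), make_net(pb, nodes, "B"))
        union = {frozenset(p) for p in pa} | {frozenset(p) for p in pb}
        assert len(cmp.common) + len(cmp.only_a) + len(cmp.only_b) == len(union)
        assert cmp.common | cmp.only_a | cmp.only_b == union


class TestTargetDegrees:
    def test_no_targets_zero_count(self):
        nodes = list("abcd")
        cmp = classify_edges(
            make_net([("a", "b")], nodes), make_net([("a", "b")], nodes, "B")
        )
        table = target_subnetwork_degrees(cmp, {n: False for n in nodes})
        assert (table["target_edges"] == 0).all()

    def test_star_hub_degree(self):
        nodes = list("habcd")
        pairs = [("h", x) for x in "abcd"]
        cmp = classify_edges(make_net(pairs, nodes, targets=("h",)),
                             make_net([], nodes, "B", targets=("h",)))
        table = target_subnetwork_degrees(cmp, {n: n == "h" for n in nodes})
        assert table.loc["A", "target_edges"] == 4
        assert table.loc["A", "nontarget_edges"] == 4  # each spoke touches a nontarget too

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(14)
        nodes = [f"n{i}" for i in range(10)]
        all_pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        idx = rng.choice(len(all_pairs), size=15, replace=False)
        pairs = [all_pairs[i] for i in idx]
        flags = {n: bool(rng.integers(2)) for n in nodes}
        cmp = classify_edges(make_net(pairs, nodes), make_net(pairs[:5], nodes, "B"))
        table = target_subnetwork_degrees(cmp, flags)
        brute_t = sum(flags[a] or flags[b] for a, b in pairs)
        brute_nt = sum((not flags[a]) or (not flags[b]) for a, b in pairs)
        assert table.loc["A", "target_edges"] == brute_t
        assert table.loc["A", "nontarget_edges"] == brute_nt


class TestEdgeCvGain:
    def _noise_cmp(self, panel, n_cells=60, seeds=(41, 42)):
        m = concat_conditions([
            simulate_expression_matrix(panel, n_cells, c, seed=s)
            for c, s in zip(("A", "B"), seeds)
        ])
        return m, compare_noise(m, "A", "B")

    def test_mean_mode_arithmetic(self):
        nodes = ["g1", "g2", "g3"]
        cmp = classify_edges(
            make_net([("g1", "g2")], nodes), make_net([("g1", "g2")], nodes, "B")
        )
        per_gene = pd.DataFrame({"cv_gain": [0.2, 0.4, 0.0]}, index=nodes)
        noise = _FakeNoise(per_gene)
        out = edge_cv_gain_comparison(cmp, noise, mode="mean")
        assert out.gains["common"][0] == pytest.approx(0.3)

    def test_partner_mode_uses_non_center_endpoint(self):
        nodes = ["hub", "g2", "g3"]
        cmp = classify_edges(
            make_net([("hub", "g2")], nodes), make_net([("hub", "g3")], nodes, "B")
        )
        per_gene = pd.DataFrame({"cv_gain": [9.9, 0.25, 0.75]}, index=nodes)
        out = edge_cv_gain_comparison(cmp, _FakeNoise(per_gene), mode="partner",
                                      centers={"hub"})
        assert out.gains["only_a"][0] == pytest.approx(0.25)
        assert out.gains["only_b"][0] == pytest.approx(0.75)

    def test_all_equal_gains_null_result(self):
        nodes = [f"g{i}" for i in range(6)]
        pairs_a = [("g0", "g1"), ("g2", "g3"), ("g0", "g2"), ("g1", "g3")]
        pairs_b = pairs_a[:2] + [("g4", "g5"), ("g0", "g4")]
        cmp = classify_edges(make_net(pairs_a, nodes), make_net(pairs_b, nodes, "B"))
        per_gene = pd.DataFrame({"cv_gain": [0.3] * 6}, index=nodes)
        out = edge_cv_gain_comparison(cmp, _FakeNoise(per_gene), mode="mean")
        row = out.tests.set_index(["class_a", "class_b"]).loc[("only_b", "common")]
        assert row["mean_diff"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_inflated_partner_genes_raise_only_b_gain(self):
        """B-unique edges recruiting CV-inflated genes show a higher mean
        gain than common edges."""
        panel = make_panel(n_genes=20, cv_inflation_alt=1.0, p_detect=1.0, seed=15)
        # inflate a subset of genes in condition B only
        inflated = [f"g{i}" for i in range(11, 21)]
        panel.genes.loc[inflated, "sd"] *= 1.0  # base sd; inflation via condition factor
        m_a = simulate_expression_matrix(panel, 200, "A", seed=16)
        panel_b = make_panel(n_genes=20, cv_inflation_alt=1.0, p_detect=1.0, seed=15)
        panel_b.genes.loc[inflated, "sd"] *= 1.6
        m_b = simulate_expression_matrix(panel_b, 200, "B", seed=17)
        m = concat_conditions([m_a, m_b])
        noise = compare_noise(m, "A", "B")
        nodes = list(panel.genes.index)
        quiet = [f"g{i}" for i in range(1, 11)]
        common_pairs = [("g1", q) for q in quiet[1:6]]
        only_b_pairs = [("g1", g) for g in inflated[:5]]
        cmp = classify_edges(
            make_net(common_pairs, nodes),
            make_net(common_pairs + only_b_pairs, nodes, "B"),
        )
        out = edge_cv_gain_comparison(cmp, noise, mode="partner", centers={"g1"})
        row = out.tests.set_index(["class_a", "class_b"]).loc[("only_b", "common")]
        assert row["mean_diff"] > 0
        assert row["p"] < 0.05

    def test_small_class_skipped(self):
        nodes = ["g1", "g2", "g3"]
        cmp = classify_edges(make_net([("g1", "g2")], nodes), make_net([], nodes, "B"))
        per_gene = pd.DataFrame({"cv_gain": [0.1, 0.2, 0.3]}, index=nodes)
        out = edge_cv_gain_comparison(cmp, _FakeNoise(per_gene), mode="mean")
        assert out.tests["skipped"].all()


class _FakeNoise:
    """Minimal stand-in carrying only the per-gene CV gains (synthetic)."""

    def __init__(self, per_gene):
        self.per_gene = per_gene
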