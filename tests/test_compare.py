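"""Topological overlap, rewiring null and differential connectivity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import net_from_edges, random_network
from coexdiff.compare import (
    connectivity_difference,
    cross_level_intersection,
    rewire,
    select_low_to,
    selected_counts,
    to_significance,
    topological_overlap,
)
from coexdiff.network import CoexpressionNetwork


def to_oracle(net1, net2):
    """Set-based per-gene TO (independent of the vectorised path)."""
    out = {}
    for g in net1.nodes:
        X, Y = net1.neighbours(g), net2.neighbours(g)
        denom = max(len(X), len(Y))
        out[g] = len(X & Y) / denom if denom else np.nan
    return out


class TestTopologicalOverlap:
    def test_identical_networks_give_to_1(self):
        net = random_network(12, 0.4, 3)
        tab = topological_overlap(net, net)
        assert (tab["to"].dropna() == 1.0).all()

    def test_disjoint_neighbourhoods_give_to_0(self):
        nodes = list("xabcd")
        net1 = net_from_edges(nodes, [("x", "a"), ("x", "b"), ("a", "b"), ("c", "d")])
        net2 = net_from_edges(nodes, [("x", "c"), ("x", "d"), ("c", "d"), ("a", "b")])
        tab = topological_overlap(net1, net2)
        assert tab.loc["x", "to"] == 0.0

    def test_partial_overlap_hand_value(self):
        # X = {a,b,c}, Y = {b,c,d,e}: TO = 2 / max(3,4) = 0.5
        nodes = list("xabcde")
        net1 = net_from_edges(nodes, [("x", "a"), ("x", "b"), ("x", "c"), ("d", "e")])
        net2 = net_from_edges(
            nodes, [("x", "b"), ("x", "c"), ("x", "d"), ("x", "e"), ("a", "b")]
        )
        tab = topological_overlap(net1, net2)
        assert tab.loc["x", "to"] == pytest.approx(0.5)
        assert tab.loc["x", "d1"] == 3
        assert tab.loc["x", "d2"] == 4

    def test_node_set_mismatch_is_an_error(self):
        net1 = net_from_edges(["a", "b"], [("a", "b")])
        net2 = net_from_edges(["a", "c"], [("a", "c")])
        with pytest.raises(ValueError):
            topological_overlap(net1, net2)

    def test_node_order_is_aligned(self):
        net1 = random_network(8, 0.5, 1)
        perm = list(reversed(net1.nodes))
        tab1 = topological_overlap(net1, net1.reordered(perm))
        assert (tab1["to"].dropna() == 1.0).all()

    def test_isolated_node_reported_missing(self):
        nodes = ["a", "b", "c"]
        net1 = net_from_edges(nodes, [("a", "b")])
        net2 = net_from_edges(nodes, [("a", "b")])
        with pytest.warns(UserWarning, match="isolated"):
            tab = topological_overlap(net1, net2)
        assert np.isnan(tab.loc["c", "to"])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_set_oracle_and_symmetry(self, seed):
        net1 = random_network(100, 0.05, seed)
        net2 = random_network(100, 0.05, seed + 100)
        tab = topological_overlap(net1, net2)
        oracle = to_oracle(net1, net2)
        for g in net1.nodes:
            if np.isnan(oracle[g]):
                assert np.isnan(tab.loc[g, "to"])
            else:
                assert tab.loc[g, "to"] == pytest.approx(oracle[g])
        flipped = topological_overlap(net2, net1)
        pd.testing.assert_series_equal(tab["to"], flipped["to"])

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_bounds_and_identity_property(self, seed):
        net1 = random_network(30, 0.2, seed)
        net2 = random_network(30, 0.2, seed + 1)
        tab = topological_overlap(net1, net2).dropna()
        assert ((tab["to"] >= 0) & (tab["to"] <= 1)).all()
        for g in tab.index:
            if tab.loc[g, "to"] == 1.0:
                assert net1.neighbours(g) == net2.neighbours(g)


class TestSelectLowTo:
    def _table(self, values):
        return pd.DataFrame({"to": values}, index=[f"g{i}" for i in range(len(values))])

    def test_all_high_empty(self):
        genes, pct = select_low_to(self._table([1.0] * 5))
        assert genes == set() and pct == 0.0

    def test_threshold_inclusive_and_fraction(self):
        # 31 low-TO genes among 503 -> 6.2%
        values = [0.05] * 31 + [0.5] * (503 - 31)
        genes, pct = select_low_to(self._table(values), 0.1)
        assert len(genes) == 31
        assert pct == 6.2
        genes_inc, _ = select_low_to(self._table([0.1, 0.2]), 0.1)
        assert len(genes_inc) == 1  # boundary value selected

    def test_threshold_one_selects_all(self):
        genes, pct = select_low_to(self._table([0.3, 0.9, 1.0]), 1.0)
        assert len(genes) == 3 and pct == 100.0


class TestRewire:
    def test_degree_sequence_preserved(self):
        net = random_network(30, 0.15, 2)
        out = rewire(net, seed=0)
        np.testing.assert_array_equal(out.degrees, net.degrees)
        assert out.n_edges == net.n_edges
        assert not np.diag(out.adjacency).any()
        assert (out.adjacency == out.adjacency.T).all()

    def test_four_cycle_stays_two_regular(self):
        # all 2-regular simple graphs on 4 labelled nodes are the three 4-cycles
        nodes = list("abcd")
        cycles = []
        for perm in itertools.permutations(nodes[1:]):
            cyc = [nodes[0], *perm]
            edges = frozenset(
                frozenset((cyc[i], cyc[(i + 1) % 4])) for i in range(4)
            )
            cycles.append(edges)
        valid = set(cycles)
        assert len(valid) == 3
        net = net_from_edges(nodes, [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        for seed in range(5):
            out = rewire(net, seed=seed)
            got = frozenset(
                frozenset((out.nodes[i], out.nodes[j])) for i, j in out.edge_array()
            )
            assert got in valid

    def test_seeds_change_edges_not_degrees(self):
        net = random_network(25, 0.2, 4)
        a = rewire(net, seed=1)
        b = rewire(net, seed=2)
        np.testing.assert_array_equal(a.degrees, b.degrees)
        assert (a.adjacency != b.adjacency).any()
        again = rewire(net, seed=1)
        np.testing.assert_array_equal(a.adjacency, again.adjacency)

    def test_unswappable_network_warns_and_returns_unchanged(self):
        # a triangle admits no degree-preserving swap
        net = net_from_edges(list("abc"), [("a", "b"), ("b", "c"), ("a", "c")])
        with pytest.warns(UserWarning, match="no valid"):
            out = rewire(net, seed=0)
        np.testing.assert_array_equal(out.adjacency, net.adjacency)

    def test_too_few_edges_rejected(self):
        net = net_from_edges(["a", "b"], [("a", "b")])
        with pytest.raises(ValueError):
            rewire(net, seed=0)


class TestToSignificance:
    def test_pvalue_sign_follows_discrepancy(self):
        # the statistic contrasts observed TO with the null mean: genes whose
        # observed TO sits below the null mean must get p < 0.5 and vice versa
        # (p = 0.5 exactly at the null mean)
        net1 = random_network(40, 0.12, 8)
        net2 = rewire(net1, seed=99)
        tab = to_significance(net1, net2, n_random=100, seed=0).dropna(subset=["t"])
        below = tab["to"] < tab["null_mean"]
        above = tab["to"] > tab["null_mean"]
        assert (tab.loc[below, "p"] < 0.5).all()
        assert (tab.loc[above, "p"] > 0.5).all()

    def test_identical_networks_not_flagged_low(self):
        net = random_network(30, 0.15, 5)
        tab = to_significance(net, net, n_random=50, seed=1)
        # observed TO = 1 for every gene: never significantly *lower* than null
        assert not tab["significant"].any()

    def test_monte_carlo_stability(self):
        net1 = random_network(30, 0.15, 6)
        net2 = random_network(30, 0.15, 7)
        t1 = to_significance(net1, net2, n_random=100, seed=3)
        t2 = to_significance(net1, net2, n_random=200, seed=4)
        assert (t1["null_mean"] - t2["null_mean"]).abs().mean() < 0.05

    def test_input_validation(self):
        net = random_network(10, 0.3, 0)
        with pytest.raises(ValueError):
            to_significance(net, net, n_random=1)
        with pytest.raises(ValueError):
            to_significance(net, net, n_random=10, randomize="nope")


class TestConnectivityDifference:
    def test_identical_networks_nothing_selected(self):
        net = random_network(20, 0.3, 1)
        conn = connectivity_difference(net, net, T=1)
        assert not conn["selected"].any()
        assert (conn["direction"] == "equal").all()

    def test_hub_difference_selected_with_direction(self):
        nodes = [f"g{i}" for i in range(16)]
        hub1 = [("g0", n) for n in nodes[1:16]]          # degree 15 in net1
        hub2 = [("g0", n) for n in nodes[1:5]]           # degree 4 in net2
        net1 = net_from_edges(nodes, hub1)
        net2 = net_from_edges(nodes, hub2)
        conn = connectivity_difference(net1, net2, T=10)
        assert conn.loc["g0", "diff"] == 11
        assert conn.loc["g0", "selected"]
        assert conn.loc["g0", "direction"] == "net1"

    def test_directional_counts_sum_to_total(self):
        net1 = random_network(60, 0.3, 10)
        net2 = random_network(60, 0.1, 11)
        conn = connectivity_difference(net1, net2, T=5)
        counts = selected_counts(conn)
        assert counts["total"] == counts["higher_in_net1"] + counts["higher_in_net2"]
        assert counts["total"] == int(conn["selected"].sum())

    def test_antisymmetry_under_swap(self):
        net1 = random_network(30, 0.3, 12)
        net2 = random_network(30, 0.15, 13)
        fwd = connectivity_difference(net1, net2, T=3)
        rev = connectivity_difference(net2, net1, T=3)
        np.testing.assert_array_equal(fwd["diff"], rev["diff"])
        swap = {"net1": "net2", "net2": "net1", "equal": "equal"}
        assert (fwd["direction"].map(swap) == rev["direction"]).all()

    def test_subset_nodes_within_supergraphs(self):
        net1 = random_network(20, 0.3, 14)
        net2 = random_network(20, 0.3, 15)
        sub = net1.nodes[:5]
        conn = connectivity_difference(net1, net2, T=2, nodes=sub)
        assert list(conn.index) == sub
        with pytest.raises(ValueError):
            connectivity_difference(net1, net2, T=2, nodes=["missing"])

    def test_node_mismatch_rejected(self):
        net1 = net_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])
        net2 = net_from_edges(["a", "b", "d"], [("a", "b"), ("b", "d")])
        with pytest.raises(ValueError):
            connectivity_difference(net1, net2)


class TestCrossLevelIntersection:
    def test_examples(self):
        assert cross_level_intersection({"a"}, {"b"}) == set()
        assert cross_level_intersection(set(), {"a", "b"}) == set()
        assert cross_level_intersection({"a", "b", "c"}, {"b", "c", "d"}) == {"b", "c"}
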