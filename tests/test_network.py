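"""Pairwise correlation, rank lists and the two-condition linking rule."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_corr
from coexdiff.network import (
    CoexpressionNetwork,
    NetworkParams,
    build_network,
    components,
    pairwise_pcc,
    rank_neighbours,
)


def corr_frame(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [chr(ord("A") + i) for i in range(len(values))]
    return pd.DataFrame(values, index=names, columns=names)


def brute_force_edges(corr: pd.DataFrame, params: NetworkParams) -> set:
    """Literal double-loop implementation of the linking rule (oracle)."""
    C = corr.to_numpy()
    if params.absolute:
        C = np.abs(C)
    m = len(C)
    tops = []
    for i in range(m):
        others = [j for j in range(m) if j != i]
        tops.append(sorted(others, key=lambda j: (-C[i, j], j)))
    edges = set()
    for i in range(m):
        for j in range(i + 1, m):
            c = C[i, j]
            cond1 = c >= params.t_low and (
                j in tops[i][: params.k_low] or i in tops[j][: params.k_low]
            )
            cond2 = c >= params.t_high and (
                j in tops[i][: params.k_high] or i in tops[j][: params.k_high]
            )
            if cond1 or cond2:
                edges.add((i, j))
    return edges


def network_edges(net: CoexpressionNetwork) -> set:
    return {tuple(e) for e in net.edge_array()}


class TestPairwisePcc:
    def test_duplicate_and_negated_profiles(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0, 5.0], [1.0, 2.0, 3.0, 5.0], [-1.0, -2.0, -3.0, -5.0]],
            index=["a", "a_copy", "neg"],
            columns=list("wxyz"),
        )
        corr = pairwise_pcc(m)
        assert corr.loc["a", "a_copy"] == pytest.approx(1.0)
        assert corr.loc["a", "neg"] == pytest.approx(-1.0)

    def test_three_gene_toy_matches_hand_pcc(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0], [4.0, 3.0, 2.0, 1.0]],
            index=["a", "b", "c"],
            columns=list("wxyz"),
        )
        corr = pairwise_pcc(m)

        def hand_pcc(x, y):
            x, y = np.asarray(x), np.asarray(y)
            xc, yc = x - x.mean(), y - y.mean()
            return (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())

        assert corr.loc["a", "b"] == pytest.approx(hand_pcc(m.loc["a"], m.loc["b"]))
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_zero_variance_gene_dropped_with_warning(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0], [2.0, 1.0, 4.0, 3.0]],
            index=["a", "flat", "b"],
            columns=list("wxyz"),
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = pairwise_pcc(m)
        assert list(corr.index) == ["a", "b"]

    def test_sample_count_preconditions(self):
        m = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], columns=["x", "y"])
        with pytest.raises(ValueError):
            pairwise_pcc(m)
        m4 = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 3)))
        with pytest.warns(UserWarning, match="noisy"):
            pairwise_pcc(m4)


class TestRankNeighbours:
    def test_descending_order(self):
        corr = corr_frame(
            [[1.0, 0.9, 0.5, 0.1],
             [0.9, 1.0, 0.2, 0.0],
             [0.5, 0.2, 1.0, 0.3],
             [0.1, 0.0, 0.3, 1.0]]
        )
        assert rank_neighbours(corr, "A") == ["B", "C", "D"]

    def test_ties_break_by_index(self):
        corr = corr_frame(
            [[1.0, 0.5, 0.5, 0.5],
             [0.5, 1.0, 0.5, 0.5],
             [0.5, 0.5, 1.0, 0.5],
             [0.5, 0.5, 0.5, 1.0]]
        )
        assert rank_neighbours(corr, "C") == ["A", "B", "D"]

    def test_negative_ranks_below_positive(self):
        corr = corr_frame(
            [[1.0, -0.9, 0.1, 0.95],
             [-0.9, 1.0, 0.0, 0.0],
             [0.1, 0.0, 1.0, 0.0],
             [0.95, 0.0, 0.0, 1.0]]
        )
        assert rank_neighbours(corr, "A") == ["D", "C", "B"]


class TestLinkingRule:
    def _toy(self, c_ab, c_ac, c_ad, background=0.1):
        C = np.full((4, 4), background)
        np.fill_diagonal(C, 1.0)
        for j, c in zip([1, 2, 3], [c_ab, c_ac, c_ad]):
            C[0, j] = C[j, 0] = c
        return corr_frame(C)

    def test_three_candidates_above_cutoff_all_link(self):
        # candidates at 0.3, 0.32, 0.4 in gene A's top-3: all three link
        net = build_network(self._toy(0.3, 0.32, 0.4))
        assert net.neighbours("A") == {"B", "C", "D"}

    def test_candidates_below_cutoff_do_not_link(self):
        # candidates at 0.3, 0.28, 0.29: only the 0.3 gene links to A
        net = build_network(self._toy(0.3, 0.28, 0.29))
        assert net.neighbours("A") == {"B"}

    def test_high_correlation_outside_top3_links_via_condition_2(self):
        # A and E correlate at 0.95 but each has three closer partners, so
        # neither is in the other's top-3: the A-E link needs condition (2)
        C = np.full((6, 6), 0.0)
        np.fill_diagonal(C, 1.0)
        names = list("ABCDEF")
        for j, c in zip([1, 2, 3], [0.97, 0.96, 0.96]):  # A's top-3: B, C, D
            C[0, j] = C[j, 0] = c
        for j, c in zip([5, 1, 2], [0.98, 0.97, 0.96]):  # E's top-3: F, B, C
            C[4, j] = C[j, 4] = c
        C[0, 4] = C[4, 0] = 0.95
        corr = corr_frame(C, names)
        net = build_network(corr)
        assert "E" in net.neighbours("A")
        strict = build_network(corr, NetworkParams(t_high=0.96))
        assert "E" not in strict.neighbours("A")
        assert brute_force_edges(corr, NetworkParams()) == network_edges(net)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("n_genes", [10, 40, 60])
    def test_matches_brute_force_oracle(self, seed, n_genes):
        corr = random_corr(n_genes, 6, seed)
        for params in [
            NetworkParams(),
            NetworkParams(t_low=0.2, k_low=2, t_high=0.8, k_high=5),
            NetworkParams(absolute=True),
        ]:
            net = build_network(corr, params)
            assert network_edges(net) == brute_force_edges(corr, params)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_raising_t_high_only_removes_edges(self, seed):
        corr = random_corr(30, 5, seed)
        loose = network_edges(build_network(corr, NetworkParams(t_high=0.7)))
        tight = network_edges(build_network(corr, NetworkParams(t_high=0.95)))
        assert tight <= loose

    def test_min_degree_when_top3_clear_cutoff(self):
        for seed in range(5):
            corr = random_corr(40, 4, seed)  # few samples -> high correlations
            net = build_network(corr)
            C = corr.to_numpy().copy()
            np.fill_diagonal(C, -np.inf)
            third_best = np.sort(C, axis=1)[:, -3]
            degrees = net.degrees.to_numpy()
            assert (degrees[third_best >= 0.3] >= 3).all()

    def test_adjacency_symmetric_zero_diagonal(self):
        net = build_network(random_corr(25, 6, 9))
        A = net.adjacency
        assert (A == A.T).all()
        assert not np.diag(A).any()


class TestNetworkContainer:
    def test_invalid_adjacency_rejected(self):
        A = np.zeros((2, 2), dtype=bool)
        A[0, 1] = True  # asymmetric
        with pytest.raises(ValueError):
            CoexpressionNetwork(["a", "b"], A)
        B = np.eye(2, dtype=bool)
        with pytest.raises(ValueError):
            CoexpressionNetwork(["a", "b"], B)

    def test_degrees_are_row_sums(self):
        from conftest import random_network

        net = random_network(15, 0.3, 0)
        np.testing.assert_array_equal(
            net.degrees.to_numpy(), net.adjacency.sum(axis=1)
        )
        assert net.n_edges == net.degrees.sum() // 2


class TestComponents:
    def test_complete_graph_single_component(self):
        A = ~np.eye(4, dtype=bool)
        n, sizes = components(CoexpressionNetwork(list("abcd"), A))
        assert (n, sizes) == (1, [4])

    def test_two_disjoint_triangles(self):
        from conftest import net_from_edges

        net = net_from_edges(
            list("abcdef"),
            [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")],
        )
        n, sizes = components(net)
        assert (n, sizes) == (2, [3, 3])
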