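"""Rank/threshold gene coexpression network construction.

Two genes are linked iff at least one of two conditions holds on their
Pearson correlation r and mutual rank positions:

(1) r >= t_low (0.3) and either gene ranks within the other's top k_low (3)
    most-correlated genes;
(2) r >= t_high (0.9) and either gene ranks within the other's top
    k_high (50).

Condition (1) guarantees sparse connectivity for every gene whose top
correlations clear the low cutoff (minimum degree k_low in practice);
condition (2) admits strongly coexpressed pairs beyond the top-3.  The
result is a binary, symmetric, zero-diagonal adjacency matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class NetworkParams:
    """Linking-rule parameters.

    ``absolute=True`` ranks and thresholds on |r| instead of signed r.
    """

    t_low: float = 0.3
    k_low: int = 3
    t_high: float = 0.9
    k_high: int = 50
    absolute: bool = False

    def __post_init__(self):
        if not 0 <= self.t_low <= self.t_high <= 1:
            raise ValueError("need 0 <= t_low <= t_high <= 1")
        if not 1 <= self.k_low <= self.k_high:
            raise ValueError("need 1 <= k_low <= k_high")


@dataclass
class CoexpressionNetwork:
    """Binary undirected network over an ordered gene list."""

    nodes: list
    adjacency: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=bool)
        if A.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node count")
        if np.any(A != A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A)):
            raise ValueError("self-edges are not allowed")
        self.adjacency = A
        self.nodes = list(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def degrees(self) -> pd.Series:
        return pd.Series(self.adjacency.sum(axis=1), index=self.nodes, name="degree")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_array(self) -> np.ndarray:
        """(E, 2) array of node indices i < j for every edge."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu, ju]
        return np.column_stack([iu[mask], ju[mask]])

    def neighbours(self, gene) -> set:
        i = self.nodes.index(gene)
        return {self.nodes[j] for j in np.flatnonzero(self.adjacency[i])}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for i, j in self.edge_array():
            g.add_edge(self.nodes[i], self.nodes[j])
        return g

    def reordered(self, nodes) -> "CoexpressionNetwork":
        """Same network with rows/columns permuted to the given node order."""
        if set(nodes) != set(self.nodes):
            raise ValueError("node sets differ")
        pos = {n: i for i, n in enumerate(self.nodes)}
        idx = np.array([pos[n] for n in nodes])
        return CoexpressionNetwork(list(nodes), self.adjacency[np.ix_(idx, idx)])


def pairwise_pcc(matrix: pd.DataFrame) -> pd.DataFrame:
    """Gene-by-gene Pearson correlation over the selected samples.

    Zero-variance genes cannot be correlated and are dropped with a warning
    before ranks are computed.  Fewer than 4 samples triggers a noisiness
    warning (dose-specific networks in the reference design rest on 4
    columns); fewer than 3 is an error.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples for meaningful correlations")
    if matrix.shape[1] < 4:
        warnings.warn("correlations from < 4 samples are extremely noisy")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if np.any(sd == 0):
        dropped = list(matrix.index[sd == 0])
        warnings.warn(f"dropping {len(dropped)} zero-variance genes: {dropped[:5]}")
        matrix = matrix.loc[sd > 0]
        values = values[sd > 0]
    corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.index, columns=matrix.index)


def rank_neighbours(corr: pd.DataFrame, gene) -> list:
    """All other genes in descending-correlation order from ``gene``.

    Ties are broken by ascending position in the correlation matrix so the
    ordering is total and reproducible.
    """
    i = corr.index.get_loc(gene)
    row = corr.to_numpy()[i].copy()
    order = _rank_order(row, i)
    return [corr.index[j] for j in order]


def _rank_order(row: np.ndarray, self_idx: int) -> np.ndarray:
    """Indices of all genes but ``self_idx``, sorted desc by row value then asc index."""
    order = np.argsort(-row, kind="stable")
    return order[order != self_idx]


def build_network(
    corr: pd.DataFrame, params: NetworkParams | None = None
) -> CoexpressionNetwork:
    """Apply the two-condition linking rule to a correlation matrix.

    Thresholds are inclusive (r >= t), matching the worked behaviour of the
    rule where a candidate at exactly the low cutoff still links.  "Top k of
    the other" is satisfied in either direction (the graph is undirected).
    """
    params = params or NetworkParams()
    C = corr.to_numpy(dtype=float).copy()
    if params.absolute:
        C = np.abs(C)
    m = C.shape[0]
    ranked = C.copy()
    np.fill_diagonal(ranked, -np.inf)  # self never ranks

    # rank_pos[i, j] = position of j in i's descending-correlation list
    order = np.argsort(-ranked, axis=1, kind="stable")
    rank_pos = np.empty_like(order)
    rows = np.arange(m)[:, None]
    rank_pos[rows, order] = np.arange(m)[None, :]

    in_top_low = rank_pos < params.k_low
    in_top_high = rank_pos < params.k_high
    cond1 = (ranked >= params.t_low) & (in_top_low | in_top_low.T)
    cond2 = (ranked >= params.t_high) & (in_top_high | in_top_high.T)
    A = cond1 | cond2
    np.fill_diagonal(A, False)
    return CoexpressionNetwork(list(corr.index), A)


def components(network: CoexpressionNetwork) -> tuple[int, list[int]]:
    """Connected components: (count, sizes in descending order).

    The rule aims for a single connected network but does not enforce it;
    this reports what was actually built.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    comps = list(nx.connected_components(network.to_networkx()))
    sizes = sorted((len(c) for c in comps), reverse=True)
    return len(comps), sizes
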