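"""Cross-network topology: topological overlap, rewiring null, connectivity.

For a gene i present in two networks over the same node set, with neighbour
sets X (network 1) and Y (network 2) and degrees d1, d2:

    TO(i) = |X ∩ Y| / max(d1, d2)   in [0, 1].

TO = 1 iff the neighbourhoods coincide; low TO marks genes whose local
wiring differs between conditions.  Significance of a low observed TO is
assessed against a null of degree-preserving random rewiring (double-edge
swaps): both networks are rewired n_random times, each gene's null TO mean
and SD are accumulated, and a one-sided t-statistic asks whether the
observed TO is lower than expected for a gene of those degrees.

Differential connectivity is the complementary view: |d1 - d2| >= T (default
10 links) marks a gene as strongly re-connected, partitioned by which
network holds the higher degree.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from coexdiff.network import CoexpressionNetwork


def _aligned(net1: CoexpressionNetwork, net2: CoexpressionNetwork):
    if set(net1.nodes) != set(net2.nodes):
        raise ValueError("networks must share an identical node set")
    if net2.nodes != net1.nodes:
        net2 = net2.reordered(net1.nodes)
    return net1, net2


def topological_overlap(
    net1: CoexpressionNetwork, net2: CoexpressionNetwork
) -> pd.DataFrame:
    """Per-gene cross-network topological overlap.

    Returns a gene-indexed table with d1, d2, n_shared (|X∩Y|) and ``to``.
    A gene isolated in both networks has no defined TO and is reported as
    NaN with a warning.
    """
    net1, net2 = _aligned(net1, net2)
    A1, A2 = net1.adjacency, net2.adjacency
    d1 = A1.sum(axis=1)
    d2 = A2.sum(axis=1)
    shared = (A1 & A2).sum(axis=1)
    denom = np.maximum(d1, d2)
    to = np.full(len(denom), np.nan)
    ok = denom > 0
    to[ok] = shared[ok] / denom[ok]
    if np.any(~ok):
        warnings.warn(
            f"{int((~ok).sum())} genes isolated in both networks: TO undefined"
        )
    return pd.DataFrame(
        {"d1": d1, "d2": d2, "n_shared": shared, "to": to}, index=net1.nodes
    )


def select_low_to(
    to_table: pd.DataFrame, threshold: float = 0.1
) -> tuple[set, float]:
    """Genes with TO <= threshold (inclusive) and the fraction they make up.

    Returns (gene set, percentage of the network's genes, one decimal).
    NaN TO values never select.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    mask = to_table["to"] <= threshold
    genes = set(to_table.index[mask.fillna(False)])
    pct = round(100.0 * len(genes) / len(to_table), 1) if len(to_table) else 0.0
    return genes, pct


def rewire(
    network: CoexpressionNetwork,
    n_swap_attempts: int | None = None,
    seed=None,
) -> CoexpressionNetwork:
    """Degree-preserving randomisation by double-edge swaps.

    Repeatedly picks two edges (a,b), (c,d) and rewires them to (a,d), (c,b)
    when that creates neither self-edges nor multi-edges; every node's
    degree is invariant.  Defaults to 10x the edge count attempted swaps.
    ``seed`` may be an int or a numpy Generator.
    """
    edges = network.edge_array()
    n_edges = len(edges)
    if n_edges < 2:
        raise ValueError("rewiring needs >= 2 edges")
    attempts = 10 * n_edges if n_swap_attempts is None else int(n_swap_attempts)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    A = network.adjacency.copy()
    edges = edges.copy()
    pairs = rng.integers(0, n_edges, size=(attempts, 2))
    flips = rng.integers(0, 2, size=attempts)
    n_success = 0
    for k in range(attempts):
        i, j = pairs[k]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flips[k]:
            c, d = d, c
        if a == d or c == b or a == c or b == d:
            continue
        if A[a, d] or A[c, b]:
            continue
        A[a, b] = A[b, a] = False
        A[c, d] = A[d, c] = False
        A[a, d] = A[d, a] = True
        A[c, b] = A[b, c] = True
        edges[i] = (a, d) if a < d else (d, a)
        edges[j] = (c, b) if c < b else (b, c)
        n_success += 1
    if n_success == 0:
        warnings.warn("no valid degree-preserving swap found; network unchanged")
    return CoexpressionNetwork(list(network.nodes), A)


def to_significance(
    net1: CoexpressionNetwork,
    net2: CoexpressionNetwork,
    n_random: int = 1000,
    seed=None,
    randomize: str = "both",
    alternative: str = "less",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Topological overlap with a degree-preserving rewiring null.

    Rewires the networks ``n_random`` times (``randomize``: "both", "net1"
    or "net2") and, per gene, forms a one-sample t-statistic

        t = (null mean - observed TO) / (null SD / sqrt(n_random)),

    with a one-sided p-value for the observed TO being *lower* than the
    null ("less", the default; "greater" flips the sign).  Genes with
    p < alpha are flagged significant.  Zero null SD is degenerate: p is
    forced to 0 or 1 by the sign of the discrepancy (0.5 on a tie) and the
    gene is flagged in the ``degenerate`` column.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    if randomize not in {"both", "net1", "net2"}:
        raise ValueError("randomize must be 'both', 'net1' or 'net2'")
    net1, net2 = _aligned(net1, net2)
    obs = topological_overlap(net1, net2)

    ss = np.random.SeedSequence(seed)
    rng1, rng2 = [np.random.default_rng(c) for c in ss.spawn(2)]
    d1 = net1.adjacency.sum(axis=1)
    d2 = net2.adjacency.sum(axis=1)
    denom = np.maximum(d1, d2).astype(float)
    denom[denom == 0] = np.nan

    null_to = np.empty((n_random, net1.n_nodes))
    for r in range(n_random):
        r1 = rewire(net1, seed=rng1) if randomize in {"both", "net1"} else net1
        r2 = rewire(net2, seed=rng2) if randomize in {"both", "net2"} else net2
        null_to[r] = (r1.adjacency & r2.adjacency).sum(axis=1) / denom

    null_mean = null_to.mean(axis=0)
    null_sd = null_to.std(axis=0, ddof=1)
    diff = null_mean - obs["to"].to_numpy()
    if alternative == "greater":
        diff = -diff
    elif alternative != "less":
        raise ValueError("alternative must be 'less' or 'greater'")

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / (null_sd / np.sqrt(n_random))
    p = stats.t.sf(t, df=n_random - 1)
    degenerate = null_sd == 0
    p[degenerate & (diff > 0)] = 0.0
    p[degenerate & (diff < 0)] = 1.0
    p[degenerate & (diff == 0)] = 0.5
    t[degenerate] = np.nan

    out = obs.copy()
    out["null_mean"] = null_mean
    out["null_sd"] = null_sd
    out["t"] = t
    out["p"] = p
    out["significant"] = p < alpha
    out["degenerate"] = degenerate
    return out


def connectivity_difference(
    net1: CoexpressionNetwork,
    net2: CoexpressionNetwork,
    T: int = 10,
    nodes=None,
) -> pd.DataFrame:
    """Per-gene cross-network degree difference, selected at |d1-d2| >= T.

    With ``nodes`` given, both networks may be larger supergraphs (e.g. the
    all-DE-gene networks) and only those genes are reported, with degrees
    taken within each full network.  Otherwise the node sets must match.
    Returns a gene-indexed table: d1, d2, diff, direction
    ("net1" / "net2" / "equal"), selected.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if nodes is None:
        net1, net2 = _aligned(net1, net2)
        nodes = net1.nodes
        d1 = pd.Series(net1.adjacency.sum(axis=1), index=net1.nodes)
        d2 = pd.Series(net2.adjacency.sum(axis=1), index=net2.nodes)
    else:
        nodes = list(nodes)
        missing = (set(nodes) - set(net1.nodes)) | (set(nodes) - set(net2.nodes))
        if missing:
            raise ValueError(f"genes absent from a network: {sorted(missing)[:5]}")
        d1 = net1.degrees
        d2 = net2.degrees
    d1 = d1.loc[nodes].to_numpy()
    d2 = d2.loc[nodes].to_numpy()
    diff = np.abs(d1 - d2)
    direction = np.where(d1 > d2, "net1", np.where(d2 > d1, "net2", "equal"))
    return pd.DataFrame(
        {
            "d1": d1,
            "d2": d2,
            "diff": diff,
            "direction": direction,
            "selected": diff >= T,
        },
        index=nodes,
    )


def selected_counts(conn: pd.DataFrame) -> dict:
    """Directional tally of selected genes: total = higher-in-net1 + higher-in-net2."""
    sel = conn[conn["selected"]]
    return {
        "total": int(len(sel)),
        "higher_in_net1": int((sel["direction"] == "net1").sum()),
        "higher_in_net2": int((sel["direction"] == "net2").sum()),
    }


def cross_level_intersection(diff_all_genes: set, diff_common_genes: set) -> set:
    """Genes exceeding the connectivity threshold at both network levels.

    Intersection of the selected sets from the all-DE-gene networks and the
    common-gene networks at the same time point.
    """
    return set(diff_all_genes) & set(diff_common_genes)
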