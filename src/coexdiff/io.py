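"""Tab-delimited and JSON readers/writers shared across the pipeline.

All matrices travel as TSV with probes as rows (index column ``probe_id``)
and sample ids as the header row; gene sets as one id per line; networks as
edge lists.  Floats are written with repr-level precision so a re-run with
the same config reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from coexdiff.network import CoexpressionNetwork

FLOAT_FMT = "%.10g"


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id", float_format=FLOAT_FMT)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_table(table: pd.DataFrame, path, index_label="gene") -> None:
    table.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def write_gene_set(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_set(path) -> set:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_network(net: CoexpressionNetwork, path, corr: pd.DataFrame | None = None) -> None:
    """Edge list (gene_a, gene_b, pcc) plus a sibling .nodes file."""
    rows = []
    for i, j in net.edge_array():
        a, b = net.nodes[i], net.nodes[j]
        pcc = float(corr.loc[a, b]) if corr is not None else float("nan")
        rows.append((a, b, pcc))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc"])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    write_gene_set(net.nodes, str(path) + ".nodes")


def read_network(path, nodes_path=None) -> CoexpressionNetwork:
    import numpy as np

    nodes_path = nodes_path or str(path) + ".nodes"
    nodes = sorted(read_gene_set(nodes_path))
    pos = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=bool)
    df = pd.read_csv(path, sep="\t")
    for a, b in zip(df["gene_a"], df["gene_b"]):
        A[pos[a], pos[b]] = A[pos[b], pos[a]] = True
    return CoexpressionNetwork(nodes, A)


def write_graphml(net: CoexpressionNetwork, path) -> None:
    import networkx as nx

    nx.write_graphml(net.to_networkx(), path)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)


def _jsonable(x):
    try:
        return x.item()
    except AttributeError:
        return str(x)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
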