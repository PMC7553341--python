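"""Czekanowski-Dice neighbourhood distance for PPI networks.

Two proteins are functionally close when they interact with the same
partners.  The Czekanowski-Dice (CD) distance quantifies this as

    d_ij = (|Int(i) u Int(j)| - |Int(i) n Int(j)|) /
           (|Int(i) u Int(j)| + |Int(i) n Int(j)|)

where Int(i) is the *open* adjacency list of protein i (a protein is not a
member of its own neighbourhood).  The distance is 0 exactly when the two
neighbourhoods coincide and 1 exactly when they are disjoint — in
particular two interacting proteins with no shared partner are at distance
1, because interaction alone carries no neighbourhood overlap under the
open convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .graph_io import PPINGraph

__all__ = ["DistanceMatrix", "cd_distance_matrix"]


class DistanceMatrix:
    """Symmetric matrix of pairwise distances over an ordered label set.

    The diagonal is stored as 0 by convention and never consumed by the
    pipeline (a protein has no distance to itself on a tour).
    """

    def __init__(self, labels: tuple[str, ...], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match label count")
        self.labels: tuple[str, ...] = tuple(labels)
        self.values: np.ndarray = values
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def to_tsv(self, path: str | Path) -> None:
        """Dump as a labelled TSV matrix (diagonal printed as '-')."""
        path = Path(path)
        lines = ["\t".join(("protein", *self.labels))]
        for i, lab in enumerate(self.labels):
            row = [lab]
            for j in range(self.n):
                row.append("-" if i == j else f"{self.values[i, j]:.4f}")
            lines.append("\t".join(row))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def cd_distance_matrix(graph: PPINGraph) -> DistanceMatrix:
    """Compute the full Czekanowski-Dice distance matrix of a clean graph.

    Because |Int(i) u Int(j)| + |Int(i) n Int(j)| = deg(i) + deg(j) and
    |Int(i) u Int(j)| - |Int(i) n Int(j)| = deg(i) + deg(j) - 2|Int(i) n Int(j)|,
    the whole matrix reduces to one boolean matrix product:

        d = 1 - 2 * (A @ A) / (deg_i + deg_j)

    with A the 0/1 adjacency matrix (zero diagonal).

    Raises
    ------
    ValueError
        If the graph contains an isolated protein (the ratio would be 0/0).
    """
    nodes = graph.nodes
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    idx = {p: i for i, p in enumerate(nodes)}
    a = np.zeros((n, n), dtype=np.int64)
    for u, v in graph.edges():
        a[idx[u], idx[v]] = 1
        a[idx[v], idx[u]] = 1
    deg = a.sum(axis=1)
    if np.any(deg == 0):
        bad = nodes[int(np.argmin(deg))]
        raise ValueError(f"isolated protein {bad!r}: CD-distance undefined")
    common = a @ a  # common[i, j] = |Int(i) n Int(j)| (open neighbourhoods)
    denom = deg[:, None] + deg[None, :]
    d = 1.0 - 2.0 * common / denom
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(nodes, d)
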