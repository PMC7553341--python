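"""Shared fixtures: the six-protein worked example and small exact oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ppintour import PPINGraph, cd_distance_matrix

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

# Six-protein example network: A-B, A-C, B-D, B-E, C-D, C-F, D-E, D-F, E-F.
EXAMPLE_EDGES: list[tuple[str, str]] = [
    ("A", "B"),
    ("A", "C"),
    ("B", "D"),
    ("B", "E"),
    ("C", "D"),
    ("C", "F"),
    ("D", "E"),
    ("D", "F"),
    ("E", "F"),
]

# CD-distance matrix of that network, rounded to four decimals
# (row/column order A..F, diagonal unused).
EXAMPLE_DISTANCES = np.array(
    [
        [0.0000, 1.0000, 1.0000, 0.3333, 0.6000, 0.6000],
        [1.0000, 0.0000, 0.3333, 0.7143, 0.6667, 0.3333],
        [1.0000, 0.3333, 0.0000, 0.7143, 0.3333, 0.6667],
        [0.3333, 0.7143, 0.7143, 0.0000, 0.4286, 0.4286],
        [0.6000, 0.6667, 0.3333, 0.4286, 0.0000, 0.6667],
        [0.6000, 0.3333, 0.6667, 0.4286, 0.6667, 0.0000],
    ]
)


@pytest.fixture(scope="session")
def example_graph() -> PPINGraph:
    return PPINGraph(EXAMPLE_EDGES)


@pytest.fixture(scope="session")
def example_dist(example_graph):
    return cd_distance_matrix(example_graph)


def cd_distance_set_oracle(graph: PPINGraph, i: str, j: str) -> float:
    """Direct set-arithmetic CD-distance, independent of the matrix code."""
    ni, nj = set(graph.neighbors(i)), set(graph.neighbors(j))
    union, inter = len(ni | nj), len(ni & nj)
    return (union - inter) / (union + inter)


def held_karp_path_length(d: np.ndarray) -> float:
    """Exact shortest Hamiltonian-path length (free endpoints) by DP.

    O(2^n n^2); intended for n <= 12.  Independent of the tour-search code.
    """
    n = d.shape[0]
    inf = float("inf")
    dp = [[inf] * n for _ in range(1 << n)]
    for j in range(n):
        dp[1 << j][j] = 0.0
    for s in range(1 << n):
        for j in range(n):
            cur = dp[s][j]
            if cur == inf or not (s >> j) & 1:
                continue
            for k in range(n):
                if (s >> k) & 1:
                    continue
                v = cur + d[j, k]
                if v < dp[s | (1 << k)][k]:
                    dp[s | (1 << k)][k] = v
    return min(dp[(1 << n) - 1])


def random_symmetric_distances(n: int, rng: np.random.Generator) -> np.ndarray:
    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m
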