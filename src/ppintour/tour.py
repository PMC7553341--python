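"""Shortest Hamiltonian path search over the protein distance matrix.

Proteins that lie close together on a short Hamiltonian path through the
CD-distance matrix tend to share interaction neighbourhoods, so the path
order is a one-dimensional functional arrangement of the network and its
contiguous low-distance stretches are candidate functional modules.

The search has two phases:

* **Nearest-neighbour construction.**  A dummy node at distance 0 to every
  protein is the start vertex; the greedy rule repeatedly appends the
  nearest unvisited protein.  The dummy is removed at the end, leaving a
  path over the real proteins.

* **Lin-Kernighan-style improvement.**  Sequential K-opt moves are applied
  until no move shortens the tour.  A move is grown as an alternating
  chain of removed and added links subject to the classic criteria:
  the chain is *sequential* (links share endpoints), every intermediate
  state is a valid Hamiltonian path (*feasibility* — guaranteed here by
  construction, each step is a prefix reversal), the cumulative gain stays
  strictly positive (*positive gain*), an added link is never a link removed
  earlier in the same chain (*disjunctive*), and added links are restricted
  to per-node nearest-neighbour candidate lists (*candidate set*).

Paths are optimised as cycles through the dummy node: a cycle containing a
node at distance 0 to everything is exactly a path plus two free ends, so
cycle optimality coincides with path optimality.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .distance import DistanceMatrix

__all__ = ["Tour", "LKParams", "tour_length", "nn_initial_tour", "lk_improve"]

_EPS = 1e-12


@dataclass(frozen=True)
class Tour:
    """An ordering of all proteins (a path, not a cycle) and its length."""

    order: tuple[str, ...]
    length: float

    def to_tsv(self, path: str | Path, dist: DistanceMatrix) -> None:
        """Debug dump: rank, protein, distance to the next protein on the path."""
        lines = ["rank\tprotein_id\td_to_next"]
        for k, p in enumerate(self.order):
            d = (
                f"{dist.get(p, self.order[k + 1]):.6f}"
                if k + 1 < len(self.order)
                else "NA"
            )
            lines.append(f"{k}\t{p}\t{d}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class LKParams:
    """Search-effort knobs for the K-opt improvement phase.

    max_move_depth
        Largest number of links a single sequential move may remove (K).
    candidate_list_size
        Length of each node's nearest-neighbour candidate list; ``n - 1``
        removes the candidate-set restriction entirely.
    runs
        Number of optimisation runs.  Runs after the first restart from a
        seeded double-bridge perturbation of the best tour found so far and
        the best result over all runs is returned.
    seed
        Seed for the perturbation randomness (unused when ``runs == 1``).
    """

    max_move_depth: int = 5
    candidate_list_size: int = 5
    runs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_move_depth < 2:
            raise ValueError("max_move_depth must be >= 2")
        if self.candidate_list_size < 1:
            raise ValueError("candidate_list_size must be >= 1")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


def tour_length(order: Sequence[str], dist: DistanceMatrix) -> float:
    """Sum of consecutive distances along ``order`` (0 for a single node)."""
    if sorted(order) != sorted(dist.labels):
        raise ValueError("order is not a permutation of the distance-matrix labels")
    idx = [dist.index(p) for p in order]
    return float(sum(dist.values[i, j] for i, j in zip(idx, idx[1:])))


def nn_initial_tour(dist: DistanceMatrix) -> Tour:
    """Greedy nearest-neighbour construction of an initial path.

    Starts from a dummy node at distance 0 to every protein, so the first
    real protein is the tie-break minimum: the lexicographically smallest
    label.  Thereafter the nearest unvisited protein is appended, ties again
    broken lexicographically (labels are sorted, so the first argmin wins).
    """
    n = dist.n
    if n == 0:
        raise ValueError("empty distance matrix")
    d = dist.values
    visited = np.zeros(n, dtype=bool)
    order = [0]  # from the dummy, every protein ties at 0; lexicographic minimum
    visited[0] = True
    for _ in range(n - 1):
        row = np.where(visited, np.inf, d[order[-1]])
        nxt = int(np.argmin(row))
        order.append(nxt)
        visited[nxt] = True
    labels = tuple(dist.labels[i] for i in order)
    return Tour(order=labels, length=tour_length(labels, dist))


class _LinKernighan:
    """Sequential K-opt improver on the dummy-augmented cycle.

    Internal node indices are 0..n-1 for proteins (in label order) and n for
    the dummy.  Every chain step is a prefix reversal of the open path, so
    feasibility holds at every depth; closing the path back to the anchor at
    any depth >= 2 yields a valid tour.
    """

    def __init__(self, dist: DistanceMatrix, params: LKParams):
        n = dist.n
        self.n = n
        self.m = n + 1  # + dummy
        d = np.zeros((self.m, self.m), dtype=float)
        d[:n, :n] = dist.values
        self.d = d
        self.depth_limit = params.max_move_depth
        cand_size = min(params.candidate_list_size, self.m - 1)
        # nearest-neighbour candidate lists; ties broken by node index,
        # i.e. lexicographically since labels are sorted
        self.cand: list[list[int]] = []
        for i in range(self.m):
            others = [j for j in range(self.m) if j != i]
            others.sort(key=lambda j: (d[i, j], j))
            self.cand.append(others[:cand_size])
        # full backtracking over the candidate list at shallow depths,
        # greedy single-candidate extension deeper down
        self.breadth_by_depth = lambda depth: cand_size if depth <= 3 else 1

    def cycle_length(self, seq: list[int]) -> float:
        d = self.d
        return float(
            sum(d[seq[k], seq[(k + 1) % len(seq)]] for k in range(len(seq)))
        )

    def optimize(self, seq: list[int], scan: list[int] | None = None) -> list[int]:
        """Apply improving moves until a full scan yields none.

        ``scan`` is the order in which anchor nodes are tried; the default
        (index order) keeps single runs deterministic, while restart runs
        pass a shuffled order to decorrelate their search trajectories.
        """
        self.seq = list(seq)
        scan = list(range(self.m)) if scan is None else scan
        improved = True
        while improved:
            improved = False
            for t1 in scan:
                if self._improve_from(t1):
                    improved = True
        return self.seq

    def _improve_from(self, t1: int) -> bool:
        seq = self.seq
        m = self.m
        i1 = seq.index(t1)
        succ = seq[(i1 + 1) % m]
        pred = seq[(i1 - 1) % m]
        for t2 in (succ, pred):
            if t2 == succ:
                path = seq[i1 + 1 :] + seq[: i1 + 1]  # t2 ... t1
            else:
                path = list(reversed(seq[i1:] + seq[:i1]))  # t2 ... t1
            ppos = {v: k for k, v in enumerate(path)}
            removed = {frozenset((t1, t2))}
            if self._chain(path, ppos, self.d[t1, t2], removed, set(), depth=1):
                self.seq = path  # closing link (free end, anchor) is implicit
                return True
        return False

    def _chain(
        self,
        path: list[int],
        ppos: dict[int, int],
        gain: float,
        removed: set[frozenset[int]],
        added: set[frozenset[int]],
        depth: int,
    ) -> bool:
        d = self.d
        anchor = path[-1]
        free = path[0]
        tried = 0
        breadth = self.breadth_by_depth(depth)
        for t3 in self.cand[free]:
            if tried >= breadth:
                break
            g1 = gain - d[free, t3]
            if g1 <= _EPS:
                break  # candidates are distance-sorted: no later one can gain
            if t3 == anchor or t3 == path[1]:
                continue
            e_add = frozenset((free, t3))
            if e_add in removed:
                continue  # disjunctive criterion
            p = ppos[t3]
            t4 = path[p - 1]
            e_rm = frozenset((t3, t4))
            if e_rm in added:
                continue
            tried += 1
            g2 = g1 + d[t3, t4]
            # prefix reversal: path becomes t4 ... free, t3, ... anchor
            path[:p] = path[p - 1 :: -1] if p > 0 else path[:p]
            for k in range(p):
                ppos[path[k]] = k
            if g2 - d[t4, anchor] > _EPS:
                return True  # positive total gain on closing: keep the move
            if depth + 1 < self.depth_limit:
                removed.add(e_rm)
                added.add(e_add)
                if self._chain(path, ppos, g2, removed, added, depth + 1):
                    return True
                removed.discard(e_rm)
                added.discard(e_add)
            path[:p] = path[p - 1 :: -1] if p > 0 else path[:p]
            for k in range(p):
                ppos[path[k]] = k
        return False

    def perturb(self, seq: list[int], rng: np.random.Generator) -> list[int]:
        """Restart tour for the next run.

        Tiny instances restart from a fresh random permutation (a double
        bridge barely changes them); larger ones use the classic
        double-bridge 4-opt kick, which sequential moves cannot undo in one
        step.
        """
        m = len(seq)
        if m <= 12:
            perm = list(rng.permutation(m))
            return [seq[i] for i in perm]
        cuts = sorted(rng.choice(np.arange(1, m), size=3, replace=False))
        a, b, c = (int(x) for x in cuts)
        return seq[:a] + seq[b:c] + seq[a:b] + seq[c:]


def _path_from_cycle(seq: list[int], n: int, labels: tuple[str, ...]) -> tuple[str, ...]:
    """Cut the cycle at the dummy node and orient the path canonically."""
    i = seq.index(n)
    path = seq[i + 1 :] + seq[:i]
    if path and path[0] > path[-1]:
        path = path[::-1]
    return tuple(labels[j] for j in path)


def lk_improve(tour: Tour, dist: DistanceMatrix, params: LKParams | None = None) -> Tour:
    """Improve a tour with sequential K-opt moves; never returns a longer one.

    The path is embedded as a cycle through a dummy node at distance 0 to
    every protein, optimised until no improving sequential move up to the
    configured depth exists, and cut back open at the dummy.  With
    ``params.runs > 1`` the search restarts from seeded double-bridge
    perturbations of the incumbent and keeps the best tour found.
    """
    params = params or LKParams()
    n = dist.n
    if sorted(tour.order) != sorted(dist.labels):
        raise ValueError("tour is not a permutation of the distance-matrix labels")
    if n <= 2:
        return Tour(order=tour.order, length=tour_length(tour.order, dist))
    lk = _LinKernighan(dist, params)
    seq = [dist.index(p) for p in tour.order] + [n]
    best = lk.optimize(seq)
    best_len = lk.cycle_length(best)
    if params.runs > 1:
        rng = np.random.default_rng(params.seed)
        for _ in range(params.runs - 1):
            cand = lk.perturb(best, rng)
            scan = [int(i) for i in rng.permutation(lk.m)]
            out = lk.optimize(cand, scan)
            out_len = lk.cycle_length(out)
            if out_len < best_len - _EPS:
                best, best_len = out, out_len
    order = _path_from_cycle(best, n, dist.labels)
    length = tour_length(order, dist)
    if length > tour.length + 1e-9:  # defensive: improvement is monotone
        return Tour(order=tour.order, length=tour.length)
    return Tour(order=order, length=length)
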