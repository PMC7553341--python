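"""From tour to protein functional modules: segmentation, merging, filtering.

The Hamiltonian path groups functionally related proteins into contiguous
stretches.  Post-processing turns the path into disjoint modules:

1. **Segmentation** cuts the path at every consecutive pair whose
   CD-distance exceeds a threshold; each maximal uncut stretch becomes a
   preliminary module.
2. **Function-information merging** repeatedly fuses the pair of modules
   with the highest Gene-Ontology functional similarity while it exceeds a
   threshold theta.  Inter-module similarity is the sum of all cross-pair
   protein similarities normalised by the smaller module size (it can
   exceed 1); protein-protein similarity is the Jaccard index of the two
   GO term sets.
3. **Density filtering** discards modules whose internal edge density
   e / (N(N-1)/2) falls below a lower bound; discarded proteins are
   reported as unassigned rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .distance import DistanceMatrix
    from .graph_io import GOAnnotationMap, PPINGraph
    from .tour import Tour

__all__ = [
    "ModuleSet",
    "PostprocessParams",
    "segment_tour",
    "protein_similarity",
    "module_similarity",
    "merge_by_function",
    "module_density",
    "filter_by_density",
]


@dataclass(frozen=True)
class ModuleSet:
    """Disjoint, nonempty protein modules plus a pool of unassigned proteins.

    The union of all modules and the unassigned pool is the protein universe
    of the stage that produced the set; it is conserved through every
    post-processing step.
    """

    modules: tuple[frozenset[str], ...]
    unassigned: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mod in self.modules:
            if not mod:
                raise ValueError("empty module")
            if seen & mod:
                raise ValueError("modules overlap")
            seen |= mod
        if seen & self.unassigned:
            raise ValueError("unassigned proteins overlap a module")

    @property
    def all_proteins(self) -> frozenset[str]:
        out: set[str] = set(self.unassigned)
        for mod in self.modules:
            out |= mod
        return frozenset(out)

    def labels(self) -> dict[str, int]:
        """Protein -> module index; every unassigned protein maps to -1."""
        lab: dict[str, int] = {}
        for k, mod in enumerate(sorted(self.modules, key=min)):
            for p in mod:
                lab[p] = k
        for p in self.unassigned:
            lab[p] = -1
        return lab

    def __len__(self) -> int:
        return len(self.modules)


@dataclass(frozen=True)
class PostprocessParams:
    """Thresholds of the post-processing stage.

    cut_threshold
        CD-distance above which a tour edge is cut (delta).  ``None`` means
        the empirical 75th percentile of the tour-edge distances.
    merge_threshold
        Minimum inter-module functional similarity for a merge (theta).
    density_min
        Lower bound on module edge density; modules below it are unassigned.
    keep_singletons
        Whether single-protein modules survive density filtering (their
        density is 0 by convention).
    """

    cut_threshold: float | None = None
    merge_threshold: float = 0.05
    density_min: float = 0.0
    keep_singletons: bool = True

    def __post_init__(self) -> None:
        if self.cut_threshold is not None and not 0.0 <= self.cut_threshold <= 1.0:
            raise ValueError("cut_threshold must be in [0, 1]")
        if self.merge_threshold < 0.0:
            raise ValueError("merge_threshold must be >= 0")
        if not 0.0 <= self.density_min <= 1.0:
            raise ValueError("density_min must be in [0, 1]")


def segment_tour(
    tour: "Tour", dist: "DistanceMatrix", cut_threshold: float | None = None
) -> ModuleSet:
    """Cut the path at long edges; each maximal uncut stretch is a module.

    With ``cut_threshold=None`` the cut level is the 75th percentile of the
    distances along the tour, so roughly the longest quarter of the path
    edges is severed.
    """
    order = tour.order
    if len(order) == 0:
        raise ValueError("empty tour")
    if len(order) == 1:
        return ModuleSet(modules=(frozenset(order),))
    edge_d = [dist.get(a, b) for a, b in zip(order, order[1:])]
    delta = float(np.percentile(edge_d, 75)) if cut_threshold is None else cut_threshold
    segments: list[list[str]] = [[order[0]]]
    for d, p in zip(edge_d, order[1:]):
        if d > delta:
            segments.append([p])
        else:
            segments[-1].append(p)
    return ModuleSet(modules=tuple(frozenset(s) for s in segments))


def protein_similarity(
    g_i: Iterable[str], g_j: Iterable[str], same_protein: bool = False
) -> float:
    """Functional similarity of two proteins from their GO term sets.

    1 for a protein with itself; otherwise the Jaccard index of the term
    sets, with the empty/empty case (two unannotated distinct proteins)
    defined as 0.
    """
    if same_protein:
        return 1.0
    si, sj = frozenset(g_i), frozenset(g_j)
    union = len(si | sj)
    if union == 0:
        return 0.0
    return len(si & sj) / union


def module_similarity(
    m_a: frozenset[str], m_b: frozenset[str], go: "GOAnnotationMap"
) -> float:
    """Inter-module functional similarity.

    The sum of protein-protein similarities over all cross pairs, divided by
    the size of the smaller module.  Because the numerator sums over every
    cross pair the value can exceed 1.
    """
    if not m_a or not m_b:
        raise ValueError("modules must be nonempty")
    if m_a & m_b:
        raise ValueError("modules overlap")
    total = 0.0
    for i in m_a:
        gi = go.terms(i)
        for j in m_b:
            total += protein_similarity(gi, go.terms(j))
    return total / min(len(m_a), len(m_b))


def _pairwise_protein_sim(
    proteins: list[str], go: "GOAnnotationMap"
) -> np.ndarray:
    n = len(proteins)
    terms = [go.terms(p) for p in proteins]
    s = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            s[i, j] = s[j, i] = protein_similarity(terms[i], terms[j])
    return s


def merge_by_function(
    modules: ModuleSet, go: "GOAnnotationMap", merge_threshold: float
) -> ModuleSet:
    """Greedily merge the most functionally similar module pair above theta.

    After each merge every similarity involving the new module is
    recomputed (the min-size normalisation changes), and the process repeats
    until no pair exceeds the threshold.  Ties on similarity are broken on
    the lexicographically smallest member labels of the pair, so the result
    is deterministic.  At most ``len(modules) - 1`` merges can occur.
    """
    mods: list[frozenset[str]] = sorted(modules.modules, key=min)
    if len(mods) < 2:
        return modules
    # cache all protein-pair similarities once; module similarity is then a
    # submatrix sum over index arrays
    proteins = sorted(set().union(*mods))
    pidx = {p: k for k, p in enumerate(proteins)}
    sim = _pairwise_protein_sim(proteins, go)
    idx: list[np.ndarray] = [np.array([pidx[p] for p in m]) for m in mods]

    def pair_sim(a: int, b: int) -> float:
        return float(sim[np.ix_(idx[a], idx[b])].sum()) / min(len(idx[a]), len(idx[b]))

    while len(mods) > 1:
        best: tuple[float, tuple[str, str], int, int] | None = None
        for a in range(len(mods)):
            for b in range(a + 1, len(mods)):
                s = pair_sim(a, b)
                if s <= merge_threshold:
                    continue
                key = tuple(sorted((min(mods[a]), min(mods[b]))))
                if best is None or s > best[0] + 1e-12 or (
                    abs(s - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (s, key, a, b)
        if best is None:
            break
        _, _, a, b = best
        merged = mods[a] | mods[b]
        merged_idx = np.concatenate([idx[a], idx[b]])
        mods = [m for k, m in enumerate(mods) if k not in (a, b)] + [merged]
        idx = [x for k, x in enumerate(idx) if k not in (a, b)] + [merged_idx]
    order = np.argsort([min(m) for m in mods])
    return ModuleSet(
        modules=tuple(mods[k] for k in order), unassigned=modules.unassigned
    )


def module_density(module: frozenset[str] | Iterable[str], graph: "PPINGraph") -> float:
    """Internal edge density e / (N(N-1)/2) of a module; 0 for singletons."""
    members = frozenset(module)
    if not members:
        raise ValueError("empty module")
    n = len(members)
    if n == 1:
        return 0.0
    e = graph.subgraph_edge_count(members)
    return e / (n * (n - 1) / 2)


def filter_by_density(
    modules: ModuleSet,
    graph: "PPINGraph",
    density_min: float,
    keep_singletons: bool = True,
) -> ModuleSet:
    """Move modules with density below the bound to the unassigned pool.

    Singleton modules (density 0 by convention) are kept only when
    ``keep_singletons`` is set.
    """
    kept: list[frozenset[str]] = []
    dropped: set[str] = set(modules.unassigned)
    for mod in sorted(modules.modules, key=min):
        if len(mod) == 1:
            if keep_singletons:
                kept.append(mod)
            else:
                dropped |= mod
            continue
        if module_density(mod, graph) >= density_min:
            kept.append(mod)
        else:
            dropped |= mod
    return ModuleSet(modules=tuple(kept), unassigned=frozenset(dropped))
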