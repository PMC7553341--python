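"""Reading, cleaning and writing of protein interaction networks and GO annotations.

A protein-protein interaction network (PPIN) is an undirected graph whose
nodes are proteins and whose edges are physical interactions.  The clustering
pipeline downstream needs a *clean* graph: no self-interactions, no duplicate
records, and no isolated proteins (the neighbourhood-overlap distance is
undefined for a protein without interaction partners, and an isolated protein
cannot be placed meaningfully on an interaction-distance tour).

Supported input formats:

* two-column TSV edge lists (``#`` starts a comment line),
* PSI-MITAB 2.5 interaction tables (only the two interactor-identifier
  columns are consumed; evidence columns are ignored),
* two-column TSV protein-to-GO-term annotation files,
* GAF 2.x annotation files (DB Object ID and GO ID columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .modules import ModuleSet

logger = logging.getLogger(__name__)

__all__ = [
    "PPINGraph",
    "GOAnnotationMap",
    "MalformedRecordError",
    "EmptyGraphError",
    "read_edge_list",
    "read_go_annotations",
    "write_modules",
    "read_modules",
]


class MalformedRecordError(ValueError):
    """A data row of an input file could not be parsed."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


class EmptyGraphError(ValueError):
    """No usable interaction survived cleaning."""


class PPINGraph:
    """Cleaned, undirected protein-protein interaction graph.

    Construction drops self-loops, collapses duplicate and reversed edge
    records, and removes proteins left without any interaction partner.
    Node order is lexicographic on the protein identifier and every
    iteration order in the pipeline derives from it, which makes the whole
    pipeline deterministic.

    The open neighbourhood of a protein (its adjacency list, excluding the
    protein itself) is exposed through :meth:`neighbors`.
    """

    def __init__(self, edges: Iterable[tuple[str, str]]):
        g = nx.Graph()
        seen: set[str] = set()
        n_self = n_dup = 0
        for a, b in edges:
            a, b = str(a), str(b)
            seen.add(a)
            seen.add(b)
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
        isolated = sorted(seen - set(g.nodes))
        if n_self or n_dup or isolated:
            logger.info(
                "graph cleaning: dropped %d self-loop(s), %d duplicate edge(s), "
                "%d isolated protein(s)%s",
                n_self,
                n_dup,
                len(isolated),
                f" ({', '.join(isolated[:5])}{'...' if len(isolated) > 5 else ''})"
                if isolated
                else "",
            )
        if g.number_of_edges() == 0:
            raise EmptyGraphError("no interactions left after cleaning")
        self._g = g
        self._nodes: tuple[str, ...] = tuple(sorted(g.nodes))
        self._dropped = {"self_loops": n_self, "duplicates": n_dup, "isolated": len(isolated)}

    # -- basic accessors -------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        """Protein identifiers in lexicographic order."""
        return self._nodes

    @property
    def edge_count(self) -> int:
        return self._g.number_of_edges()

    @property
    def dropped(self) -> dict[str, int]:
        """Counts of records removed during cleaning."""
        return dict(self._dropped)

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, protein: str) -> bool:
        return protein in self._g

    def neighbors(self, protein: str) -> frozenset[str]:
        """Open neighbourhood: interaction partners, never the protein itself."""
        return frozenset(self._g.neighbors(protein))

    def degree(self, protein: str) -> int:
        return self._g.degree(protein)

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def edges(self) -> Iterator[tuple[str, str]]:
        """Edges as sorted pairs, in lexicographic order."""
        for a, b in sorted(tuple(sorted(e)) for e in self._g.edges):
            yield a, b

    def subgraph_edge_count(self, proteins: Iterable[str]) -> int:
        """Number of interactions with both endpoints in ``proteins``."""
        return self._g.subgraph(list(proteins)).number_of_edges()


class GOAnnotationMap:
    """Mapping from protein identifier to its set of GO term identifiers.

    Term identifiers are opaque strings; looking up a protein that was never
    annotated returns the empty set.
    """

    def __init__(self, annotations: Mapping[str, Iterable[str]] | None = None):
        self._ann: dict[str, frozenset[str]] = {}
        if annotations:
            for protein, terms in annotations.items():
                self._ann[str(protein)] = frozenset(str(t) for t in terms)

    def terms(self, protein: str) -> frozenset[str]:
        return self._ann.get(protein, frozenset())

    __getitem__ = terms

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(sorted(self._ann))

    def __len__(self) -> int:
        return len(self._ann)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GOAnnotationMap):
            return NotImplemented
        return self._ann == other._ann


# -- readers -------------------------------------------------------------


def _iter_data_lines(path: Path, comment: str) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(comment):
                continue
            yield lineno, line


def _strip_db_prefix(field: str) -> str:
    # MITAB interactor ids look like "uniprotkb:P12345"
    return field.split(":", 1)[1] if ":" in field else field


def read_edge_list(path: str | Path, dialect: str = "tsv") -> PPINGraph:
    """Read an interaction file and return the cleaned :class:`PPINGraph`.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"tsv"`` for a plain two-column edge list, ``"mitab"`` for
        PSI-MITAB 2.5 (interactor identifier columns 1-2).
    """
    path = Path(path)
    if dialect not in ("tsv", "mitab"):
        raise ValueError(f"unknown edge-list dialect {dialect!r}")
    edges: list[tuple[str, str]] = []
    for lineno, line in _iter_data_lines(path, comment="#"):
        fields = line.split("\t")
        if len(fields) < 2 and dialect == "tsv":
            fields = line.split()
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise MalformedRecordError(
                path, lineno, f"expected two interactor columns, got {line!r}"
            )
        a, b = fields[0].strip(), fields[1].strip()
        if dialect == "mitab":
            a, b = _strip_db_prefix(a), _strip_db_prefix(b)
        edges.append((a, b))
    if not edges:
        raise EmptyGraphError(f"{path}: no interaction records found")
    return PPINGraph(edges)


def read_go_annotations(path: str | Path, dialect: str = "tsv") -> GOAnnotationMap:
    """Read protein-to-GO-term annotations.

    ``"tsv"`` expects two columns (protein, term); ``"gaf"`` expects GAF 2.x
    rows (``!`` comment lines, >= 15 tab-separated columns) and uses the
    DB Object ID (column 2) and GO ID (column 5).  Duplicate rows collapse
    under set semantics.
    """
    path = Path(path)
    if dialect not in ("tsv", "gaf"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    comment = "#" if dialect == "tsv" else "!"
    ann: dict[str, set[str]] = {}
    for lineno, line in _iter_data_lines(path, comment=comment):
        fields = line.split("\t")
        if dialect == "tsv":
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise MalformedRecordError(
                    path, lineno, f"expected protein<TAB>term, got {line!r}"
                )
            protein, term = fields[0].strip(), fields[1].strip()
        else:
            if len(fields) < 15:
                raise MalformedRecordError(
                    path, lineno, f"GAF row has {len(fields)} columns, expected >= 15"
                )
            protein, term = fields[1].strip(), fields[4].strip()
            if not protein or not term:
                raise MalformedRecordError(path, lineno, "empty identifier in GAF row")
        ann.setdefault(protein, set()).add(term)
    return GOAnnotationMap(ann)


# -- writers -------------------------------------------------------------


def write_modules(modules: ModuleSet, path: str | Path) -> None:
    """Write a module assignment as TSV with columns ``module_id, protein_id``.

    Modules are numbered M1, M2, ... in order of their lexicographically
    smallest member; unassigned proteins get module_id ``NA``.  The output
    is byte-deterministic for a given :class:`~ppintour.modules.ModuleSet`.
    """
    path = Path(path)
    ordered = sorted(modules.modules, key=min)
    lines = ["module_id\tprotein_id"]
    for k, mod in enumerate(ordered, start=1):
        for protein in sorted(mod):
            lines.append(f"M{k}\t{protein}")
    for protein in sorted(modules.unassigned):
        lines.append(f"NA\t{protein}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_modules(path: str | Path) -> ModuleSet:
    """Read a module TSV written by :func:`write_modules`."""
    path = Path(path)
    by_id: dict[str, set[str]] = {}
    unassigned: set[str] = set()
    first = True
    for lineno, line in _iter_data_lines(path, comment="#"):
        fields = line.split("\t")
        if first and fields[:2] == ["module_id", "protein_id"]:
            first = False
            continue
        first = False
        if len(fields) < 2:
            raise MalformedRecordError(path, lineno, f"expected two columns, got {line!r}")
        mid, protein = fields[0].strip(), fields[1].strip()
        if mid == "NA":
            unassigned.add(protein)
        else:
            by_id.setdefault(mid, set()).add(protein)
    return ModuleSet(
        modules=tuple(frozenset(s) for _, s in sorted(by_id.items(), key=lambda kv: min(kv[1]))),
        unassigned=frozenset(unassigned),
    )
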