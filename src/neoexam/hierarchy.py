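"""Data model, CSV I/O, and validation for concept hierarchies.

A hierarchy is a rooted set of concepts linked by child-parent (is_a) edges.
Two modes are supported: ``mono`` (a tree -- every non-root concept has
exactly one parent, the convention used for the neurological examination
ontology) and ``dag`` (a poly-hierarchy in the style of SNOMED CT, where a
concept may have several parents).

The on-disk format is a UTF-8 CSV with header ``name,cui,sctid,parent_cui``
and an optional fifth ``source`` column; one row per child-parent link, the
root row with an empty ``parent_cui``.  Because every row carries its own
parent link, subsumption tables and depths are derived directly from the
file with no auxiliary relationship tables.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import (
    CycleError,
    DanglingParentError,
    DuplicateConceptError,
    HierarchyParseError,
    MissingConceptError,
    MultiRootError,
)

#: UMLS concept identifiers: the letter C followed by exactly seven digits.
CUI_RE = re.compile(r"^C\d{7}$")

CSV_COLUMNS = ("name", "cui", "sctid", "parent_cui")
CSV_SOURCE_COLUMN = "source"

MODES = ("mono", "dag")


def is_valid_cui(cui: str) -> bool:
    """True if *cui* matches the 8-character ``C#######`` pattern."""
    return bool(CUI_RE.match(cui))


@dataclass(frozen=True)
class Concept:
    """One hierarchy node.

    Parameters
    ----------
    id:
        Concept unique identifier (CUI).
    name:
        Preferred concept name.
    sctid:
        SNOMED CT identifier, if the concept has one.
    parents:
        Parent CUIs; empty only for the root, length 1 in mono mode.
    source:
        Optional source-terminology label (e.g. ``"SNOMED CT"``) used for
        contribution accounting.
    """

    id: str
    name: str
    sctid: str | None = None
    parents: tuple[str, ...] = ()
    source: str | None = None


@dataclass
class HierarchyStats:
    n_concepts: int
    max_depth: int
    mean_children: float  # averaged over non-leaf concepts


@dataclass
class ValidationReport:
    ok: bool
    errors: list[tuple[str, str, str]]  # (code, concept id, message)
    stats: HierarchyStats | None


class ConceptHierarchy:
    """A validated rooted concept hierarchy with depth/ancestor queries.

    Structural invariants (single root, resolvable parents, acyclicity,
    mono-mode arity) are enforced at construction; content checks such as
    the CUI pattern are deferred to :func:`validate` so that imperfect
    files can still be loaded and inspected.
    """

    def __init__(self, concepts: Iterable[Concept], mode: str = "mono"):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        self.mode = mode
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.id in self.concepts:
                raise DuplicateConceptError(f"duplicate concept id {c.id!r}")
            if c.id in c.parents:
                raise CycleError(f"concept {c.id!r} lists itself as a parent")
            if len(set(c.parents)) != len(c.parents):
                raise DuplicateConceptError(
                    f"concept {c.id!r} lists a duplicate parent"
                )
            self.concepts[c.id] = c

        # Directed edges parent -> child.  Cycles are diagnosed before the
        # root check: a file where every concept has a parent is a cycle,
        # not a missing root.
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        for c in self.concepts.values():
            for p in c.parents:
                if p not in self.concepts:
                    raise DanglingParentError(
                        f"concept {c.id!r} references unknown parent {p!r}"
                    )
                g.add_edge(p, c.id)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
            raise CycleError(f"parent graph contains a cycle: {path}")
        self._graph = g

        roots = [c.id for c in self.concepts.values() if not c.parents]
        if len(roots) > 1:
            raise MultiRootError(
                f"expected a single parentless concept, found {sorted(roots)}"
            )
        if not roots:  # pragma: no cover - impossible once acyclic
            raise MultiRootError("no parentless (root) concept found")
        self.root: str = roots[0]

        if mode == "mono":
            for c in self.concepts.values():
                if c.id != self.root and len(c.parents) != 1:
                    raise DuplicateConceptError(
                        f"mono mode: concept {c.id!r} has "
                        f"{len(c.parents)} parents"
                    )
        # Shortest root->node path lengths; root depth is 0 by convention.
        self._depths: dict[str, int] = dict(
            nx.single_source_shortest_path_length(g, self.root)
        )
        unreachable = set(self.concepts) - set(self._depths)
        if unreachable:
            # Cannot happen on an acyclic single-root graph, but guard anyway.
            raise DanglingParentError(
                f"concepts unreachable from root: {sorted(unreachable)}"
            )

    # -- queries ---------------------------------------------------------

    def __contains__(self, cui: str) -> bool:
        return cui in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ConceptHierarchy)
            and self.mode == other.mode
            and self.concepts == other.concepts
        )

    def _require(self, cui: str) -> None:
        if cui not in self.concepts:
            raise MissingConceptError(f"unknown concept id {cui!r}")

    def depth(self, cui: str) -> int:
        """Number of levels from the root to *cui* (root depth is 0).

        In DAG mode this is the length of the shortest root path.
        """
        self._require(cui)
        return self._depths[cui]

    def ancestors(self, cui: str) -> frozenset[str]:
        """All proper ancestors of *cui* plus *cui* itself (inclusive)."""
        self._require(cui)
        return frozenset(nx.ancestors(self._graph, cui)) | {cui}

    def subsumes(self, a: str, b: str) -> bool:
        """True iff *a* is an (inclusive) ancestor of *b*."""
        self._require(a)
        return a in self.ancestors(b)

    def descent_length(self, anc: str, desc: str) -> int:
        """Length of the shortest is_a path from *anc* down to *desc*."""
        self._require(anc)
        self._require(desc)
        return nx.shortest_path_length(self._graph, anc, desc)

    def children(self, cui: str) -> list[str]:
        self._require(cui)
        return sorted(self._graph.successors(cui))

    def leaves(self) -> list[str]:
        return sorted(
            c for c in self.concepts if self._graph.out_degree(c) == 0
        )

    def sorted_ids(self) -> list[str]:
        """Concept ids in the package's canonical (depth, CUI) order."""
        return sorted(self.concepts, key=lambda c: (self._depths[c], c))

    def subsumption_table(self) -> list[tuple[str, str]]:
        """All (ancestor, descendant) pairs of the transitive closure.

        Reflexive pairs are excluded; ordering is deterministic by
        (depth, CUI) of the ancestor, then of the descendant.
        """
        key = lambda c: (self._depths[c], c)
        pairs: list[tuple[str, str]] = []
        for anc in self.sorted_ids():
            for desc in sorted(nx.descendants(self._graph, anc), key=key):
                pairs.append((anc, desc))
        return pairs


# -- validation ----------------------------------------------------------


def validate(h: ConceptHierarchy) -> ValidationReport:
    """Check content invariants and compute summary statistics.

    Violations are reported, not raised, so imperfect hierarchies can be
    inspected.  ``ok`` is true iff the error list is empty.
    """
    errors: list[tuple[str, str, str]] = []
    for c in h.concepts.values():
        if not is_valid_cui(c.id):
            errors.append(
                (
                    "cui-format",
                    c.id,
                    f"CUI {c.id!r} does not match 'C' + seven digits",
                )
            )
        if not c.name:
            errors.append(("empty-name", c.id, "concept name is empty"))
        if c.sctid is not None and not c.sctid.isdigit():
            errors.append(
                ("sctid-format", c.id, f"SCTID {c.sctid!r} is not numeric")
            )

    n_children = [
        h._graph.out_degree(c) for c in h.concepts if h._graph.out_degree(c)
    ]
    stats = HierarchyStats(
        n_concepts=len(h),
        max_depth=max(h._depths.values()),
        mean_children=(sum(n_children) / len(n_children)) if n_children else 0.0,
    )
    return ValidationReport(ok=not errors, errors=errors, stats=stats)


# -- CSV I/O -------------------------------------------------------------


def _parse_rows(reader: Iterable[list[str]], mode: str) -> ConceptHierarchy:
    rows = list(reader)
    if not rows:
        raise HierarchyParseError("empty file: expected a header row")
    header = [c.strip().lower() for c in rows[0]]
    if tuple(header[:4]) != CSV_COLUMNS:
        raise HierarchyParseError(
            f"line 1: expected header {','.join(CSV_COLUMNS)}"
            f"[,{CSV_SOURCE_COLUMN}], got {','.join(header)!r}"
        )
    has_source = len(header) >= 5 and header[4] == CSV_SOURCE_COLUMN

    # cui -> (name, sctid, source, [parents])
    records: dict[str, tuple[str, str | None, str | None, list[str]]] = {}
    seen_links: set[tuple[str, str]] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not cell.strip() for cell in row):
            continue
        if len(row) < 4:
            raise HierarchyParseError(
                f"line {lineno}: expected at least 4 fields, got {len(row)}"
            )
        name, cui, sctid, parent = (cell.strip() for cell in row[:4])
        source = row[4].strip() if has_source and len(row) > 4 else ""
        link = (cui, parent)
        if link in seen_links:
            raise DuplicateConceptError(
                f"line {lineno}: duplicate row for concept {cui!r}"
                + (f" with parent {parent!r}" if parent else "")
            )
        seen_links.add(link)
        if cui in records:
            if mode == "mono":
                raise DuplicateConceptError(
                    f"line {lineno}: duplicate CUI {cui!r} in mono mode"
                )
            prev = records[cui]
            if prev[0] != name:
                raise HierarchyParseError(
                    f"line {lineno}: concept {cui!r} re-declared with a "
                    f"different name ({prev[0]!r} vs {name!r})"
                )
            if parent:
                prev[3].append(parent)
        else:
            records[cui] = (
                name,
                sctid or None,
                source or None,
                [parent] if parent else [],
            )

    concepts = [
        Concept(id=cui, name=name, sctid=sctid, parents=tuple(parents), source=source)
        for cui, (name, sctid, source, parents) in records.items()
    ]
    return ConceptHierarchy(concepts, mode=mode)


def load_hierarchy(path: str | Path, mode: str = "mono") -> ConceptHierarchy:
    """Load a hierarchy from a child-parent CSV file.

    Raises a specific error for malformed CSV, duplicate rows, dangling
    parents, cycles, or multiple roots; row order is not significant.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        try:
            return _parse_rows(csv.reader(fh), mode)
        except csv.Error as exc:  # pragma: no cover - csv rarely raises here
            raise HierarchyParseError(f"{path}: {exc}") from exc


def loads_hierarchy(text: str, mode: str = "mono") -> ConceptHierarchy:
    """Load a hierarchy from CSV text (convenience for tests and fixtures)."""
    return _parse_rows(csv.reader(io.StringIO(text)), mode)


def write_hierarchy(h: ConceptHierarchy, path: str | Path) -> Path:
    """Write *h* as a child-parent CSV; inverse of :func:`load_hierarchy`.

    Rows are emitted in canonical (depth, CUI) order, one row per
    child-parent link; empty SCTID/source fields are written as empty
    cells.  The ``source`` column is included only when some concept
    carries a source label.
    """
    path = Path(path)
    has_source = any(c.source for c in h.concepts.values())
    header = list(CSV_COLUMNS) + ([CSV_SOURCE_COLUMN] if has_source else [])
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for cui in h.sorted_ids():
            c = h.concepts[cui]
            parents: tuple[str, ...] = c.parents or ("",)
            for p in sorted(parents):
                row = [c.name, c.id, c.sctid or "", p]
                if has_source:
                    row.append(c.source or "")
                writer.writerow(row)
    return path
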