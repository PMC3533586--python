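"""Concept graph parsing and taxonomy construction.

A :class:`ConceptGraph` is the raw parse of a semantic network: a set of
concept ids, directed (child, parent) taxonomic edges, and undirected
labelled non-taxonomic edges.  :func:`build_taxonomy` derives a validated
rooted DAG from it — dropping cycle-inducing edges deterministically,
adding a synthetic root when needed — and precomputes the per-concept
structural quantities (depth, leaf counts, subsumer counts) every
similarity measure consumes.

Three readers cover the common interchange formats: a minimal tab-separated
edge list, OBO 1.2 documents, and a configurable pipe-delimited relations
table (the shape of UMLS MRREL-style files).
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

from .errors import (
    FormatError,
    MissingConceptError,
    OntosimError,
    ParseError,
    VersionError,
)

logger = logging.getLogger(__name__)

#: id used for the synthetic root added when a source has several parentless
#: concepts; escalated with underscores if the source already uses the name.
VROOT = "VROOT"

TAXONOMY_FORMAT_TAG = "ontosim-taxonomy"
TAXONOMY_FORMAT_VERSION = 1


@dataclass
class ConceptGraph:
    """Raw directed/labelled semantic network parsed from an input source.

    Attributes
    ----------
    concepts:
        Opaque concept identifiers.
    taxonomic_edges:
        Directed ``(child, parent)`` pairs.
    other_edges:
        Undirected labelled triples stored canonically as
        ``(min(a, b), max(a, b), label)``.
    metadata:
        Free-form source name/version strings.
    """

    concepts: set[str] = field(default_factory=set)
    taxonomic_edges: set[tuple[str, str]] = field(default_factory=set)
    other_edges: set[tuple[str, str, str]] = field(default_factory=set)
    metadata: dict[str, str] = field(default_factory=dict)

    def add_taxonomic_edge(self, child: str, parent: str) -> bool:
        """Register a child→parent edge; self-loops are rejected (returns False)."""
        if child == parent:
            return False
        self.concepts.update((child, parent))
        self.taxonomic_edges.add((child, parent))
        return True

    def add_other_edge(self, a: str, b: str, label: str) -> bool:
        if a == b:
            return False
        self.concepts.update((a, b))
        lo, hi = (a, b) if a <= b else (b, a)
        self.other_edges.add((lo, hi, label))
        return True


class Taxonomy:
    """Validated rooted DAG with cached structural quantities.

    The parent relation is acyclic and every concept reaches :attr:`root`.
    ``depth`` is the node count of the shortest path to the root
    (``depth(root) == 1``); ``d`` is the taxonomy's maximum depth.
    ``n_leaves[c]`` counts the leaves that descend from ``c`` (a leaf counts
    itself), ``n_subsumers[c]`` counts ``c`` plus all its ancestors, and
    ``max_leaves`` is the total number of leaves.
    """

    def __init__(
        self,
        parents: Mapping[str, frozenset[str]],
        root: str,
        removed_edges: list[tuple[str, str]] | None = None,
        metadata: dict[str, str] | None = None,
    ):
        self.parents: dict[str, frozenset[str]] = {
            c: frozenset(ps) for c, ps in parents.items()
        }
        self.root = root
        self.removed_edges: list[tuple[str, str]] = list(removed_edges or [])
        self.metadata: dict[str, str] = dict(metadata or {})

        self.concepts: frozenset[str] = frozenset(self.parents)
        self.children: dict[str, frozenset[str]] = self._invert(self.parents)
        self._topo: list[str] = self._topological_order()
        self.depth: dict[str, int] = self._compute_depth()
        self.d: int = max(self.depth.values())
        self._leaf_sets: dict[str, frozenset[str]] = self._compute_leaf_sets()
        self.n_leaves: dict[str, int] = {
            c: len(s) for c, s in self._leaf_sets.items()
        }
        self.max_leaves: int = self.n_leaves[self.root]
        self.n_subsumers: dict[str, int] = self._compute_n_subsumers()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _invert(parents: Mapping[str, frozenset[str]]) -> dict[str, frozenset[str]]:
        kids: dict[str, set[str]] = {c: set() for c in parents}
        for child, ps in parents.items():
            for p in ps:
                kids[p].add(child)
        return {c: frozenset(s) for c, s in kids.items()}

    def _topological_order(self) -> list[str]:
        """Root-first order (parents before children); raises on a cycle."""
        indeg = {c: len(self.parents[c]) for c in self.parents}
        queue = deque(sorted(c for c, k in indeg.items() if k == 0))
        order: list[str] = []
        while queue:
            node = queue.popleft()
            order.append(node)
            for child in sorted(self.children[node]):
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if len(order) != len(self.parents):
            raise OntosimError("taxonomy parent relation contains a cycle")
        return order

    def _compute_depth(self) -> dict[str, int]:
        depth = {self.root: 1}
        for node in self._topo:
            if node == self.root:
                continue
            depth[node] = min(depth[p] for p in self.parents[node]) + 1
        return depth

    def _compute_leaf_sets(self) -> dict[str, frozenset[str]]:
        sets: dict[str, frozenset[str]] = {}
        for node in reversed(self._topo):
            kids = self.children[node]
            if not kids:
                sets[node] = frozenset((node,))
            else:
                acc: set[str] = set()
                for k in kids:
                    acc |= sets[k]
                sets[node] = frozenset(acc)
        return sets

    def _compute_n_subsumers(self) -> dict[str, int]:
        subs: dict[str, frozenset[str]] = {}
        for node in self._topo:
            acc: set[str] = {node}
            for p in self.parents[node]:
                acc |= subs[p]
            subs[node] = frozenset(acc)
        self._subsumer_sets = subs
        return {c: len(s) for c, s in subs.items()}

    # -- queries --------------------------------------------------------------

    def __contains__(self, concept: str) -> bool:
        return concept in self.parents

    def require(self, concept: str) -> None:
        if concept not in self.parents:
            raise MissingConceptError(concept)

    def subsumers(self, concept: str) -> frozenset[str]:
        """The concept itself plus every ancestor reachable via any parent path."""
        self.require(concept)
        return self._subsumer_sets[concept]

    def leaves(self, concept: str) -> frozenset[str]:
        self.require(concept)
        return self._leaf_sets[concept]

    def topological_order(self) -> list[str]:
        return list(self._topo)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Taxonomy):
            return NotImplemented
        return (
            self.parents == other.parents
            and self.root == other.root
            and self.removed_edges == other.removed_edges
            and self.depth == other.depth
            and self.n_leaves == other.n_leaves
            and self.n_subsumers == other.n_subsumers
            and self.d == other.d
            and self.max_leaves == other.max_leaves
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Taxonomy({len(self.parents)} concepts, root={self.root!r}, "
            f"d={self.d}, max_leaves={self.max_leaves})"
        )


# -- readers ------------------------------------------------------------------


def read_edge_list(stream: Iterable[str]) -> ConceptGraph:
    """Parse a tab-separated edge list into a :class:`ConceptGraph`.

    Each non-comment line is ``child<TAB>parent[<TAB>label]``; lines without
    a label are taxonomic edges, labelled lines become undirected
    ``other_edges``.  Duplicate lines collapse by set semantics.

    Raises
    ------
    ParseError
        If a line has fewer than two fields.
    """
    g = ConceptGraph()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(
                f"expected child<TAB>parent[<TAB>label], got {line!r}", line=lineno
            )
        child, parent = fields[0].strip(), fields[1].strip()
        if not child or not parent:
            raise ParseError("empty concept id", line=lineno)
        if len(fields) >= 3 and fields[2].strip():
            ok = g.add_other_edge(child, parent, fields[2].strip())
        else:
            ok = g.add_taxonomic_edge(child, parent)
        if not ok:
            logger.warning("line %d: self-edge %r rejected", lineno, child)
    return g


def _obo_stanzas(lines: Iterable[str]) -> Iterator[tuple[str, list[tuple[str, str]]]]:
    """Yield (stanza-name, [(tag, value), ...]) for each OBO stanza."""
    name: str | None = None
    tags: list[tuple[str, str]] = []
    for raw in lines:
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            if name is not None:
                yield name, tags
            name, tags = line[1:-1], []
        elif name is not None:
            if ":" not in line:
                raise FormatError(f"malformed OBO tag line: {line!r}")
            tag, value = line.split(":", 1)
            tags.append((tag.strip(), value.strip()))
    if name is not None:
        yield name, tags


def read_obo(stream: Iterable[str]) -> ConceptGraph:
    """Parse an OBO 1.2 document.

    ``is_a`` tags become taxonomic edges; ``relationship`` tags become
    labelled other_edges; obsolete terms are skipped (and counted in a log
    message).
    """
    g = ConceptGraph()
    n_obsolete = 0
    pending_tax: list[tuple[str, str]] = []
    pending_other: list[tuple[str, str, str]] = []
    saw_term = False
    for name, tags in _obo_stanzas(stream):
        if name != "Term":
            continue
        saw_term = True
        tag_map: dict[str, list[str]] = {}
        for tag, value in tags:
            tag_map.setdefault(tag, []).append(value)
        if tag_map.get("is_obsolete", ["false"])[0].lower() == "true":
            n_obsolete += 1
            continue
        ids = tag_map.get("id")
        if not ids:
            raise FormatError("OBO Term stanza without an id tag")
        term = ids[0]
        g.concepts.add(term)
        for parent in tag_map.get("is_a", []):
            pending_tax.append((term, parent.split()[0]))
        for rel in tag_map.get("relationship", []):
            parts = rel.split()
            if len(parts) < 2:
                raise FormatError(f"malformed relationship value: {rel!r}")
            pending_other.append((term, parts[1], parts[0]))
    if not saw_term:
        raise FormatError("no [Term] stanzas found; not an OBO document?")
    # edges to obsolete (absent) terms are dropped with the term
    for child, parent in pending_tax:
        if parent in g.concepts:
            g.add_taxonomic_edge(child, parent)
    for a, b, label in pending_other:
        if b in g.concepts:
            g.add_other_edge(a, b, label)
    if n_obsolete:
        logger.info("skipped %d obsolete OBO terms", n_obsolete)
    return g


@dataclass
class RRFConfig:
    """Column map for the pipe-delimited relations dialect.

    ``concept1_col``/``concept2_col``/``label_col`` are 0-based column
    indices.  Rows whose label is in ``hierarchical_labels`` become
    taxonomic edges; ``child_first`` controls the orientation (True means
    column 1 holds the child).
    """

    concept1_col: int = 0
    concept2_col: int = 1
    label_col: int = 2
    hierarchical_labels: frozenset[str] = frozenset({"PAR", "isa"})
    child_first: bool = True

    def __post_init__(self) -> None:
        self.hierarchical_labels = frozenset(self.hierarchical_labels)


def read_rrf_relations(stream: Iterable[str], config: RRFConfig) -> ConceptGraph:
    """Parse a pipe-delimited relations table into a :class:`ConceptGraph`.

    All rows contribute undirected ``other_edges``; rows carrying one of the
    configured hierarchical labels additionally become taxonomic edges.
    """
    g = ConceptGraph()
    n_rows = 0
    needed = max(config.concept1_col, config.concept2_col, config.label_col)
    from .errors import ConfigError

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("|")
        if len(fields) <= needed:
            raise ConfigError(
                f"line {lineno}: row has {len(fields)} columns but the "
                f"configured column map needs index {needed}"
            )
        c1 = fields[config.concept1_col].strip()
        c2 = fields[config.concept2_col].strip()
        label = fields[config.label_col].strip()
        if not c1 or not c2:
            raise ParseError("empty concept id", line=lineno)
        n_rows += 1
        g.add_other_edge(c1, c2, label)
        if label in config.hierarchical_labels:
            child, parent = (c1, c2) if config.child_first else (c2, c1)
            g.add_taxonomic_edge(child, parent)
    if n_rows == 0:
        logger.warning("relations table contained no rows; graph is empty")
    return g


# -- taxonomy construction ----------------------------------------------------


def _remove_cycles(
    concepts: Iterable[str], parents: dict[str, set[str]]
) -> list[tuple[str, str]]:
    """Drop back-edges from the parent relation, depth-first in lexicographic
    order.  Mutates ``parents``; returns the removed (child, parent) edges."""
    WHITE, GREY, BLACK = 0, 1, 2
    color = {c: WHITE for c in parents}
    removed: list[tuple[str, str]] = []
    for start in sorted(concepts):
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, Iterator[str]]] = [(start, iter(sorted(parents[start])))]
        color[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for parent in it:
                if parent not in parents[node]:
                    continue  # already removed
                if color[parent] == GREY:
                    parents[node].discard(parent)
                    removed.append((node, parent))
                elif color[parent] == WHITE:
                    color[parent] = GREY
                    stack.append((parent, iter(sorted(parents[parent]))))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()
    return removed


def build_taxonomy(g: ConceptGraph) -> Taxonomy:
    """Derive a rooted DAG taxonomy from a concept graph.

    Only ``taxonomic_edges`` are used.  Cycle-inducing edges are removed
    deterministically (lexicographic depth-first traversal, back-edges
    dropped as encountered) and recorded in ``removed_edges``.  If more than
    one concept ends up parentless, a synthetic root (:data:`VROOT`) is added
    as the parent of each.
    """
    if not g.concepts:
        raise OntosimError("cannot build a taxonomy from an empty concept set")
    parents: dict[str, set[str]] = {c: set() for c in g.concepts}
    for child, parent in g.taxonomic_edges:
        parents[child].add(parent)
    removed = _remove_cycles(g.concepts, parents)
    if removed:
        logger.info("removed %d cycle-inducing edges", len(removed))

    roots = sorted(c for c, ps in parents.items() if not ps)
    if len(roots) == 1:
        root = roots[0]
    else:
        root = VROOT
        while root in parents:
            root += "_"
        parents[root] = set()
        for r in roots:
            parents[r].add(root)
        if not g.taxonomic_edges:
            logger.warning(
                "graph has no taxonomic edges; all %d concepts attached "
                "directly to %s",
                len(g.concepts),
                root,
            )
    return Taxonomy(
        {c: frozenset(ps) for c, ps in parents.items()},
        root=root,
        removed_edges=removed,
        metadata=dict(g.metadata),
    )


# -- persistence --------------------------------------------------------------


def save_taxonomy(t: Taxonomy, path: str) -> None:
    """Write a versioned taxonomy artifact (deterministic JSON)."""
    doc = {
        "format": TAXONOMY_FORMAT_TAG,
        "version": TAXONOMY_FORMAT_VERSION,
        "root": t.root,
        "parents": {c: sorted(ps) for c, ps in sorted(t.parents.items())},
        "removed_edges": [list(e) for e in t.removed_edges],
        "metadata": t.metadata,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))


def load_taxonomy(path: str) -> Taxonomy:
    """Load an artifact written by :func:`save_taxonomy`.

    Structural caches (depth, leaf/subsumer counts) are recomputed on load;
    the computation is deterministic, so a round trip reproduces every field.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"not a taxonomy artifact: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != TAXONOMY_FORMAT_TAG:
        raise FormatError("not a taxonomy artifact (missing format tag)")
    version = doc.get("version")
    if version != TAXONOMY_FORMAT_VERSION:
        raise VersionError(
            f"artifact format version {version!r} is not supported "
            f"(this build reads version {TAXONOMY_FORMAT_VERSION})"
        )
    try:
        parents = {c: frozenset(ps) for c, ps in doc["parents"].items()}
        return Taxonomy(
            parents,
            root=doc["root"],
            removed_edges=[tuple(e) for e in doc["removed_edges"]],
            metadata=doc.get("metadata", {}),
        )
    except (KeyError, TypeError, AttributeError) as exc:
        raise FormatError(f"corrupt taxonomy artifact: {exc}") from exc


def read_graph(path: str, fmt: str, rrf_config: RRFConfig | None = None) -> ConceptGraph:
    """Dispatch to the reader for ``fmt`` (``edgelist``, ``obo`` or ``rrf``)."""
    with open(path, "r", encoding="utf-8") as fh:
        if fmt == "edgelist":
            return read_edge_list(fh)
        if fmt == "obo":
            return read_obo(fh)
        if fmt == "rrf":
            return read_rrf_relations(fh, rrf_config or RRFConfig())
    from .errors import ConfigError

    raise ConfigError(f"unknown input format: {fmt!r}")
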