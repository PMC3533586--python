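"""Pairwise structural quantities: ancestor distances, shortest taxonomic
path, and least common subsumer selection (path-minimal and IC-maximal).

Paths are constrained to up–up shapes: from one concept up to a common
subsumer and down to the other.  Path length is a node count, so identical
concepts are at path length 1.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .graph import Taxonomy

if TYPE_CHECKING:  # pragma: no cover
    from .ic import ICTable


@dataclass(frozen=True)
class PathResult:
    """Shortest-path outcome for a concept pair.

    ``p`` is the node count of the shortest taxonomic path (1 for identical
    concepts); ``lcs`` is the common subsumer on that path.
    """

    p: int
    lcs: str


def ancestors_with_distance(t: Taxonomy, c: str) -> dict[str, int]:
    """Map every ancestor-or-self of ``c`` to its minimum edge distance.

    ``c`` itself appears at distance 0.  Distances are minimal over all
    parent paths (Dijkstra on unit-weight parent edges, equivalent to BFS
    but robust to parent orderings).
    """
    t.require(c)
    dist: dict[str, int] = {}
    heap: list[tuple[int, str]] = [(0, c)]
    while heap:
        d, node = heapq.heappop(heap)
        if node in dist:
            continue
        dist[node] = d
        for p in t.parents[node]:
            if p not in dist:
                heapq.heappush(heap, (d + 1, p))
    return dist


def shortest_path(t: Taxonomy, c1: str, c2: str) -> PathResult:
    """Shortest taxonomic path between two concepts through a common subsumer.

    ``p = min_s [dist(c1, s) + dist(c2, s)] + 1`` over common subsumers
    ``s``, counted in nodes.  Ties between minimizing subsumers are broken
    by greater depth, then lexicographically by id.
    """
    a1 = ancestors_with_distance(t, c1)
    a2 = ancestors_with_distance(t, c2)
    best: tuple[int, int, str] | None = None
    for s, d1 in a1.items():
        d2 = a2.get(s)
        if d2 is None:
            continue
        key = (d1 + d2, -t.depth[s], s)
        if best is None or key < best:
            best = key
    assert best is not None, "VROOT guarantees a common subsumer"
    return PathResult(p=best[0] + 1, lcs=best[2])


def lcs_by_ic(t: Taxonomy, ic: "ICTable", c1: str, c2: str) -> str:
    """The common subsumer of maximal information content.

    Ties are broken lexicographically by id.  May differ from the
    path-minimal LCS; IC-based measures use this selection.
    """
    common = t.subsumers(c1) & t.subsumers(c2)
    best: str | None = None
    for s in sorted(common):
        if best is None or ic.values[s] > ic.values[best]:
            best = s
    assert best is not None
    return best
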