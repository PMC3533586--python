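"""Deterministic fixtures, random graph generators, and independent
brute-force oracles.

Everything here exists so the rest of the package can be exercised and
verified without downloading any external knowledge source.  The oracles
deliberately avoid the implementations they check: paths and LCS are found
by exhaustive enumeration over networkx ancestor sets, frequency
aggregation sums explicit descendant sets, personalized PageRank is a
dense linear solve, and Spearman is fractional ranking followed by a
textbook Pearson formula.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .evaluation import Benchmark
from .graph import ConceptGraph, Taxonomy
from .ppr import PPRGraph


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for :func:`random_dag`; the same seed always yields the
    same fixture."""

    seed: int
    n_concepts: int = 20
    max_parents: int = 3
    p_extra_edge: float = 0.0


def toy_T0() -> ConceptGraph:
    """The canonical 5-concept worked example.

    Concepts {R, A, B, C, D} with taxonomic edges C→A, D→A, A→R, B→R.
    Single root R; leaves {B, C, D}; depths (R, A, B, C, D) = (1, 2, 2, 3, 3).
    """
    g = ConceptGraph(metadata={"source": "toy_T0"})
    for child, parent in (("C", "A"), ("D", "A"), ("A", "R"), ("B", "R")):
        g.add_taxonomic_edge(child, parent)
    return g


def random_dag(spec: FixtureSpec) -> ConceptGraph:
    """Seed-deterministic random DAG.

    Concepts ``N000..`` are created in topological order; every concept
    after the first draws 1..max_parents parents from earlier concepts, so
    the result is acyclic and single-rooted at ``N000`` by construction.
    With probability ``p_extra_edge`` per concept, an extra labelled
    non-taxonomic edge is added between two random concepts.
    """
    rng = random.Random(spec.seed)
    names = [f"N{i:03d}" for i in range(spec.n_concepts)]
    g = ConceptGraph(metadata={"source": f"random_dag(seed={spec.seed})"})
    g.concepts.update(names[:1])
    for i in range(1, spec.n_concepts):
        k = rng.randint(1, min(spec.max_parents, i))
        for parent in rng.sample(names[:i], k):
            g.add_taxonomic_edge(names[i], parent)
    if spec.p_extra_edge > 0:
        for i in range(spec.n_concepts):
            if rng.random() < spec.p_extra_edge:
                a, b = rng.sample(names, 2)
                g.add_other_edge(a, b, "related_to")
    return g


# -- oracles ------------------------------------------------------------------


def _nx_parent_digraph(t: Taxonomy) -> nx.DiGraph:
    dg = nx.DiGraph()
    dg.add_nodes_from(t.parents)
    for child, ps in t.parents.items():
        for p in ps:
            dg.add_edge(child, p)  # edge points child -> parent
    return dg


def oracle_shortest_path(t: Taxonomy, c1: str, c2: str) -> tuple[int, str]:
    """Exhaustive up–up shortest path: enumerate every common subsumer and
    minimize the summed upward distances.  Returns (node count, lcs) with
    the same greater-depth / lexicographic tie-break as the module."""
    dg = _nx_parent_digraph(t)
    anc1 = nx.descendants(dg, c1) | {c1}  # "descendants" along child->parent
    anc2 = nx.descendants(dg, c2) | {c2}
    best = None
    for s in anc1 & anc2:
        d = nx.shortest_path_length(dg, c1, s) + nx.shortest_path_length(dg, c2, s)
        key = (d, -t.depth[s], s)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[0] + 1, best[2]


def oracle_lcs(t: Taxonomy, c1: str, c2: str) -> str:
    return oracle_shortest_path(t, c1, c2)[1]


def oracle_descendant_sum(t: Taxonomy, raw: dict[str, float]) -> dict[str, float]:
    """Aggregated frequencies via an explicit per-concept descendant set."""
    dg = _nx_parent_digraph(t)
    out: dict[str, float] = {}
    for c in t.parents:
        members = nx.ancestors(dg, c) | {c}  # concepts below c, plus c
        out[c] = sum(raw.get(m, 0.0) for m in members)
    return out


def oracle_ppr_dense(
    graph: PPRGraph, seed: str, damping: float = 0.85
) -> dict[str, float]:
    """Dense linear solve of (I - cM')P = (1-c)v, where M' augments the
    transition matrix so dangling-vertex columns teleport to the seed."""
    n = graph.n
    s = graph.index[seed]
    m = graph.matrix.toarray().astype(float)
    for i in range(n):
        if graph.outdegree[i] == 0:
            m[s, i] = 1.0
    v = np.zeros(n)
    v[s] = 1.0
    p = np.linalg.solve(np.eye(n) - damping * m, (1.0 - damping) * v)
    p /= p.sum()
    return {graph.concepts[i]: float(p[i]) for i in range(n)}


def oracle_spearman(x, y) -> float:
    """Fractional ranks by hand, then the textbook Pearson formula."""
    def frac_ranks(v):
        v = list(map(float, v))
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = frac_ranks(x), frac_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def synthetic_benchmark(
    t: Taxonomy,
    generating_measure,
    noise_sd: float = 0.0,
    n_pairs: int = 50,
    seed: int = 0,
    name: str = "synthetic",
) -> Benchmark:
    """A rating set whose truth is a known measure.

    Samples distinct unordered concept pairs and rates each with a strictly
    increasing transform of ``generating_measure(c1, c2)`` plus Gaussian
    noise of standard deviation ``noise_sd``.
    """
    rng = random.Random(seed)
    concepts = sorted(t.parents)
    seen: set[frozenset[str]] = set()
    pairs: list[tuple[str, str, float]] = []
    max_pairs = len(concepts) * (len(concepts) + 1) // 2
    n_pairs = min(n_pairs, max_pairs)
    while len(pairs) < n_pairs:
        c1, c2 = rng.choice(concepts), rng.choice(concepts)
        key = frozenset((c1, c2))
        if key in seen:
            continue
        seen.add(key)
        rating = 10.0 * generating_measure(c1, c2) + 1.0
        if noise_sd > 0:
            rating += rng.gauss(0.0, noise_sd)
        pairs.append((c1, c2, rating))
    return Benchmark(pairs=pairs, name=name)
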