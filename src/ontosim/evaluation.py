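"""Benchmark evaluation: Spearman rank correlation of measure outputs
against human ratings, and Fisher r-to-z tests between correlations.

The Fisher test implemented here is the independent-samples form (n-3
variance terms).  Correlations computed on the same benchmark are in fact
dependent; a dependent-correlations correction is deliberately out of
scope, so treat cross-measure p-values on a shared benchmark as
approximate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, OntosimError, ParseError, ValidationError
from .graph import Taxonomy
from .ic import ICTable
from .measures import ALL_MEASURES, IC_MEASURES, PATH_MEASURES
from .ppr import PPRGraph, PPRVector, ppr_relatedness, ppr_vector

logger = logging.getLogger(__name__)


@dataclass
class Benchmark:
    """Ordered list of (concept-1, concept-2, mean human rating) triples."""

    pairs: list[tuple[str, str, float]]
    name: str = "benchmark"

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CorrelationResult:
    measure: str
    rho: float
    n: int
    skipped: list[tuple[str, str]] = field(default_factory=list)


def read_benchmark(stream: Iterable[str], name: str = "benchmark") -> Benchmark:
    """Parse ``concept1<TAB>concept2<TAB>rating`` lines, preserving order.

    Duplicate unordered pairs and non-numeric ratings are rejected with the
    offending line number.
    """
    pairs: list[tuple[str, str, float]] = []
    seen: set[frozenset[str]] = set()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError("expected concept1<TAB>concept2<TAB>rating", line=lineno)
        c1, c2 = fields[0].strip(), fields[1].strip()
        try:
            rating = float(fields[2])
        except ValueError as exc:
            raise ParseError(f"non-numeric rating {fields[2]!r}", line=lineno) from exc
        if not math.isfinite(rating):
            raise ParseError(f"non-finite rating {rating}", line=lineno)
        key = frozenset((c1, c2)) if c1 != c2 else frozenset((c1,))
        if key in seen:
            raise ValidationError(
                f"line {lineno}: duplicate unordered pair ({c1}, {c2})"
            )
        seen.add(key)
        pairs.append((c1, c2, rating))
    return Benchmark(pairs=pairs, name=name)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with fractional (average) rank ties.

    Equivalent to the Pearson correlation of the two rank vectors, which is
    exact in the presence of ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise OntosimError("input vectors differ in length")
    if x.size < 3:
        raise OntosimError(f"need at least 3 observations, got {x.size}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise OntosimError("zero rank variance: a vector is constant")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sided test of r1 vs r2 via the Fisher variance-stabilizing
    transform: ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``."""
    if n1 <= 3 or n2 <= 3:
        raise OntosimError("Fisher r-to-z needs n > 3 in both samples")
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise OntosimError("|r| must be < 1 (atanh diverges at ±1)")
    if r1 == r2:
        return 0.0, 1.0
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return z, float(p)


PPR_MEASURES = ("ppr-taxonomy", "ppr-all")


def make_scorer(
    measure: str,
    t: Taxonomy | None = None,
    ic: ICTable | None = None,
    ppr_graphs: dict[str, PPRGraph] | None = None,
    damping: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> Callable[[str, str], float]:
    """Bind a named measure to its inputs, returning a pair-scoring callable.

    PPR scorers cache one vector per concept across calls.
    """
    if measure in PATH_MEASURES:
        if t is None:
            raise ConfigError(f"measure {measure!r} requires a taxonomy")
        fn = PATH_MEASURES[measure]
        return lambda c1, c2: fn(t, c1, c2)
    if measure in IC_MEASURES:
        if t is None or ic is None:
            raise ConfigError(f"measure {measure!r} requires a taxonomy and IC table")
        fn = IC_MEASURES[measure]
        return lambda c1, c2: fn(t, ic, c1, c2)
    if measure in PPR_MEASURES:
        mode = measure.split("-", 1)[1]
        if not ppr_graphs or mode not in ppr_graphs:
            raise ConfigError(f"measure {measure!r} requires a {mode!r} PPR graph")
        graph = ppr_graphs[mode]
        cache: dict[str, PPRVector] = {}

        def ppr_score(c1: str, c2: str) -> float:
            for c in (c1, c2):
                if c not in cache:
                    cache[c] = ppr_vector(
                        graph, c, damping=damping, tol=tol, max_iter=max_iter
                    )
            return ppr_relatedness(cache[c1], cache[c2])

        return ppr_score
    raise ConfigError(
        f"unknown measure {measure!r}; known: "
        f"{', '.join(ALL_MEASURES + PPR_MEASURES)}"
    )


def _covers(measure: str, c: str, t: Taxonomy | None, ppr_graphs) -> bool:
    if measure in PPR_MEASURES:
        mode = measure.split("-", 1)[1]
        return c in ppr_graphs[mode].index
    return t is not None and c in t


def evaluate(
    benchmark: Benchmark,
    measures: Sequence[str],
    t: Taxonomy | None = None,
    ic: ICTable | None = None,
    ppr_graphs: dict[str, PPRGraph] | None = None,
    compare: bool = False,
    damping: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> tuple[list[CorrelationResult], pd.DataFrame | None]:
    """Correlate each measure with the benchmark ratings.

    Pairs containing a concept the measure's graph cannot resolve are
    skipped (never scored 0) and reported in ``CorrelationResult.skipped``.
    With ``compare=True`` a symmetric DataFrame of Fisher r-to-z p-values
    between all measure pairs is also returned.
    """
    results: list[CorrelationResult] = []
    for measure in measures:
        scorer = make_scorer(
            measure, t=t, ic=ic, ppr_graphs=ppr_graphs,
            damping=damping, tol=tol, max_iter=max_iter,
        )
        xs: list[float] = []
        ys: list[float] = []
        skipped: list[tuple[str, str]] = []
        for c1, c2, rating in benchmark.pairs:
            if not (_covers(measure, c1, t, ppr_graphs)
                    and _covers(measure, c2, t, ppr_graphs)):
                skipped.append((c1, c2))
                continue
            xs.append(scorer(c1, c2))
            ys.append(rating)
        if skipped:
            logger.info(
                "%s: skipped %d/%d pairs with unresolvable concepts",
                measure, len(skipped), len(benchmark),
            )
        rho = spearman(xs, ys)
        results.append(
            CorrelationResult(measure=measure, rho=rho, n=len(xs), skipped=skipped)
        )

    matrix: pd.DataFrame | None = None
    if compare:
        names = [r.measure for r in results]
        matrix = pd.DataFrame(np.ones((len(names), len(names))),
                              index=names, columns=names)
        for i, a in enumerate(results):
            for j, b in enumerate(results):
                if i < j:
                    try:
                        _, p = fisher_r_to_z(a.rho, a.n, b.rho, b.n)
                    except OntosimError:  # |rho| = 1 or tiny n: untestable
                        p = float("nan")
                    matrix.iloc[i, j] = matrix.iloc[j, i] = p
    return results, matrix


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tabulate results with columns measure, rho, n, skipped."""
    return pd.DataFrame(
        {
            "measure": [r.measure for r in results],
            "rho": [r.rho for r in results],
            "n": [r.n for r in results],
            "skipped": [len(r.skipped) for r in results],
        }
    )
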