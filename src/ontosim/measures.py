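"""The pairwise similarity measures.

Path-based: Path (inverse path length), a unit-interval scaled
Leacock–Chodorow, and the self-similarity-corrected Wu & Palmer.
IC-based: Lin, the Jiang–Conrath distance, and IC reformulations of LCH
and Path built on that distance.

All similarities map into [0, 1], are symmetric, and score identical
concepts as exactly 1; the Jiang–Conrath distance is ≥ 0 with 0 for
identical concepts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .graph import Taxonomy
from .ic import ICTable
from .pairwise import lcs_by_ic, shortest_path


@dataclass(frozen=True)
class SimilarityScore:
    """A scored concept pair: ``value`` under measure ``measure``."""

    value: float
    measure: str
    pair: tuple[str, str]


def sim_path(t: Taxonomy, c1: str, c2: str) -> float:
    """Inverse of the node-count shortest path: ``1/p``."""
    return 1.0 / shortest_path(t, c1, c2).p


def sim_lch(t: Taxonomy, c1: str, c2: str) -> float:
    """Log-scaled path measure on the unit interval: ``1 - log(p)/log(2d)``."""
    p = shortest_path(t, c1, c2).p
    return 1.0 - math.log(p) / math.log(2 * t.d)


def sim_wupalmer(t: Taxonomy, c1: str, c2: str) -> float:
    """Depth-of-LCS measure: ``2·depth(lcs) / ((p - 1) + 2·depth(lcs))``.

    The ``p - 1`` in the denominator (rather than ``p + 1``) makes the
    self-similarity exactly 1.
    """
    res = shortest_path(t, c1, c2)
    dl = t.depth[res.lcs]
    return 2.0 * dl / ((res.p - 1) + 2.0 * dl)


def sim_lin(t: Taxonomy, ic: ICTable, c1: str, c2: str) -> float:
    """``2·IC(lcs) / (IC(c1) + IC(c2))`` with the IC-maximal LCS.

    Identical concepts score 1 by convention even at IC 0 (the root); a
    zero denominator otherwise scores 0.
    """
    t.require(c1)
    t.require(c2)
    if c1 == c2:
        return 1.0
    denom = ic.values[c1] + ic.values[c2]
    if denom == 0.0:
        return 0.0
    return 2.0 * ic.values[lcs_by_ic(t, ic, c1, c2)] / denom


def dist_jc(t: Taxonomy, ic: ICTable, c1: str, c2: str) -> float:
    """Jiang–Conrath semantic distance: ``IC(c1) + IC(c2) - 2·IC(lcs)``."""
    t.require(c1)
    t.require(c2)
    if c1 == c2:
        return 0.0
    d = ic.values[c1] + ic.values[c2] - 2.0 * ic.values[lcs_by_ic(t, ic, c1, c2)]
    assert d >= -1e-12, f"negative Jiang-Conrath distance {d} for ({c1}, {c2})"
    return max(d, 0.0)


def sim_lch_ic(t: Taxonomy, ic: ICTable, c1: str, c2: str) -> float:
    """IC reformulation of LCH: ``1 - log(dist_jc + 1) / log(2·ic_max + 1)``.

    The ``+ 1`` terms keep the logs finite and the value in [0, 1].
    """
    d = dist_jc(t, ic, c1, c2)
    if ic.ic_max == 0.0:
        return 1.0  # degenerate taxonomy: every distance is 0
    return 1.0 - math.log(d + 1.0) / math.log(2.0 * ic.ic_max + 1.0)


def sim_path_ic(t: Taxonomy, ic: ICTable, c1: str, c2: str) -> float:
    """IC reformulation of Path: ``1 / (dist_jc + 1)``."""
    return 1.0 / (dist_jc(t, ic, c1, c2) + 1.0)


#: measures that need only the taxonomy
PATH_MEASURES = {
    "path": sim_path,
    "lch": sim_lch,
    "wupalmer": sim_wupalmer,
}

#: measures that additionally need an ICTable
IC_MEASURES = {
    "lin": sim_lin,
    "jc": dist_jc,
    "lch-ic": sim_lch_ic,
    "path-ic": sim_path_ic,
}

#: every similarity measure bounded to [0, 1] (excludes the jc distance)
SIMILARITY_MEASURES = ("path", "lch", "wupalmer", "lin", "lch-ic", "path-ic")

ALL_MEASURES = tuple(PATH_MEASURES) + tuple(IC_MEASURES)


def score(
    measure: str, t: Taxonomy, c1: str, c2: str, ic: ICTable | None = None
) -> SimilarityScore:
    """Score a pair under a named measure (see :data:`ALL_MEASURES`)."""
    if measure in PATH_MEASURES:
        value = PATH_MEASURES[measure](t, c1, c2)
    elif measure in IC_MEASURES:
        if ic is None:
            from .errors import ConfigError

            raise ConfigError(f"measure {measure!r} requires an IC table")
        value = IC_MEASURES[measure](t, ic, c1, c2)
    else:
        from .errors import ConfigError

        raise ConfigError(f"unknown measure: {measure!r}")
    return SimilarityScore(value=value, measure=measure, pair=(c1, c2))
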