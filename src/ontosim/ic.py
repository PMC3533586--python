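"""Information content: intrinsic (from taxonomy structure) and corpus
(from raw concept frequencies).

Intrinsic IC follows the leaves-to-subsumers formulation: concepts with
many descendant leaves relative to their number of ancestors carry little
information.  Corpus IC is the negative log of a concept's aggregated
frequency normalized by the root's aggregated frequency, so the root has
IC 0 and all values are non-negative.  Natural logarithms throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import OntosimError, ParseError, ValidationError
from .graph import Taxonomy

logger = logging.getLogger(__name__)


@dataclass
class ICTable:
    """Per-concept information content values.

    ``kind`` is ``"intrinsic"`` or ``"corpus"``; ``ic_max`` caches the
    maximum value over all concepts.
    """

    values: dict[str, float]
    kind: str
    ic_max: float


@dataclass
class FrequencyTable:
    """Raw and taxonomy-aggregated concept counts.

    ``aggregated[c]`` sums the raw counts over the *set* ``{c} ∪
    descendants(c)`` — each descendant contributes once no matter how many
    parent paths reach it.
    """

    raw: dict[str, float]
    aggregated: dict[str, float]


def intrinsic_ic(t: Taxonomy) -> ICTable:
    """Structure-only IC: ``-log((n_leaves/n_subsumers + 1) / (max_leaves + 1))``.

    The root scores exactly 0; IC strictly increases from parent to child.
    """
    ml1 = t.max_leaves + 1
    values = {
        c: -math.log((t.n_leaves[c] / t.n_subsumers[c] + 1) / ml1)
        for c in t.parents
    }
    # root: leaves/subsumers = max_leaves/1, ratio is exactly 1
    values[t.root] = 0.0
    return ICTable(values=values, kind="intrinsic", ic_max=max(values.values()))


def aggregate_frequencies(t: Taxonomy, raw: Mapping[str, float]) -> FrequencyTable:
    """Aggregate raw counts over descendant sets.

    Concepts absent from ``raw`` count as 0; counts for unknown ids are
    ignored with a warning; negative counts are rejected.
    """
    unknown = [c for c in raw if c not in t.parents]
    if unknown:
        logger.warning(
            "ignoring counts for %d ids not in the taxonomy (e.g. %r)",
            len(unknown),
            unknown[0],
        )
    clean: dict[str, float] = {}
    for c in t.parents:
        v = float(raw.get(c, 0.0))
        if v < 0:
            raise ValidationError(f"negative count for {c!r}: {v}")
        clean[c] = v

    # descendant sets via reverse topological order (children first);
    # set union avoids double counting through diamond motifs
    desc: dict[str, frozenset[str]] = {}
    aggregated: dict[str, float] = {}
    for node in reversed(t.topological_order()):
        acc: set[str] = {node}
        for k in t.children[node]:
            acc |= desc[k]
        fs = frozenset(acc)
        desc[node] = fs
        aggregated[node] = sum(clean[x] for x in fs)
    return FrequencyTable(raw=clean, aggregated=aggregated)


def corpus_ic(t: Taxonomy, f: FrequencyTable) -> ICTable:
    """Corpus IC: ``-log(aggregated(c) / aggregated(root))``.

    Concepts with aggregated frequency 0 are capped at the maximum finite
    IC observed rather than +inf, so downstream measures stay defined.
    """
    total = f.aggregated[t.root]
    if total <= 0:
        raise OntosimError(
            "total corpus frequency is 0; corpus IC is undefined "
            "(provide at least one non-zero raw count)"
        )
    values: dict[str, float] = {}
    finite_max = 0.0
    zeros: list[str] = []
    for c in t.parents:
        a = f.aggregated[c]
        if a > 0:
            v = -math.log(a / total)
            values[c] = max(v, 0.0)
            finite_max = max(finite_max, values[c])
        else:
            zeros.append(c)
    for c in zeros:
        values[c] = finite_max
    return ICTable(values=values, kind="corpus", ic_max=max(values.values()))


def read_frequencies(stream: Iterable[str]) -> dict[str, float]:
    """Parse ``concept<TAB>raw_count`` lines ('#' comments allowed)."""
    raw: dict[str, float] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError("expected concept<TAB>count", line=lineno)
        try:
            count = float(fields[1])
        except ValueError as exc:
            raise ParseError(f"non-numeric count {fields[1]!r}", line=lineno) from exc
        raw[fields[0].strip()] = raw.get(fields[0].strip(), 0.0) + count
    return raw
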