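"""Best match / best close match identification and multi-level success
rates (leave-one-out over a reference library).

Under "best match" a query is assigned the label(s) of its nearest
neighbour(s) in the distance matrix; ties at the minimal distance are all
retained, which is what makes the "ambiguous" category well-defined.
"Best close match" additionally rejects queries whose nearest neighbour
lies beyond a distance threshold, by convention the 95th percentile
(nearest rank) of all intra-species pairwise distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix

CATEGORIES = ("correct", "ambiguous", "misidentified", "no_match")


class IdentificationError(ValueError):
    pass


@dataclass(frozen=True)
class MatchResult:
    query: str
    best_hits: tuple[str, ...]
    best_distance: float
    assigned_labels: frozenset[str]
    true_label: str
    category: str          # one of CATEGORIES, or "unevaluable"
    threshold: float | None = None


@dataclass(frozen=True)
class IdentificationSummary:
    level: str
    criterion: str                      # best_match | best_close_match
    counts: dict[str, int]              # category -> count
    n: int                              # evaluable queries
    n_singletons: int                   # queries with no same-label partner
    unevaluable: tuple[str, ...]        # queries with no defined distance
    threshold: float | None = None

    @property
    def fractions(self) -> dict[str, float]:
        return {c: (self.counts[c] / self.n if self.n else math.nan)
                for c in CATEGORIES}

    @property
    def percentages(self) -> dict[str, int]:
        """Integer percentages in the style of published success tables."""
        return {c: round(100.0 * self.counts[c] / self.n) if self.n else 0
                for c in CATEGORIES}


def _categorize(hit_labels: frozenset[str], true_label: str) -> str:
    if hit_labels == {true_label}:
        return "correct"
    if true_label in hit_labels:
        return "ambiguous"
    return "misidentified"


def best_match(dm: DistanceMatrix, labels: dict[str, str], query: str,
               exclude: set[str] | frozenset[str] = frozenset()
               ) -> MatchResult:
    """Nearest-neighbour identification of one query against all others.

    ``exclude`` removes reference ids from consideration (the query itself
    is always excluded). A query with no defined distance to any reference
    is flagged ``unevaluable``.
    """
    return best_close_match(dm, labels, query, math.inf, exclude,
                            _criterion="best_match")


def best_close_match(dm: DistanceMatrix, labels: dict[str, str], query: str,
                     threshold: float,
                     exclude: set[str] | frozenset[str] = frozenset(),
                     _criterion: str = "best_close_match") -> MatchResult:
    """Best match with rejection: best distance above threshold → no_match."""
    qi = dm.index(query)
    true_label = labels[query]
    best_d, hits = math.inf, []
    for j, sid in enumerate(dm.ids):
        if sid == query or sid in exclude or not dm.defined[qi, j]:
            continue
        d = dm.matrix[qi, j]
        if d < best_d - 1e-15:
            best_d, hits = d, [sid]
        elif abs(d - best_d) <= 1e-15:
            hits.append(sid)
    thr = None if _criterion == "best_match" else threshold
    if not hits:
        return MatchResult(query, (), math.nan, frozenset(), true_label,
                           "unevaluable", thr)
    hit_labels = frozenset(labels[h] for h in hits)
    if best_d > threshold:
        cat = "no_match"
    else:
        cat = _categorize(hit_labels, true_label)
    return MatchResult(query, tuple(hits), best_d, hit_labels, true_label,
                       cat, thr)


def intraspecific_threshold(dm: DistanceMatrix, species: dict[str, str],
                            percentile: float = 95.0,
                            exclude: set[str] | frozenset[str] = frozenset()
                            ) -> float:
    """Nearest-rank percentile of pooled intra-species pairwise distances.

    With n sorted values the p-th nearest-rank percentile is the
    ceil(p/100 * n)-th smallest; percentile 100 gives the maximum.
    """
    vals = []
    for i in range(len(dm.ids)):
        if dm.ids[i] in exclude:
            continue
        for j in range(i + 1, len(dm.ids)):
            if dm.ids[j] in exclude or not dm.defined[i, j]:
                continue
            if species[dm.ids[i]] == species[dm.ids[j]]:
                vals.append(float(dm.matrix[i, j]))
    if not vals:
        raise IdentificationError(
            "no intra-species pairs with defined distances "
            "(all species singletons?)")
    vals.sort()
    rank = max(1, math.ceil(percentile / 100.0 * len(vals)))
    return vals[min(rank, len(vals)) - 1]


def relabel(species: dict[str, str], mapping: dict[str, str]
            ) -> dict[str, str]:
    """Coarsen a species-level map via species → group mapping."""
    missing = sorted(set(species.values()) - set(mapping))
    if missing:
        raise IdentificationError(
            f"mapping lacks entries for species: {missing}")
    return {sid: mapping[sp] for sid, sp in species.items()}


def success_rates(dm: DistanceMatrix, labels: dict[str, str],
                  criterion: str = "best_match",
                  threshold: float | None = None,
                  exclude: set[str] | frozenset[str] = frozenset(),
                  level: str = "species",
                  collect: bool = False
                  ) -> IdentificationSummary | tuple[
                      IdentificationSummary, list[MatchResult]]:
    """Leave-one-out identification of every sequence against the rest.

    Queries with zero defined distances are excluded from the denominator
    and listed. Singletons at the evaluation level (no other sequence with
    the same label) can never be "correct" and are counted separately so
    success tables remain comparable across levels.
    """
    if criterion not in ("best_match", "best_close_match"):
        raise IdentificationError(f"unknown criterion {criterion!r}")
    if criterion == "best_close_match" and threshold is None:
        raise IdentificationError("best_close_match requires a threshold")
    thr = math.inf if criterion == "best_match" else threshold
    counts = {c: 0 for c in CATEGORIES}
    results, unevaluable, n_singletons = [], [], 0
    label_tally: dict[str, int] = {}
    queries = [s for s in dm.ids if s not in exclude]
    for q in queries:
        label_tally[labels[q]] = label_tally.get(labels[q], 0) + 1
    for q in queries:
        r = best_close_match(dm, labels, q, thr, exclude,
                             _criterion=criterion)
        if r.category == "unevaluable":
            unevaluable.append(q)
            continue
        counts[r.category] += 1
        if label_tally[labels[q]] == 1:
            n_singletons += 1
        results.append(r)
    summary = IdentificationSummary(
        level, criterion, counts, sum(counts.values()), n_singletons,
        tuple(unevaluable), None if criterion == "best_match" else threshold)
    return (summary, results) if collect else summary
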