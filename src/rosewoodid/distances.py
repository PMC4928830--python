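"""Kimura 2-parameter pairwise distances with pairwise deletion, and
intra-/inter-label distance distributions.

The K2P model corrects the observed proportions of transition (P) and
transversion (Q) differences for multiple hits:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence carries a gap, missing symbol, or any IUPAC
ambiguity code are excluded pair-by-pair (pairwise deletion). When the
logarithm's argument is non-positive the distance is undefined and masked,
never coerced to a large number — coercion would silently distort
nearest-neighbour ranking downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment_io import LabeledAlignment

# Encoding: A,C,G,T -> 0..3; everything else (gap, ?, N, ambiguity) -> 255.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_PURINE = np.array([True, False, True, False])  # A, G


class DistanceError(ValueError):
    pass


@dataclass(frozen=True)
class SitePairCounts:
    """Per-pair site tallies under pairwise deletion."""

    n_compared: int
    n_transitions: int
    n_transversions: int

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_compared if self.n_compared else 0.0

    @property
    def Q(self) -> float:
        return (self.n_transversions / self.n_compared
                if self.n_compared else 0.0)


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def site_pair_counts(a: str | np.ndarray, b: str | np.ndarray
                     ) -> SitePairCounts:
    ea = encode(a) if isinstance(a, str) else a
    eb = encode(b) if isinstance(b, str) else b
    if ea.shape != eb.shape:
        raise DistanceError(
            f"length mismatch: {ea.size} vs {eb.size}")
    valid = (ea < 4) & (eb < 4)
    diff = valid & (ea != eb)
    ts = diff & (_PURINE[ea % 4] == _PURINE[eb % 4])
    return SitePairCounts(int(valid.sum()), int(ts.sum()),
                          int(diff.sum() - ts.sum()))


def k2p_from_counts(c: SitePairCounts) -> float:
    """K2P distance from site counts; NaN when undefined."""
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0   # -0.0 -> 0.0


def p_from_counts(c: SitePairCounts) -> float:
    """Uncorrected p-distance from the same site counts."""
    return (c.n_transitions + c.n_transversions) / c.n_compared


def k2p_distance(a: str, b: str, min_overlap: int = 1,
                 model: str = "k2p") -> tuple[float, SitePairCounts]:
    """Distance between two aligned sequences.

    Returns ``(distance, counts)``; the distance is NaN when fewer than
    ``min_overlap`` sites are comparable or the K2P correction is undefined.
    Raises on length mismatch or zero comparable sites.
    """
    c = site_pair_counts(a, b)
    if c.n_compared == 0:
        raise DistanceError("no comparable sites between the two sequences")
    if c.n_compared < min_overlap:
        return math.nan, c
    if model == "p":
        return p_from_counts(c), c
    return k2p_from_counts(c), c


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with a validity mask.

    ``defined[i, j]`` is False where the pair's distance is undefined
    (insufficient overlap or K2P correction impossible); ``matrix`` holds
    NaN there.
    """

    ids: list[str]
    matrix: np.ndarray
    defined: np.ndarray
    n_compared: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        assert self.matrix.shape == (n, n)

    def index(self, sample_id: str) -> int:
        return self.ids.index(sample_id)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.index(a), self.index(b)])

    def to_phylip(self) -> str:
        lines = [f" {len(self.ids)}"]
        for i, sid in enumerate(self.ids):
            row = " ".join(f"{self.matrix[i, j]:.8f}"
                           if self.defined[i, j] else "NA"
                           for j in range(len(self.ids)))
            lines.append(f"{sid}  {row}")
        return "\n".join(lines) + "\n"

    def to_long_tsv(self, marker: str = "all") -> str:
        out = ["id_a\tid_b\tmarker\tdistance\tn_compared\tdefined"]
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                d = f"{self.matrix[i, j]:.8f}" if self.defined[i, j] else "NA"
                out.append(f"{self.ids[i]}\t{self.ids[j]}\t{marker}\t{d}\t"
                           f"{int(self.n_compared[i, j])}\t"
                           f"{int(self.defined[i, j])}")
        return "\n".join(out) + "\n"


def pairwise_matrix(aln: LabeledAlignment, min_overlap: int = 1,
                    markers: list[str] | None = None,
                    model: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix, optionally restricted to some markers.

    Per-pair failures (zero overlap, undefined correction) become masked
    entries, not exceptions.
    """
    if len(aln) < 2:
        raise DistanceError("need at least 2 sequences")
    sub = aln.restrict(markers) if markers is not None else aln
    enc = [encode(s) for s in sub.sequences]
    n = len(enc)
    dist = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    ncmp = np.zeros((n, n))
    for i in range(n):
        ncmp[i, i] = int((enc[i] < 4).sum())
        for j in range(i + 1, n):
            c = site_pair_counts(enc[i], enc[j])
            if c.n_compared < max(min_overlap, 1):
                d = math.nan
            elif model == "p":
                d = p_from_counts(c)
            else:
                d = k2p_from_counts(c)
            dist[i, j] = dist[j, i] = d
            ok = not math.isnan(d)
            defined[i, j] = defined[j, i] = ok
            ncmp[i, j] = ncmp[j, i] = c.n_compared
    return DistanceMatrix(list(sub.samples), dist, defined, ncmp)


@dataclass(frozen=True)
class DistanceSummary:
    """Intra- vs inter-label distance distribution at one label level."""

    level: str
    n_intra: int
    n_inter: int
    n_undefined: int
    mean_intra: float
    range_intra: tuple[float, float]
    mean_inter: float
    range_inter: tuple[float, float]
    frac_inter_below: float
    epsilon: float


def distance_summary(dm: DistanceMatrix, labels: dict[str, str],
                     exclude: set[str] | frozenset[str] = frozenset(),
                     level: str = "species",
                     epsilon: float = 0.002) -> DistanceSummary:
    """Summarise intra- and inter-label pairwise distances.

    ``exclude`` drops ids (typically the outgroup) from both pools.
    Undefined pairs are excluded and counted. Singleton labels contribute
    no intra pairs. ``frac_inter_below`` is the share of inter-label
    distances under ``epsilon`` (near-zero divergence between labels).
    """
    keep = [i for i, sid in enumerate(dm.ids) if sid not in exclude]
    for i in keep:
        if dm.ids[i] not in labels:
            raise DistanceError(f"id {dm.ids[i]!r} unlabeled at {level!r}")
    intra, inter, undef = [], [], 0
    for ai in range(len(keep)):
        for bi in range(ai + 1, len(keep)):
            i, j = keep[ai], keep[bi]
            if not dm.defined[i, j]:
                undef += 1
                continue
            d = dm.matrix[i, j]
            if labels[dm.ids[i]] == labels[dm.ids[j]]:
                intra.append(d)
            else:
                inter.append(d)

    def stats(vals):
        if not vals:
            return math.nan, (math.nan, math.nan)
        return float(np.mean(vals)), (float(min(vals)), float(max(vals)))

    mi, ri = stats(intra)
    me, re_ = stats(inter)
    frac = (sum(1 for d in inter if d < epsilon) / len(inter)
            if inter else math.nan)
    return DistanceSummary(level, len(intra), len(inter), undef,
                           mi, ri, me, re_, frac, epsilon)
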