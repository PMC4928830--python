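"""Labeled multi-marker alignments: reading, validation, concatenation,
haplotype collapsing, and coordinate conventions.

All user-facing coordinates are 1-based inclusive on the concatenated
alignment (the convention of published diagnostic-position tables).
Internally, Python slices (0-based half-open) are used but never serialized.
"""

from __future__ import annotations

import io
from collections import OrderedDict
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

# IUPAC nucleotide codes, '-' for alignment gaps, '?' for missing data.
IUPAC_BASES = frozenset("ACGT")
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")
GAP_CHARS = frozenset("-?")
VALID_CHARS = IUPAC_BASES | IUPAC_AMBIGUITY | GAP_CHARS

#: Expansion of every IUPAC code into the set of plain bases it denotes.
IUPAC_EXPANSION = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

RESERVED_LEVELS = ("species", "level1", "level2")

METADATA_COLUMNS = ["sample_id", "species", "level1", "level2", "outgroup",
                    "region"]


class AlignmentError(ValueError):
    """Invalid alignment input (lengths, alphabet, metadata join)."""


@dataclass(frozen=True)
class PartitionMap:
    """Ordered markers with 1-based inclusive spans on the concatenation.

    Spans are contiguous, non-overlapping and cover ``1..total_length``.
    """

    partitions: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        if not self.partitions:
            raise AlignmentError("empty partition map")
        names = [p[0] for p in self.partitions]
        if len(set(names)) != len(names):
            raise AlignmentError(f"duplicate marker names in {names}")
        expect = 1
        for name, start, end in self.partitions:
            if start != expect or end < start:
                raise AlignmentError(
                    f"partition {name!r} [{start},{end}] not contiguous "
                    f"(expected start {expect})")
            expect = end + 1

    @classmethod
    def from_lengths(cls, items: list[tuple[str, int]]) -> "PartitionMap":
        spans, pos = [], 1
        for name, length in items:
            spans.append((name, pos, pos + length - 1))
            pos += length
        return cls(tuple(spans))

    @property
    def total_length(self) -> int:
        return self.partitions[-1][2]

    @property
    def markers(self) -> list[str]:
        return [p[0] for p in self.partitions]

    def span(self, marker: str) -> tuple[int, int]:
        for name, start, end in self.partitions:
            if name == marker:
                return start, end
        raise KeyError(marker)

    def slice(self, marker: str) -> slice:
        """0-based half-open slice for a marker (internal use)."""
        start, end = self.span(marker)
        return slice(start - 1, end)

    def marker_of(self, position: int) -> str:
        """Marker containing a 1-based concatenated position."""
        for name, start, end in self.partitions:
            if start <= position <= end:
                return name
        raise KeyError(f"position {position} outside 1..{self.total_length}")

    def to_text(self) -> str:
        """RAxML-style partition text, e.g. ``DNA, matK = 1-565``."""
        return "\n".join(f"DNA, {n} = {s}-{e}"
                         for n, s, e in self.partitions) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PartitionMap":
        spans = []
        for line in text.strip().splitlines():
            left, right = line.split("=")
            name = left.split(",")[1].strip()
            s, e = right.strip().split("-")
            spans.append((name, int(s), int(e)))
        return cls(tuple(spans))


@dataclass
class LabeledAlignment:
    """Aligned sequences plus per-sample labels at several taxonomic levels.

    ``labels`` maps a level name ("species", "level1", "level2", ...) to a
    sample→label dict. Every sample must carry a "species" label; any other
    level present must cover all samples.
    """

    samples: list[str]
    sequences: list[str]
    labels: dict[str, dict[str, str]]
    partitions: PartitionMap
    outgroup_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        self.outgroup_ids = frozenset(self.outgroup_ids)
        if len(self.samples) != len(self.sequences):
            raise AlignmentError("samples/sequences length mismatch")
        if len(set(self.samples)) != len(self.samples):
            raise AlignmentError("duplicate sample IDs")
        self.sequences = [s.upper() for s in self.sequences]
        L = self.partitions.total_length
        for sid, seq in zip(self.samples, self.sequences):
            if len(seq) != L:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(seq)}, expected {L}")
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains invalid characters {sorted(bad)}")
        if "species" not in self.labels:
            raise AlignmentError('missing "species" label level')
        for level, mapping in self.labels.items():
            missing = set(self.samples) - set(mapping)
            if missing:
                raise AlignmentError(
                    f"level {level!r} lacks labels for {sorted(missing)}")
        if not self.outgroup_ids <= set(self.samples):
            raise AlignmentError("outgroup_ids not a subset of samples")

    # -- convenience -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def length(self) -> int:
        return self.partitions.total_length

    def sequence_of(self, sample: str) -> str:
        return self.sequences[self.samples.index(sample)]

    def labels_at(self, level: str) -> dict[str, str]:
        return self.labels[level]

    def restrict(self, markers: list[str]) -> "LabeledAlignment":
        """Sub-alignment over the given markers, in the given order."""
        slices = [self.partitions.slice(m) for m in markers]
        newparts = PartitionMap.from_lengths(
            [(m, sl.stop - sl.start) for m, sl in zip(markers, slices)])
        seqs = ["".join(seq[sl] for sl in slices) for seq in self.sequences]
        return LabeledAlignment(list(self.samples), seqs,
                                {lv: dict(mp) for lv, mp in self.labels.items()},
                                newparts, self.outgroup_ids)

    def drop(self, sample_ids) -> "LabeledAlignment":
        drop = set(sample_ids)
        keep = [i for i, s in enumerate(self.samples) if s not in drop]
        return LabeledAlignment(
            [self.samples[i] for i in keep],
            [self.sequences[i] for i in keep],
            {lv: {s: l for s, l in mp.items() if s not in drop}
             for lv, mp in self.labels.items()},
            self.partitions,
            self.outgroup_ids - drop)

    def to_fasta(self, handle) -> None:
        close = False
        if isinstance(handle, str):
            handle, close = open(handle, "w"), True
        try:
            for sid, seq in zip(self.samples, self.sequences):
                handle.write(f">{sid}\n{seq}\n")
        finally:
            if close:
                handle.close()


@dataclass(frozen=True)
class HaplotypeMap:
    """Assignment of samples to distinct-sequence haplotypes."""

    representative: dict[str, str]      # haplotype ID -> sequence
    assignment: dict[str, str]          # sample ID -> haplotype ID
    label_sets: dict[str, dict[str, frozenset[str]]]  # level -> hap -> labels

    def members(self, hap_id: str) -> list[str]:
        return [s for s, h in self.assignment.items() if h == hap_id]


# ---------------------------------------------------------------------------
# Reading


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"sample_id", "species"} - set(df.columns)
    if missing:
        raise AlignmentError(f"metadata missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise AlignmentError(f"duplicate sample_id in metadata: {dups}")
    return df.set_index("sample_id", drop=False)


def read_labeled_alignment(fasta_paths: "OrderedDict[str, object] | dict",
                           metadata_path) -> list[LabeledAlignment]:
    """Read one aligned FASTA per marker plus a metadata TSV.

    ``fasta_paths`` maps marker name → FASTA path (or handle), in marker
    order. Returns one single-partition :class:`LabeledAlignment` per
    marker, validated against the metadata.
    """
    meta = read_metadata(metadata_path)
    out = []
    for marker, path in fasta_paths.items():
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise AlignmentError(f"marker {marker!r}: empty FASTA")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"marker {marker!r}: unequal sequence lengths {sorted(lengths)}")
        ids = [r.id for r in records]
        unknown = set(ids) - set(meta.index)
        if unknown:
            raise AlignmentError(
                f"marker {marker!r}: samples absent from metadata: "
                f"{sorted(unknown)}")
        labels: dict[str, dict[str, str]] = {
            "species": {s: meta.at[s, "species"] for s in ids}}
        for level in ("level1", "level2"):
            if level in meta.columns and all(meta.at[s, level] for s in ids):
                labels[level] = {s: meta.at[s, level] for s in ids}
        outgroup = frozenset(
            s for s in ids
            if "outgroup" in meta.columns
            and str(meta.at[s, "outgroup"]).strip().lower()
            in ("1", "true", "yes"))
        out.append(LabeledAlignment(
            ids, [str(r.seq) for r in records], labels,
            PartitionMap.from_lengths([(marker, lengths.pop())]), outgroup))
    return out


# ---------------------------------------------------------------------------
# Concatenation


def concatenate(alignments: list[LabeledAlignment],
                pad_missing: bool = False) -> LabeledAlignment:
    """Concatenate per-marker alignments into one partitioned alignment.

    Sample sets must be identical across markers unless ``pad_missing``,
    in which case a sample absent from a marker gets ``?`` over that span.
    """
    if not alignments:
        raise AlignmentError("empty alignment list")
    if len(alignments) == 1:
        return alignments[0]
    all_samples: list[str] = []
    for aln in alignments:
        for s in aln.samples:
            if s not in all_samples:
                all_samples.append(s)
    if not pad_missing:
        for aln in alignments:
            if set(aln.samples) != set(all_samples):
                missing = set(all_samples) - set(aln.samples)
                raise AlignmentError(
                    f"marker {aln.partitions.markers[0]!r} lacks samples "
                    f"{sorted(missing)} (use pad_missing to allow)")
    parts = []
    for aln in alignments:
        for name, start, end in aln.partitions.partitions:
            parts.append((name, end - start + 1))
    pm = PartitionMap.from_lengths(parts)

    seqs, labels = [], {}
    for s in all_samples:
        chunks = []
        for aln in alignments:
            if s in aln.samples:
                chunks.append(aln.sequence_of(s))
            else:
                chunks.append("?" * aln.length)
        seqs.append("".join(chunks))
    levels = set()
    for aln in alignments:
        levels |= set(aln.labels)
    for level in levels:
        merged: dict[str, str] = {}
        for aln in alignments:
            merged.update(aln.labels.get(level, {}))
        if set(merged) >= set(all_samples):
            labels[level] = {s: merged[s] for s in all_samples}
    outgroup = frozenset().union(*(a.outgroup_ids for a in alignments))
    return LabeledAlignment(all_samples, seqs, labels, pm, outgroup)


def split(aln: LabeledAlignment) -> list[LabeledAlignment]:
    """Inverse of :func:`concatenate`: one alignment per marker."""
    return [aln.restrict([m]) for m in aln.partitions.markers]


# ---------------------------------------------------------------------------
# Haplotype collapsing


def collapse_haplotypes(aln: LabeledAlignment
                        ) -> tuple[LabeledAlignment, HaplotypeMap]:
    """Prune identical sequences, keeping one representative per haplotype.

    Identity is exact string equality, gaps included; ``?``/``N`` are not
    wildcards. Haplotype IDs are ``H1, H2, ...`` in first-occurrence order.
    A haplotype's label at each level is the ``|``-joined sorted union of
    its members' labels (the full sets live in the HaplotypeMap).
    """
    if not aln.samples:
        raise AlignmentError("empty alignment")
    by_seq: "OrderedDict[str, list[str]]" = OrderedDict()
    for sid, seq in zip(aln.samples, aln.sequences):
        by_seq.setdefault(seq, []).append(sid)
    representative, assignment = {}, {}
    for i, (seq, members) in enumerate(by_seq.items(), start=1):
        hid = f"H{i}"
        representative[hid] = seq
        for m in members:
            assignment[m] = hid
    label_sets = {
        level: {hid: frozenset(mapping[m]
                               for m in members if m in mapping)
                for hid, members in
                ((h, [s for s in aln.samples if assignment[s] == h])
                 for h in representative)}
        for level, mapping in aln.labels.items()}
    hap_labels = {
        level: {hid: "|".join(sorted(ls)) for hid, ls in per.items()}
        for level, per in label_sets.items()}
    out_haps = frozenset(assignment[s] for s in aln.outgroup_ids)
    collapsed = LabeledAlignment(
        list(representative), list(representative.values()),
        hap_labels, aln.partitions, out_haps)
    return collapsed, HaplotypeMap(representative, assignment, label_sets)


# ---------------------------------------------------------------------------
# Parsimony-informative positions


def count_informative_positions(aln: LabeledAlignment,
                                include_outgroup: bool = True
                                ) -> dict[str, int]:
    """Count parsimony-informative columns per marker and in total.

    A column is informative iff at least two distinct non-gap, non-missing,
    non-ambiguous states each occur in at least two sequences.
    """
    seqs = aln.sequences
    if not include_outgroup:
        seqs = [q for s, q in zip(aln.samples, aln.sequences)
                if s not in aln.outgroup_ids]
    if len(seqs) < 4:
        raise AlignmentError("need >=4 sequences to assess informativeness")
    counts = {m: 0 for m in aln.partitions.markers}
    for name, start, end in aln.partitions.partitions:
        for col in range(start - 1, end):
            tally: dict[str, int] = {}
            for seq in seqs:
                c = seq[col]
                if c in IUPAC_BASES:
                    tally[c] = tally.get(c, 0) + 1
            if sum(1 for v in tally.values() if v >= 2) >= 2:
                counts[name] += 1
    counts["total"] = sum(counts[m] for m in aln.partitions.markers)
    return counts
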