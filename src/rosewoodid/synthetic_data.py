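"""Synthetic labeled alignments with recorded ground truth, plus the
embedded diagnostic-polymorphism reference table.

The generator emulates the structure the identification analysis assumes:
a concatenated three-partition plastid alignment (~1530 columns), a
hierarchical group → subgroup → species classification, low intraspecific
variation overlapping interspecific variation, haplotype sharing among
species within a subgroup, group-specific multi-base indels, and a
divergent outgroup. Mutations are placed without replacement across the
whole tree by default (no multiple hits), so planted diagnostics are
exactly recoverable; this deliberately under-models homoplasy and can be
relaxed with ``allow_multiple_hits``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .alignment_io import (IUPAC_EXPANSION, LabeledAlignment, PartitionMap)
from .diagnostics import (CharacterMatrix, Column, IndelCharacter, MISSING)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

OUTGROUP_ID = "OUT1"
OUTGROUP_LABEL = "OUT"


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedIndel:
    """A multi-base indel present (as its motif) only in the owning group."""

    name: str
    start: int
    end: int
    motif: str
    owner: str                     # group label, e.g. "G1"

    def as_character(self) -> IndelCharacter:
        return IndelCharacter(self.name, self.start, self.end, self.motif)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped defaults: ~1530 columns, 2 groups × 2 subgroups,
    36 species / 144 samples plus one divergent outgroup.

    Substitution counts are per lineage step (root→group, group→subgroup,
    subgroup→species, per within-species sample); defaults give mean
    intraspecific K2P distances of ~0.001 and interspecific means near
    0.01, i.e. overlapping intra/inter distributions at species level but
    clean separation of groups. ``p_share`` is the probability that a
    species reuses an earlier sister species' haplotype (chloroplast
    haplotype sharing). ``kappa`` is the transition:transversion ratio.
    """

    seed: int
    marker_names: tuple[str, ...] = ("matK", "rbcL", "trnL")
    marker_lengths: tuple[int, ...] = (565, 510, 455)
    n_groups: int = 2
    subgroups_per_group: int = 2
    species_per_subgroup: int = 9
    samples_per_species: int = 4
    subs_root_to_group: int = 20
    subs_group_to_subgroup: int = 10
    subs_subgroup_to_species: int = 4
    subs_within_species: int = 1
    p_share: float = 0.2
    planted_indels: tuple[PlantedIndel, ...] = (
        PlantedIndel("Indel1", 1178, 1182, "TGAAT", "G1"),
        PlantedIndel("Indel2", 1338, 1347, "TCTATAGAAT", "G2"),
    )
    outgroup_divergence: int = 40
    kappa: float = 2.0
    allow_multiple_hits: bool = False
    include_outgroup: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise SyntheticError("seed is mandatory")
        if not (0.0 <= self.p_share <= 1.0):
            raise SyntheticError("p_share must be in [0, 1]")
        for v in (self.n_groups, self.subgroups_per_group,
                  self.species_per_subgroup, self.samples_per_species):
            if v < 1:
                raise SyntheticError("hierarchy counts must be >= 1")
        for v in (self.subs_root_to_group, self.subs_group_to_subgroup,
                  self.subs_subgroup_to_species, self.subs_within_species,
                  self.outgroup_divergence):
            if v < 0:
                raise SyntheticError("substitution counts must be >= 0")
        L = sum(self.marker_lengths)
        for ind in self.planted_indels:
            if not (1 <= ind.start <= ind.end <= L):
                raise SyntheticError(
                    f"indel {ind.name!r} span outside alignment")

    @property
    def partitions(self) -> PartitionMap:
        return PartitionMap.from_lengths(
            list(zip(self.marker_names, self.marker_lengths)))


@dataclass
class GroundTruth:
    """Everything the generator planted, for oracle-style assertions."""

    species: dict[str, str]
    subgroup: dict[str, str]
    group: dict[str, str]
    group_columns: dict[str, list[tuple[int, str]]]      # 1-based (pos, state)
    subgroup_columns: dict[str, list[tuple[int, str]]]
    species_columns: dict[str, list[tuple[int, str]]]
    planted_indels: list[PlantedIndel]
    sharing_events: list[tuple[str, str]]                # (species, donor)
    tree_newick: str
    hierarchy: dict[str, list[str]]

    def to_json(self) -> str:
        d = asdict(self)
        d["planted_indels"] = [asdict(i) for i in self.planted_indels]
        return json.dumps(d, indent=1, sort_keys=True)


def _mutate(seq: list[str], columns: np.ndarray, rng,
            kappa: float) -> list[tuple[int, str]]:
    """Apply one substitution per column in place; returns (pos1, state)."""
    placed = []
    p_ts = kappa / (kappa + 1.0)
    for col in columns:
        base = seq[col]
        if base not in _TRANSITION:      # gap from an indel span: skip
            continue
        if rng.random() < p_ts:
            new = _TRANSITION[base]
        else:
            new = _TRANSVERSIONS[base][rng.integers(2)]
        seq[col] = new
        placed.append((int(col) + 1, new))
    return placed


class _ColumnPool:
    """Columns to mutate: globally without replacement, or free draws."""

    def __init__(self, available: np.ndarray, rng, with_replacement: bool):
        self.rng = rng
        self.with_replacement = with_replacement
        self.order = rng.permutation(available)
        self.cursor = 0
        self.available = available

    def draw(self, n: int) -> np.ndarray:
        if self.with_replacement:
            return self.rng.choice(self.available, size=n, replace=True)
        if self.cursor + n > len(self.order):
            raise SyntheticError(
                f"requested mutations exceed available columns "
                f"({len(self.order)})")
        out = self.order[self.cursor:self.cursor + n]
        self.cursor += n
        return out


def generate(config: SyntheticConfig
             ) -> tuple[LabeledAlignment, GroundTruth]:
    """Simulate an alignment down the declared hierarchy.

    Fully reproducible from ``config.seed``: same seed and config give
    byte-identical sequences, labels and ground truth.
    """
    rng = np.random.default_rng(config.seed)
    pm = config.partitions
    L = pm.total_length
    indel_cols = set()
    for ind in config.planted_indels:
        indel_cols.update(range(ind.start - 1, ind.end))
    available = np.array([c for c in range(L) if c not in indel_cols])
    pool = _ColumnPool(available, rng, config.allow_multiple_hits)

    root = [b for b in rng.choice(list("ACGT"), size=L)]
    for ind in config.planted_indels:
        # concrete realization of the motif (ambiguity codes resolved once)
        real = [sorted(IUPAC_EXPANSION[m])[rng.integers(
            len(IUPAC_EXPANSION[m]))] for m in ind.motif]
        root[ind.start - 1:ind.end] = real

    samples, seqs = [], []
    species_map, subgroup_map, group_map = {}, {}, {}
    group_cols: dict[str, list] = {}
    subgroup_cols: dict[str, list] = {}
    species_cols: dict[str, list] = {}
    sharing: list[tuple[str, str]] = []
    hierarchy: dict[str, list[str]] = {}
    tree_groups = []

    for gi in range(1, config.n_groups + 1):
        gname = f"G{gi}"
        gseq = list(root)
        for ind in config.planted_indels:
            if ind.owner != gname:
                gseq[ind.start - 1:ind.end] = ["-"] * len(ind.motif)
        group_cols[gname] = _mutate(
            gseq, pool.draw(config.subs_root_to_group), rng, config.kappa)
        hierarchy[gname] = []
        tree_subgroups = []
        for si in range(1, config.subgroups_per_group + 1):
            sgname = f"{gname}.S{si}"
            hierarchy[gname].append(sgname)
            sgseq = list(gseq)
            subgroup_cols[sgname] = _mutate(
                sgseq, pool.draw(config.subs_group_to_subgroup), rng,
                config.kappa)
            bases: list[tuple[str, list[str]]] = []
            tree_species = []
            for pi in range(1, config.species_per_subgroup + 1):
                spname = f"{sgname}.sp{pi}"
                if bases and rng.random() < config.p_share:
                    donor, donor_seq = bases[rng.integers(len(bases))]
                    spseq = list(donor_seq)
                    species_cols[spname] = []
                    sharing.append((spname, donor))
                else:
                    spseq = list(sgseq)
                    species_cols[spname] = _mutate(
                        spseq, pool.draw(config.subs_subgroup_to_species),
                        rng, config.kappa)
                bases.append((spname, spseq))
                sample_ids = []
                for ki in range(1, config.samples_per_species + 1):
                    sid = f"{spname}_{ki:02d}"
                    sseq = list(spseq)
                    if ki > 1 and config.subs_within_species:
                        _mutate(sseq,
                                pool.draw(config.subs_within_species),
                                rng, config.kappa)
                    samples.append(sid)
                    seqs.append("".join(sseq))
                    species_map[sid] = spname
                    subgroup_map[sid] = sgname
                    group_map[sid] = gname
                    sample_ids.append(sid)
                tree_species.append(
                    "(" + ",".join(sample_ids) + ")" if len(sample_ids) > 1
                    else sample_ids[0])
            tree_subgroups.append("(" + ",".join(tree_species) + ")")
        tree_groups.append("(" + ",".join(tree_subgroups) + ")")

    outgroup_ids = frozenset()
    if config.include_outgroup:
        oseq = list(root)
        for ind in config.planted_indels:
            oseq[ind.start - 1:ind.end] = ["-"] * len(ind.motif)
        _mutate(oseq, pool.draw(config.outgroup_divergence), rng,
                config.kappa)
        samples.append(OUTGROUP_ID)
        seqs.append("".join(oseq))
        species_map[OUTGROUP_ID] = OUTGROUP_LABEL
        subgroup_map[OUTGROUP_ID] = OUTGROUP_LABEL
        group_map[OUTGROUP_ID] = OUTGROUP_LABEL
        outgroup_ids = frozenset([OUTGROUP_ID])
        newick = "(" + ",".join(tree_groups + [OUTGROUP_ID]) + ");"
    else:
        newick = "(" + ",".join(tree_groups) + ");"

    aln = LabeledAlignment(
        samples, seqs,
        {"species": species_map, "level1": group_map,
         "level2": subgroup_map},
        pm, outgroup_ids)
    gt = GroundTruth(dict(species_map), dict(subgroup_map), dict(group_map),
                     group_cols, subgroup_cols, species_cols,
                     list(config.planted_indels), sharing, newick, hierarchy)
    return aln, gt


def write_bundle(aln: LabeledAlignment, gt: GroundTruth, outdir) -> None:
    """Emit the per-marker FASTAs, metadata TSV, partition text and ground
    truth JSON that the pipeline consumes."""
    import os
    os.makedirs(outdir, exist_ok=True)
    from .alignment_io import split
    for sub in split(aln):
        marker = sub.partitions.markers[0]
        sub.to_fasta(os.path.join(outdir, f"{marker}.fasta"))
    with open(os.path.join(outdir, "metadata.tsv"), "w") as fh:
        fh.write("sample_id\tspecies\tlevel1\tlevel2\toutgroup\tregion\n")
        for sid in aln.samples:
            og = int(sid in aln.outgroup_ids)
            region = "outgroup" if og else aln.labels["level1"][sid]
            fh.write(f"{sid}\t{aln.labels['species'][sid]}\t"
                     f"{aln.labels['level1'][sid]}\t"
                     f"{aln.labels['level2'][sid]}\t{og}\t{region}\n")
    with open(os.path.join(outdir, "partitions.txt"), "w") as fh:
        fh.write(aln.partitions.to_text())
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        fh.write(gt.to_json())


# ---------------------------------------------------------------------------
# Embedded reference table: diagnostic polymorphisms of the published
# Malagasy/non-Malagasy haplotype comparison (8 haplotypes × 17 characters:
# 15 substitution positions + 2 coded indels).

REFERENCE_POSITIONS = (178, 205, 937, 1008, 1063, 1087, 1175, 1231, 1256,
                    1265, 1268, 1299, 1359, 1365, 1439)

REFERENCE_INDELS = (
    IndelCharacter("Indel1", 1178, 1182, "TGAAT"),
    IndelCharacter("Indel2", 1338, 1347, "TYTHTHDAAT"),
)

REFERENCE_HIERARCHY = {"I": ["SG1", "SG2"], "II": ["SG3", "SG4"]}

REFERENCE_PARTITIONS = PartitionMap.from_lengths(
    [("matK", 565), ("rbcL", 510), ("trnL", 455)])

# Printed column order:
#   178 205 | 937 1008 1063 | 1087 1175 Indel1 1231 1256 1265 1268 1299
#   Indel2 1359 1365 1439
_REFERENCE_ROWS = [
    # (row id, group, subgroup, states in printed order)
    ("SG1_h1", "I", "SG1",
     "T G A C C A A 1 G G T A T 1 G T 0"),
    ("SG2_h1", "I", "SG2",
     "C C A A A G G 1 G C T G T 1 G T T"),
    ("SG2_h2", "I", "SG2",
     "C C A A A G G 1 G C G G T 1 G T T"),
    ("SG3_h1", "II", "SG3",
     "C C A C C G G 0 T C T A C 0 C C 0"),
    ("SG4_h1", "II", "SG4",
     "C C G C C G G 0 T C T A C 0 C C 0"),
    ("III_h1", "III", "III",
     "C C A C C G G 0 G C T A T 1 G C 0"),
    ("IV_h1", "IV", "IV",
     "C C A C C G G 0 ? C T A T 1 G C 0"),   # 1231 missing in this taxon
    ("Pterocarpus", "OUT", "OUT",
     "C C A C A G G 0 G C T A T 1 G C 0"),
]


def reference_character_matrix() -> CharacterMatrix:
    """The published diagnostic-polymorphism matrix as a CharacterMatrix.

    Rows: SG1, SG2 (two haplotypes), SG3, SG4, non-Malagasy groups III and
    IV, and the *Pterocarpus* outgroup. Columns in printed order: 15
    substitution positions (matK: 178, 205; rbcL: 937, 1008, 1063; trnL:
    the rest) and two binary indel characters in trnL.
    """
    columns = []
    ordered = [178, 205, 937, 1008, 1063, 1087, 1175, "Indel1", 1231, 1256,
               1265, 1268, 1299, "Indel2", 1359, 1365, 1439]
    ind = {i.name: i for i in REFERENCE_INDELS}
    for c in ordered:
        if isinstance(c, int):
            columns.append(Column(str(c), "substitution", c))
        else:
            columns.append(Column(c, "indel", ind[c].start,
                                  (ind[c].start, ind[c].end)))
    row_ids, states = [], []
    group_labels, subgroup_labels = {}, {}
    for rid, group, subgroup, packed in _REFERENCE_ROWS:
        row_ids.append(rid)
        states.append(packed.split())
        group_labels[rid] = group
        subgroup_labels[rid] = subgroup
    return CharacterMatrix(row_ids, columns, states,
                           {"group": group_labels,
                            "subgroup": subgroup_labels},
                           frozenset(["Pterocarpus"]))


def reference_row_sequence(row_id: str, background: str = "A") -> str:
    """Full-length (1530) aligned sequence realizing one fixture row.

    Non-diagnostic positions are filled with ``background``; indel spans
    carry a concrete motif realization when present, gaps when absent; the
    printed per-position gap state ("0" at 1439) becomes ``-`` and a
    missing state becomes ``?``.
    """
    cm = reference_character_matrix()
    ridx = cm.row_ids.index(row_id)
    seq = [background] * REFERENCE_PARTITIONS.total_length
    realized = {"Indel1": "TGAAT", "Indel2": "TCTATAGAAT"}
    for col, state in zip(cm.columns, cm.states[ridx]):
        if col.kind == "indel":
            start, end = col.span
            if state == "1":
                seq[start - 1:end] = list(realized[col.name])
            else:
                seq[start - 1:end] = ["-"] * (end - start + 1)
        else:
            if state == MISSING:
                seq[col.position - 1] = "?"
            elif state == "0":
                seq[col.position - 1] = "-"
            else:
                seq[col.position - 1] = state
    return "".join(seq)
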