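"""Diagnostic-character discovery and rule-based classification.

A character state is *diagnostic* for a group when it is **pure** (every
group member whose state is known carries it) and **private** (no
non-member carries it). Characters are either single-column nucleotide
substitutions or binary indel presence/absence characters coding a
multi-base insertion/deletion as one character (simple indel coding).
Diagnostics discovered at the group and subgroup levels of a declared
hierarchy are assembled into a decision key: a query is assigned to a
target (Malagasy) group only when its attributes match; anything else
falls through to "non-target" — absence of evidence is never asserted
positively, since reference libraries never sample the rest of the genus
exhaustively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .alignment_io import (IUPAC_BASES, IUPAC_EXPANSION, LabeledAlignment,
                           PartitionMap)

MISSING = "?"
NON_TARGET = "non-target"


class DiagnosticsError(ValueError):
    pass


@dataclass(frozen=True)
class IndelCharacter:
    """A multi-base indel coded as one binary character.

    ``start``/``end`` are 1-based inclusive on the concatenated alignment;
    the motif may contain IUPAC ambiguity codes. State per row: 1 if the
    row's span matches the motif under IUPAC compatibility, 0 if the span
    is entirely gaps, missing otherwise.
    """

    name: str
    start: int
    end: int
    motif: str

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.motif):
            raise DiagnosticsError(
                f"indel {self.name!r}: span {self.start}-{self.end} does "
                f"not match motif length {len(self.motif)}")

    def state_of(self, sequence: str) -> str:
        segment = sequence[self.start - 1:self.end]
        if all(c == "-" for c in segment):
            return "0"
        ok = all(c in IUPAC_BASES and c in IUPAC_EXPANSION[m]
                 for c, m in zip(segment, self.motif))
        return "1" if ok else MISSING


@dataclass(frozen=True)
class Column:
    """One character-matrix column: a substitution position or an indel."""

    name: str
    kind: str                     # "substitution" | "indel"
    position: int                 # 1-based; indels use span start
    span: tuple[int, int] | None = None


@dataclass
class CharacterMatrix:
    """Haplotype rows × character columns with hierarchical row labels.

    ``states[i][j]`` is the state of row i at column j: A/C/G/T or missing
    for substitutions, 0/1/missing for indels. ``row_labels`` maps a level
    name ("group", "subgroup", ...) to row-id → label.
    """

    row_ids: list[str]
    columns: list[Column]
    states: list[list[str]]
    row_labels: dict[str, dict[str, str]]
    outgroup_rows: frozenset[str] = frozenset()

    def __post_init__(self):
        for rid, row in zip(self.row_ids, self.states):
            if len(row) != len(self.columns):
                raise DiagnosticsError(
                    f"row {rid!r} has {len(row)} states, expected "
                    f"{len(self.columns)}")

    def column_index(self, name: str) -> int:
        for i, c in enumerate(self.columns):
            if c.name == name:
                return i
        raise KeyError(name)

    def state(self, row_id: str, column: str) -> str:
        return self.states[self.row_ids.index(row_id)][
            self.column_index(column)]

    def rows_of(self, level: str, group: str) -> list[int]:
        lab = self.row_labels[level]
        return [i for i, r in enumerate(self.row_ids) if lab[r] == group]


def build_character_matrix(aln: LabeledAlignment,
                           indels: list[IndelCharacter] = (),
                           levels: dict[str, str] | None = None
                           ) -> CharacterMatrix:
    """Character matrix from a haplotype-collapsed alignment.

    Every alignment column outside the declared indel spans becomes a
    substitution column (gaps/ambiguities → missing); each indel span is
    reduced to a single binary column. ``levels`` maps matrix level names
    to alignment label levels (default: group ← level1, subgroup ← level2).
    """
    L = aln.length
    covered = set()
    for ind in indels:
        if not (1 <= ind.start <= ind.end <= L):
            raise DiagnosticsError(
                f"indel {ind.name!r} span {ind.start}-{ind.end} outside "
                f"1..{L}")
        covered.update(range(ind.start, ind.end + 1))
    columns = [Column(str(p), "substitution", p)
               for p in range(1, L + 1) if p not in covered]
    columns += [Column(i.name, "indel", i.start, (i.start, i.end))
                for i in indels]
    states = []
    for seq in aln.sequences:
        row = [seq[c.position - 1]
               if seq[c.position - 1] in IUPAC_BASES else MISSING
               for c in columns if c.kind == "substitution"]
        for ind in indels:
            s = ind.state_of(seq)
            if s == MISSING:
                warnings.warn(
                    f"indel {ind.name!r}: span neither gapped nor "
                    f"motif-compatible; coded missing")
            row.append(s)
        states.append(row)
    if levels is None:
        levels = {"group": "level1", "subgroup": "level2"}
    row_labels = {mat_level: dict(aln.labels[aln_level])
                  for mat_level, aln_level in levels.items()
                  if aln_level in aln.labels}
    return CharacterMatrix(list(aln.samples), columns, states, row_labels,
                           aln.outgroup_ids)


@dataclass(frozen=True)
class DiagnosticAttribute:
    """A (column, state) pair pure in and private to one group."""

    column: str
    state: str
    group: str
    scope: str                    # group | subgroup | within_subgroup
    kind: str                     # substitution | indel
    position: int
    supported_by: int             # group members with a known state
    group_size: int

    @property
    def fully_supported(self) -> bool:
        return self.supported_by == self.group_size


def find_diagnostics(cm: CharacterMatrix, level: str,
                     exclude_outgroup: bool = True,
                     scope: str | None = None) -> list[DiagnosticAttribute]:
    """Pure+private character states for every group at one label level.

    A group member with a missing state does not veto purity (the
    attribute is then flagged ``supported_by < group_size``); a non-member
    with a missing state does not veto privacy. Outgroup rows are excluded
    from the comparison set by default.
    """
    labels = cm.row_labels[level]
    rows = [i for i, r in enumerate(cm.row_ids)
            if not (exclude_outgroup and r in cm.outgroup_rows)]
    groups = sorted({labels[cm.row_ids[i]] for i in rows})
    if len(groups) < 2:
        raise DiagnosticsError(
            f"level {level!r} has {len(groups)} group(s) after exclusions; "
            "need >=2")
    out = []
    for g in groups:
        members = [i for i in rows if labels[cm.row_ids[i]] == g]
        others = [i for i in rows if labels[cm.row_ids[i]] != g]
        for j, col in enumerate(cm.columns):
            member_states = {cm.states[i][j] for i in members}
            known = member_states - {MISSING}
            if len(known) != 1:
                continue                      # not pure (or all missing)
            state = next(iter(known))
            if any(cm.states[i][j] == state for i in others):
                continue                      # not private
            out.append(DiagnosticAttribute(
                col.name, state, g, scope or level, col.kind, col.position,
                sum(1 for i in members if cm.states[i][j] != MISSING),
                len(members)))
    return out


def within_group_differentiators(cm: CharacterMatrix, level: str,
                                 group: str) -> list[str]:
    """Columns whose known states vary among the group's rows."""
    members = cm.rows_of(level, group)
    if not members:
        raise DiagnosticsError(f"group {group!r} absent at level {level!r}")
    out = []
    for j, col in enumerate(cm.columns):
        known = {cm.states[i][j] for i in members} - {MISSING}
        if len(known) >= 2:
            out.append(col.name)
    return out


@dataclass
class DiagnosticKey:
    """Hierarchical decision key over diagnostic attributes.

    Level 1 assigns a query to one of the target groups when that group's
    attributes match; otherwise the query falls through to
    ``fallback_label``. Level 2 repeats the logic among the assigned
    group's subgroups. ``within_subgroup`` lists further differentiating
    columns inside a subgroup (informational, not used for assignment).
    """

    group_attributes: dict[str, list[DiagnosticAttribute]]
    subgroup_attributes: dict[str, dict[str, list[DiagnosticAttribute]]]
    within_subgroup: dict[str, list[str]]
    hierarchy: dict[str, list[str]]
    columns: dict[str, Column]
    fallback_label: str = NON_TARGET

    @property
    def unclassifiable_groups(self) -> list[str]:
        out = [g for g, a in self.group_attributes.items() if not a]
        for g, subs in self.subgroup_attributes.items():
            out += [sg for sg, a in subs.items() if not a]
        return out

    def all_attributes(self) -> list[DiagnosticAttribute]:
        out = []
        for attrs in self.group_attributes.values():
            out += attrs
        for subs in self.subgroup_attributes.values():
            for attrs in subs.values():
                out += attrs
        return out

    def to_dict(self) -> dict:
        def enc(a: DiagnosticAttribute) -> dict:
            return {"column": a.column, "state": a.state, "group": a.group,
                    "scope": a.scope, "kind": a.kind,
                    "position": a.position, "supported_by": a.supported_by,
                    "group_size": a.group_size}
        return {
            "hierarchy": self.hierarchy,
            "fallback_label": self.fallback_label,
            "group_attributes": {g: [enc(a) for a in attrs]
                                 for g, attrs in
                                 self.group_attributes.items()},
            "subgroup_attributes": {
                g: {sg: [enc(a) for a in attrs] for sg, attrs in subs.items()}
                for g, subs in self.subgroup_attributes.items()},
            "within_subgroup": self.within_subgroup,
        }


def key_from_dict(d: dict) -> DiagnosticKey:
    """Inverse of :meth:`DiagnosticKey.to_dict` (columns reconstructed
    from the attributes themselves)."""
    def dec(e: dict) -> DiagnosticAttribute:
        return DiagnosticAttribute(e["column"], e["state"], e["group"],
                                   e["scope"], e["kind"], e["position"],
                                   e["supported_by"], e["group_size"])
    group_attributes = {g: [dec(e) for e in attrs]
                        for g, attrs in d["group_attributes"].items()}
    subgroup_attributes = {
        g: {sg: [dec(e) for e in attrs] for sg, attrs in subs.items()}
        for g, subs in d["subgroup_attributes"].items()}
    columns = {}
    for a in ([a for attrs in group_attributes.values() for a in attrs]
              + [a for subs in subgroup_attributes.values()
                 for attrs in subs.values() for a in attrs]):
        columns[a.column] = Column(a.column, a.kind, a.position)
    return DiagnosticKey(group_attributes, subgroup_attributes,
                         {k: list(v) for k, v in d["within_subgroup"].items()},
                         {k: list(v) for k, v in d["hierarchy"].items()},
                         columns, d["fallback_label"])


def build_key(cm: CharacterMatrix, hierarchy: dict[str, list[str]],
              fallback_label: str = NON_TARGET) -> DiagnosticKey:
    """Assemble the diagnostic key for the declared group→subgroup tree.

    ``hierarchy`` lists only the *target* groups and their subgroups;
    every other group in the matrix serves as background and is reached by
    fall-through. Reduction of the raw pure+private attribute pool to the
    key follows from computing diagnostics only at the declared group and
    subgroup scopes (attributes private to single undeclared haplotypes
    never enter).
    """
    group_attrs_all = find_diagnostics(cm, "group", scope="group")
    sub_attrs_all = (find_diagnostics(cm, "subgroup", scope="subgroup")
                     if "subgroup" in cm.row_labels else [])
    group_attributes = {
        g: [a for a in group_attrs_all if a.group == g] for g in hierarchy}
    subgroup_attributes = {
        g: {sg: [a for a in sub_attrs_all if a.group == sg] for sg in subs}
        for g, subs in hierarchy.items()}
    within = {}
    for g, subs in hierarchy.items():
        for sg in subs:
            if len(cm.rows_of("subgroup", sg)) >= 2:
                diffs = within_group_differentiators(cm, "subgroup", sg)
                if diffs:
                    within[sg] = diffs
    key = DiagnosticKey(group_attributes, subgroup_attributes, within,
                        {g: list(s) for g, s in hierarchy.items()},
                        {c.name: c for c in cm.columns}, fallback_label)
    if key.unclassifiable_groups:
        warnings.warn(
            "groups without diagnostic attributes (unclassifiable): "
            f"{key.unclassifiable_groups}")
    return key


@dataclass(frozen=True)
class ClassificationResult:
    group: str                     # assigned group or fallback label
    subgroup: str | None
    report: tuple[tuple[str, str, str, str], ...]  # (group, column, want, got)


def _query_state(sequence: str, col: Column,
                 indels: dict[str, IndelCharacter]) -> str:
    if col.kind == "indel":
        return indels[col.name].state_of(sequence)
    c = sequence[col.position - 1]
    return c if c in IUPAC_BASES else MISSING


def _matches(attrs: list[DiagnosticAttribute], sequence: str,
             columns: dict[str, Column],
             indels: dict[str, IndelCharacter], mode: str) -> bool:
    if not attrs:
        return False
    matched = mismatched = 0
    for a in attrs:
        got = _query_state(sequence, columns[a.column], indels)
        if got == MISSING:
            continue
        if got == a.state:
            matched += 1
        else:
            mismatched += 1
    if mode == "strict":
        return mismatched == 0 and matched == len(attrs)
    if mode == "majority":
        return matched >= 1 and matched > mismatched
    raise DiagnosticsError(f"unknown match mode {mode!r}")


def classify(sequence: str, key: DiagnosticKey, partitions: PartitionMap,
             indels: list[IndelCharacter] = (),
             mode: str = "strict") -> ClassificationResult:
    """Assign an aligned query sequence with the diagnostic key.

    ``mode="strict"`` requires every attribute of a group to match
    positively; ``mode="majority"`` tolerates missing data (more positive
    matches than mismatches, at least one match). Deterministic; emits a
    per-attribute report for audit.
    """
    if len(sequence) != partitions.total_length:
        raise DiagnosticsError(
            f"query length {len(sequence)} != alignment length "
            f"{partitions.total_length}")
    sequence = sequence.upper()
    ind = {i.name: i for i in indels}
    report = []
    for g, attrs in key.group_attributes.items():
        for a in attrs:
            got = _query_state(sequence, key.columns[a.column], ind)
            report.append((g, a.column, a.state, got))
    assigned = [g for g, attrs in key.group_attributes.items()
                if _matches(attrs, sequence, key.columns, ind, mode)]
    if len(assigned) != 1:
        return ClassificationResult(key.fallback_label, None, tuple(report))
    group = assigned[0]
    sub_assigned = []
    for sg, attrs in key.subgroup_attributes.get(group, {}).items():
        for a in attrs:
            got = _query_state(sequence, key.columns[a.column], ind)
            report.append((sg, a.column, a.state, got))
        if _matches(attrs, sequence, key.columns, ind, mode):
            sub_assigned.append(sg)
    subgroup = sub_assigned[0] if len(sub_assigned) == 1 else None
    return ClassificationResult(group, subgroup, tuple(report))


def classify_rows(cm: CharacterMatrix, key: DiagnosticKey,
                  mode: str = "strict") -> dict[str, ClassificationResult]:
    """Apply the key to character-matrix rows directly (self-consistency)."""
    out = {}
    for ridx, rid in enumerate(cm.row_ids):
        def state_of(col_name: str) -> str:
            return cm.states[ridx][cm.column_index(col_name)]

        def match(attrs: list[DiagnosticAttribute]) -> bool:
            if not attrs:
                return False
            m = mm = 0
            for a in attrs:
                got = state_of(a.column)
                if got == MISSING:
                    continue
                if got == a.state:
                    m += 1
                else:
                    mm += 1
            if mode == "strict":
                return mm == 0 and m == len(attrs)
            return m >= 1 and m > mm

        assigned = [g for g, attrs in key.group_attributes.items()
                    if match(attrs)]
        if len(assigned) != 1:
            out[rid] = ClassificationResult(key.fallback_label, None, ())
            continue
        g = assigned[0]
        subs = [sg for sg, attrs in key.subgroup_attributes.get(g, {}).items()
                if match(attrs)]
        out[rid] = ClassificationResult(g, subs[0] if len(subs) == 1 else None,
                                        ())
    return out


def count_diagnostics_by_marker(attrs: list[DiagnosticAttribute],
                                partitions: PartitionMap,
                                within_columns: list[Column] = ()
                                ) -> dict[str, int]:
    """Distinct diagnostic columns per marker partition.

    Indel characters are assigned to the marker containing their span
    start. ``within_columns`` adds within-subgroup differentiator columns
    to the tally.
    """
    seen: dict[str, set[int]] = {m: set() for m in partitions.markers}
    for a in attrs:
        seen[partitions.marker_of(a.position)].add(a.position)
    for col in within_columns:
        seen[partitions.marker_of(col.position)].add(col.position)
    counts = {m: len(s) for m, s in seen.items()}
    counts["total"] = sum(counts[m] for m in partitions.markers)
    return counts
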