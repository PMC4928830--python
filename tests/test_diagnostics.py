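import warnings

import numpy as np
import pytest

from rosewoodid import (CharacterMatrix, Column, DiagnosticsError,
                        IndelCharacter, LabeledAlignment, PartitionMap,
                        REFERENCE_HIERARCHY, REFERENCE_INDELS, REFERENCE_PARTITIONS,
                        build_character_matrix, build_key, classify,
                        classify_rows, count_diagnostics_by_marker,
                        find_diagnostics, key_from_dict, reference_character_matrix,
                        reference_row_sequence, within_group_differentiators)


def attrs_of(attrs, group):
    return {(a.column, a.state) for a in attrs if a.group == group}


def oracle_diagnostics(cm, level, exclude_outgroup=True):
    """Brute-force pure+private scan, written independently of the
    implementation's column bookkeeping."""
    labels = cm.row_labels[level]
    rows = [i for i, r in enumerate(cm.row_ids)
            if not (exclude_outgroup and r in cm.outgroup_rows)]
    found = set()
    for g in {labels[cm.row_ids[i]] for i in rows}:
        for j, col in enumerate(cm.columns):
            member = [cm.states[i][j] for i in rows
                      if labels[cm.row_ids[i]] == g]
            other = [cm.states[i][j] for i in rows
                     if labels[cm.row_ids[i]] != g]
            known = set(member) - {"?"}
            if len(known) == 1:
                state = known.pop()
                if state not in other:
                    found.add((col.name, state, g))
    return found


class TestIndelCharacter:
    def test_motif_present(self):
        ind = IndelCharacter("i", 3, 7, "TGAAT")
        assert ind.state_of("AA" + "TGAAT" + "CC") == "1"

    def test_all_gaps_absent(self):
        ind = IndelCharacter("i", 3, 7, "TGAAT")
        assert ind.state_of("AA-----CC") == "0"

    def test_iupac_ambiguity_expansion(self):
        # Y={C,T}, H={A,C,T}, D={A,G,T}
        ind = IndelCharacter("i", 1, 10, "TYTHTHDAAT")
        assert ind.state_of("TCTATAGAAT") == "1"
        assert ind.state_of("TTTTTTTAAT") == "1"
        assert ind.state_of("TGTATAGAAT") == "?"   # G not in Y

    def test_mismatch_is_missing_not_absent(self):
        ind = IndelCharacter("i", 1, 5, "TGAAT")
        assert ind.state_of("TGACT") == "?"
        assert ind.state_of("TG--T") == "?"        # partial gap

    def test_span_motif_length_mismatch_rejected(self):
        with pytest.raises(DiagnosticsError):
            IndelCharacter("i", 1, 5, "TGA")


class TestBuildCharacterMatrix:
    @pytest.fixture
    def hap_aln(self):
        # 20 columns, indel at 11-15 owned by rows 1-2
        seqs = ["AAAAAAAAAA" + "TGAAT" + "GGGGG",
                "AAAAAAAAAC" + "TGAAT" + "GGGGG",
                "AAAAAAAAAC" + "-----" + "GGGGC",
                "AAAAAAAAAC" + "TGACT" + "GGGGC"]
        ids = ["h1", "h2", "h3", "h4"]
        return LabeledAlignment(
            ids, seqs,
            {"species": {i: i for i in ids},
             "level1": {"h1": "X", "h2": "X", "h3": "Y", "h4": "Y"},
             "level2": {"h1": "X1", "h2": "X2", "h3": "Y1", "h4": "Y2"}},
            PartitionMap.from_lengths([("m", 20)]))

    def test_indel_states_and_span_exclusion(self, hap_aln):
        ind = IndelCharacter("Indel1", 11, 15, "TGAAT")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = build_character_matrix(hap_aln, [ind])
        assert len(cm.columns) == 16        # 15 substitution + 1 indel
        assert cm.state("h1", "Indel1") == "1"
        assert cm.state("h3", "Indel1") == "0"
        assert cm.state("h4", "Indel1") == "?"   # mismatching bases

    def test_mismatching_span_warns(self, hap_aln):
        ind = IndelCharacter("Indel1", 11, 15, "TGAAT")
        with pytest.warns(UserWarning, match="Indel1"):
            build_character_matrix(hap_aln, [ind])

    def test_out_of_bounds_span_rejected(self, hap_aln):
        with pytest.raises(DiagnosticsError):
            build_character_matrix(
                hap_aln, [IndelCharacter("i", 18, 22, "AAAAA")])

    def test_gap_and_ambiguity_become_missing(self):
        ids = ["a", "b"]
        aln = LabeledAlignment(
            ids, ["A-RT", "ACGT"],
            {"species": {i: i for i in ids},
             "level1": {"a": "X", "b": "Y"}},
            PartitionMap.from_lengths([("m", 4)]))
        cm = build_character_matrix(aln, [], levels={"group": "level1"})
        assert cm.state("a", "2") == "?" and cm.state("a", "3") == "?"


class TestFindDiagnostics:
    def test_reference_group_level_attributes(self):
        cm = reference_character_matrix()
        attrs = find_diagnostics(cm, "group")
        assert attrs_of(attrs, "I") == {("Indel1", "1"), ("1365", "T")}
        assert attrs_of(attrs, "II") == {("1231", "T"), ("1299", "C"),
                                         ("Indel2", "0"), ("1359", "C")}
        assert attrs_of(attrs, "III") == set()
        assert attrs_of(attrs, "IV") == set()

    def test_reference_subgroup_level_attributes(self):
        cm = reference_character_matrix()
        attrs = find_diagnostics(cm, "subgroup")
        assert attrs_of(attrs, "SG4") == {("937", "G")}
        assert attrs_of(attrs, "SG1") == {("178", "T"), ("205", "G"),
                                          ("1087", "A"), ("1175", "A"),
                                          ("1256", "G")}
        assert attrs_of(attrs, "SG2") == {("1008", "A"), ("1063", "A"),
                                          ("1268", "G"), ("1439", "T")}
        assert attrs_of(attrs, "SG3") == set()

    def test_outgroup_exclusion_is_required_for_1063(self):
        # the outgroup shares state A at 1063 with SG2; including it must
        # remove that attribute
        cm = reference_character_matrix()
        attrs = find_diagnostics(cm, "subgroup", exclude_outgroup=False)
        assert ("1063", "A") not in attrs_of(attrs, "SG2")

    def test_constant_matrix_yields_nothing(self):
        cm = CharacterMatrix(
            ["a", "b"], [Column("1", "substitution", 1)], [["A"], ["A"]],
            {"group": {"a": "X", "b": "Y"}})
        assert find_diagnostics(cm, "group") == []

    def test_single_group_rejected(self):
        cm = CharacterMatrix(
            ["a", "b"], [Column("1", "substitution", 1)], [["A"], ["C"]],
            {"group": {"a": "X", "b": "X"}})
        with pytest.raises(DiagnosticsError):
            find_diagnostics(cm, "group")

    def test_missing_member_state_does_not_veto_but_flags(self):
        cm = CharacterMatrix(
            ["a", "b", "c"], [Column("1", "substitution", 1)],
            [["A"], ["?"], ["C"]],
            {"group": {"a": "X", "b": "X", "c": "Y"}})
        (attr,) = [a for a in find_diagnostics(cm, "group")
                   if a.group == "X"]
        assert attr.state == "A"
        assert attr.supported_by == 1 and attr.group_size == 2
        assert not attr.fully_supported

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n_rows, n_cols = rng.integers(4, 9), rng.integers(3, 10)
            states = [[rng.choice(["A", "C", "G", "?"]) for _ in
                       range(n_cols)] for _ in range(n_rows)]
            ids = [f"r{i}" for i in range(n_rows)]
            groups = {r: f"g{rng.integers(3)}" for r in ids}
            if len(set(groups.values())) < 2:
                continue
            cm = CharacterMatrix(
                ids, [Column(str(j + 1), "substitution", j + 1)
                      for j in range(n_cols)], states, {"group": groups})
            got = {(a.column, a.state, a.group)
                   for a in find_diagnostics(cm, "group")}
            assert got == oracle_diagnostics(cm, "group")

    def test_invariant_under_group_label_permutation(self):
        cm = reference_character_matrix()
        base = find_diagnostics(cm, "group")
        swapped = {"I": "II", "II": "I", "III": "IV", "IV": "III",
                   "OUT": "OUT"}
        cm2 = CharacterMatrix(
            cm.row_ids, cm.columns, cm.states,
            {"group": {r: swapped[g]
                       for r, g in cm.row_labels["group"].items()},
             "subgroup": cm.row_labels["subgroup"]},
            cm.outgroup_rows)
        permuted = find_diagnostics(cm2, "group")
        assert len(permuted) == len(base)
        assert attrs_of(permuted, "II") == attrs_of(base, "I")

    def test_removing_a_row_never_shrinks_its_groups_diagnostics(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            n_rows, n_cols = 6, 8
            ids = [f"r{i}" for i in range(n_rows)]
            states = [[rng.choice(["A", "C", "G", "T"]) for _ in
                       range(n_cols)] for _ in range(n_rows)]
            groups = {r: ("X" if i < 3 else "Y") for i, r in enumerate(ids)}
            cm = CharacterMatrix(
                ids, [Column(str(j + 1), "substitution", j + 1)
                      for j in range(n_cols)], states, {"group": groups})
            before = attrs_of(find_diagnostics(cm, "group"), "X")
            cm_less = CharacterMatrix(
                ids[:2] + ids[3:], cm.columns, states[:2] + states[3:],
                {"group": {r: groups[r] for r in ids if r != "r2"}})
            after = attrs_of(find_diagnostics(cm_less, "group"), "X")
            assert before <= after


class TestWithinGroupDifferentiators:
    def test_reference_sg2_differentiator(self):
        cm = reference_character_matrix()
        assert within_group_differentiators(cm, "subgroup", "SG2") == \
            ["1265"]

    def test_identical_rows_give_nothing(self):
        cm = CharacterMatrix(
            ["a", "b"], [Column("1", "substitution", 1)], [["A"], ["A"]],
            {"group": {"a": "X", "b": "X"}})
        assert within_group_differentiators(cm, "group", "X") == []

    def test_matches_column_scan(self):
        cm = CharacterMatrix(
            ["a", "b", "c"],
            [Column(str(j), "substitution", j) for j in (1, 2, 3)],
            [["A", "C", "G"], ["A", "T", "G"], ["A", "C", "C"]],
            {"group": {"a": "X", "b": "X", "c": "X"}})
        assert within_group_differentiators(cm, "group", "X") == ["2", "3"]

    def test_absent_group_rejected(self):
        cm = reference_character_matrix()
        with pytest.raises(DiagnosticsError):
            within_group_differentiators(cm, "group", "ZZ")


class TestKey:
    def test_reference_key_attribute_counts(self):
        key = build_key(reference_character_matrix(), REFERENCE_HIERARCHY)
        assert {g: len(a) for g, a in key.group_attributes.items()} == \
            {"I": 2, "II": 4}
        flat = {sg: len(a) for subs in key.subgroup_attributes.values()
                for sg, a in subs.items()}
        assert flat == {"SG1": 5, "SG2": 4, "SG3": 0, "SG4": 1}
        assert key.within_subgroup == {"SG2": ["1265"]}
        assert len(key.all_attributes()) == 16
        assert key.unclassifiable_groups == ["SG3"]

    def test_key_round_trips_through_json_dict(self):
        import json
        key = build_key(reference_character_matrix(), REFERENCE_HIERARCHY)
        back = key_from_dict(json.loads(json.dumps(key.to_dict())))
        assert back.to_dict() == key.to_dict()

    def test_self_consistency_on_training_rows(self):
        cm = reference_character_matrix()
        key = build_key(cm, REFERENCE_HIERARCHY)
        calls = classify_rows(cm, key)
        expected = {
            "SG1_h1": ("I", "SG1"), "SG2_h1": ("I", "SG2"),
            "SG2_h2": ("I", "SG2"), "SG3_h1": ("II", None),
            "SG4_h1": ("II", "SG4"), "III_h1": ("non-target", None),
            "IV_h1": ("non-target", None),
            "Pterocarpus": ("non-target", None)}
        got = {r: (c.group, c.subgroup) for r, c in calls.items()}
        assert got == expected


class TestClassifySequences:
    @pytest.fixture
    def key(self):
        return build_key(reference_character_matrix(), REFERENCE_HIERARCHY)

    def test_reference_haplotype_sequences_classify_to_their_rows(
            self, key):
        for row, expect in [("SG1_h1", ("I", "SG1")),
                            ("SG2_h1", ("I", "SG2")),
                            ("SG4_h1", ("II", "SG4")),
                            ("Pterocarpus", ("non-target", None))]:
            seq = reference_row_sequence(row)
            res = classify(seq, key, REFERENCE_PARTITIONS,
                           list(REFERENCE_INDELS))
            assert (res.group, res.subgroup) == expect, row

    def test_missing_state_strict_vs_majority(self, key):
        seq = list(reference_row_sequence("SG1_h1"))
        seq[1365 - 1] = "?"                  # hide one group-I attribute
        res_strict = classify("".join(seq), key, REFERENCE_PARTITIONS,
                              list(REFERENCE_INDELS), mode="strict")
        res_maj = classify("".join(seq), key, REFERENCE_PARTITIONS,
                           list(REFERENCE_INDELS), mode="majority")
        assert res_strict.group == "non-target"
        assert res_maj.group == "I"

    def test_length_mismatch_rejected(self, key):
        with pytest.raises(DiagnosticsError):
            classify("ACGT", key, REFERENCE_PARTITIONS)

    def test_report_lists_every_group_attribute(self, key):
        res = classify(reference_row_sequence("SG3_h1"), key,
                       REFERENCE_PARTITIONS, list(REFERENCE_INDELS))
        assert len(res.report) >= 6         # 2 group-I + 4 group-II


class TestCountByMarker:
    def test_reference_17_columns_split_2_3_12(self):
        key = build_key(reference_character_matrix(), REFERENCE_HIERARCHY)
        within = [key.columns[c] for cols in key.within_subgroup.values()
                  for c in cols]
        counts = count_diagnostics_by_marker(
            key.all_attributes(), REFERENCE_PARTITIONS, within)
        assert counts == {"matK": 2, "rbcL": 3, "trnL": 12, "total": 17}

    def test_group_level_attributes_all_fall_in_trnl(self):
        attrs = find_diagnostics(reference_character_matrix(), "group")
        counts = count_diagnostics_by_marker(attrs, REFERENCE_PARTITIONS)
        assert counts == {"matK": 0, "rbcL": 0, "trnL": 6, "total": 6}

    def test_empty_attribute_list_gives_zeros(self):
        counts = count_diagnostics_by_marker([], REFERENCE_PARTITIONS)
        assert counts == {"matK": 0, "rbcL": 0, "trnL": 0, "total": 0}
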