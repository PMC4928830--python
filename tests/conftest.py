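import pytest

from rosewoodid import (LabeledAlignment, PartitionMap, SyntheticConfig,
                        generate)


@pytest.fixture
def toy_alignment():
    """Two markers, 6 samples; one haplotype shared between species B
    (two samples) and species C (a singleton): s3 == s4 == s5."""
    seqs = {
        "s1": "ACGTACGT" + "AAAACCCC",
        "s2": "ACGTACGA" + "AAAACCCC",
        "s3": "ACGAACGA" + "AAAACCCG",
        "s4": "ACGAACGA" + "AAAACCCG",
        "s5": "ACGAACGA" + "AAAACCCG",
        "out": "TTTAACTA" + "TATACGGG",
    }
    species = {"s1": "A", "s2": "A", "s3": "B", "s4": "B", "s5": "C",
               "out": "OUT"}
    level1 = {"s1": "M", "s2": "M", "s3": "M", "s4": "M", "s5": "M",
              "out": "OUT"}
    return LabeledAlignment(
        list(seqs), list(seqs.values()),
        {"species": species, "level1": level1},
        PartitionMap.from_lengths([("m1", 8), ("m2", 8)]),
        frozenset(["out"]))


@pytest.fixture
def small_synthetic():
    """Study-shaped but small: 2 groups x 2 subgroups x 3 species x 2."""
    cfg = SyntheticConfig(seed=7, species_per_subgroup=3,
                          samples_per_species=2)
    return generate(cfg)
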