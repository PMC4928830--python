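# Methods

## Data model and coordinates

The central container is a `LabeledAlignment`: equal-length uppercase
IUPAC sequences (`-` gap, `?`/`N` missing), per-sample labels at a
"species" level plus optional coarser levels ("level1" = phylogenetic
group, "level2" = subgroup), a `PartitionMap` of marker spans, and a set
of outgroup ids. All user-facing coordinates are **1-based inclusive on
the concatenated alignment** — the convention of published
diagnostic-position tables — so with marker lengths 565/510/455 the
partitions are matK 1–565, rbcL 566–1075, trnL 1076–1530 (total 1530).
Python slices are used internally but never serialized.

Haplotype collapsing uses exact string identity, gaps included; `?`/`N`
are deliberately *not* wildcards (treating them as wildcards would merge
non-identical sequence classes and is not what alignment-pruning tools
do by default). A collapsed haplotype carries the union of its members'
labels, so a haplotype shared between species remains representable.
Missing markers are rejected by default; opt-in padding with `?` is
available because real concatenated matrices contain a small missing
fraction.

## K2P distances

For each pair, sites where either sequence has a gap, missing symbol or
any ambiguity code are excluded (pairwise deletion — the behaviour of
the TAXONDNA/SpeciesIdentifier lineage of tools); transitions and
transversions are counted over the remaining sites and

d = −½ ln((1 − 2P − Q)·√(1 − 2Q)).

When the logarithm's argument is non-positive (substitutional
saturation) or fewer than `min_overlap` sites are comparable, the pair
is **masked as undefined, never coerced to a large value**: coercion
would silently promote garbage pairs into nearest-neighbour rankings.
`min_overlap` defaults to 1 (toy-friendly); ~100 is a sensible value for
real partial sequences. An uncorrected p-distance mode (`model="p"`) is
kept as a sensitivity check. Identification uses K2P proper: published
"K2P-corrected p-distances" from that tool family are the corrected
distances implemented here.

## Best match / best close match

Every sequence is queried once against all others (leave-one-out). All
co-minimal hits are retained; this makes the categories well defined:
*correct* (hit labels = {true label}), *ambiguous* (true label plus
others among the hits), *misidentified* (true label absent), and — for
best close match only — *no match* when the best distance exceeds the
threshold. The threshold is the nearest-rank 95th percentile of all
pooled intraspecific distances (the conventional default of the
criterion's reference implementation; configurable). Singletons at the
evaluation level can never be correct; they stay in the denominator and
are counted separately so tables remain comparable across levels.
Queries with no defined distance at all are excluded from the
denominator and listed. Reports print integer percentages; exact
fractions are retained in machine output.

Tie detection uses an absolute tolerance of 1e-15 on distances, i.e.
effectively exact ties (identical haplotypes); K2P values computed from
different site counts essentially never collide within 1e-15.

## Diagnostic characters and the key

The character matrix is built from the haplotype-collapsed alignment:
one column per alignment position (gap/ambiguity → missing) plus one
binary column per declared indel (motif present under IUPAC expansion →
1, span entirely gapped → 0, anything else → missing with a warning).
Positions inside declared indel spans are excluded from the substitution
columns: non-owning groups are gapped there, so per-position states
would duplicate the indel character as spurious "pure state vs missing"
attributes.

An attribute (column, state, group) is diagnostic iff every group member
with a known state carries it (*pure*) and no non-member carries it
(*private*). A member with missing data does not veto purity but the
attribute is flagged `supported_by < group_size`; a non-member's missing
state does not veto privacy. The outgroup is excluded from comparisons
by default — required for concordance with the published table, where
the outgroup shares the SG2 state at position 1063 yet 1063 counts as
diagnostic. Note that with only two groups in view, the ancestral state
at a column fixed in one group is necessarily pure and private to the
other; retaining the outgroup (`exclude_outgroup=False`) suppresses
these complementary attributes, which is how the generator's planted
diagnostics are checked for exact recall and precision.

The key computes diagnostics only at the declared group and subgroup
scopes of the hierarchy, which operationally performs the published
reduction of the raw attribute pool (hundreds of states, many private to
single haplotypes) to the handful relevant for group/subgroup
assignment. Level 1 assigns a query to a target group iff that group's
attributes match, else falls through to "non-target"; level 2 repeats
the logic among the assigned group's subgroups. A group with zero
attributes (SG3 in the reference table) is marked unclassifiable and
warned about; its members are still assigned at the group level.
Within-subgroup differentiating columns (position 1265 inside SG2) are
reported for information but never used for assignment. Classification
strictness is configurable: `strict` requires every attribute to match
positively (missing data fails); `majority` requires more positive
matches than mismatches, at least one, with missing ignored — useful for
degraded queries. Strict is the default: under `majority`, partially
missing non-target sequences could satisfy a group's reduced evidence.

The embedded reference fixture has **8** haplotype rows (SG1; two SG2
haplotypes; SG3; SG4; groups III and IV; the *Pterocarpus* outgroup) and
17 characters. The printed footnote for the second indel gives a 10-base
motif (TYTHTHDAAT) against an 11-column span (1338–1348); the motif
length and start coordinate are taken as authoritative, span 1338–1347.
The printed per-position gap state ("0" at position 1439) is kept as a
literal state in the fixture; in sequence classification a single-base
gap codes as missing, which is conservative and does not affect the key
(only the presence state T at 1439 is ever tested).

## Neighbor joining and monophyly

Canonical Saitou–Nei NJ with deterministic tie-breaking (first
lowest-index pair on Q ties, tolerance 1e-12) and negative branch
lengths clamped to zero on output. This is a deliberate lightweight
surrogate for full ML/Bayesian inference: it is used to validate that
labeled groups form clades, not to reproduce published phylogenies.
Monophyly relative to an outgroup is tested on bipartitions of the
unrooted topology (some edge splits exactly the query set from the rest,
outgroup on the far side); without an outgroup the tree is
midpoint-rooted first and clades are read off the rooted tree. Trees are
exchanged as newick via dendropy.

## Synthetic data

The generator walks the declared hierarchy root → group → subgroup →
species → sample, placing a fixed number of substitutions per step at
columns drawn **globally without replacement** (no multiple hits), each
a transition with probability κ/(κ+1), κ = 2 by default. Consequences:
planted group/subgroup columns are exactly diagnostic, expected distance
grows monotonically with the number of separating events, and homoplasy
is deliberately under-modelled (`allow_multiple_hits` lifts this, losing
the exact-recovery guarantee). Group-specific indels are realized as the
motif in the owning group and a gap run everywhere else, mirroring
presence/absence coding. Haplotype sharing: with probability `p_share` a
species adopts an earlier sister species' haplotype instead of deriving
its own (chloroplast capture / incomplete lineage sorting at the
phenomenological level). The outgroup diverges by its own substitution
count and lacks all planted indels.

Defaults are sized to the study system: 565/510/455-column partitions,
2 groups × 2 subgroups × 9 species × 4 samples (144 samples, 36
species) plus outgroup; 20/10/4/1 substitutions per step give mean
intraspecific K2P ≈ 0.001 and interspecific means ≈ 0.01, i.e.
overlapping distributions at species level; `p_share` = 0.2 produces
occasional cross-species haplotype identity. Tests and the acceptance
script scale the counts down (typically 2 species × 2 samples per
subgroup, sometimes 200/180/160-column partitions) to keep suites fast;
the properties asserted are scale-free. What the generator does *not*
emulate: recombination, rate heterogeneity across sites, sequencing
error, alignment uncertainty, and realistic indel evolution — so passing
tests demonstrate the correctness of the machinery under the stated
model, not field performance of the markers.

Determinism: all randomness flows from one `numpy` generator seeded by
`SyntheticConfig.seed`; identical config + seed gives byte-identical
sequences, metadata, ground truth and downstream reports (reports embed
a hash of their resolved config and carry no timestamps).

## Published success rates

The published per-marker success-rate table was computed on the full
163-sequence deposited dataset, which is an optional external input, not
shipped; those percentages are therefore not asserted anywhere. The
machinery that produces them (marker subsets × levels × criteria) is
exercised end-to-end on synthetic data, where the expected outcomes are
known from the generator's ground truth. When the deposited alignment is
available, `rosewoodid identify` accepts it unchanged (three aligned
FASTAs plus a metadata TSV).

## Known limitations

- Pure/private discovery is per-character; compound (multi-column)
  attributes are out of scope.
- The no-multiple-hits default makes synthetic divergence slightly
  sub-saturating; K2P correction is then nearly linear, so the synthetic
  suites exercise the formula far from its singular region (the
  saturation branch is covered by unit tests directly).
- NJ assumes a complete, defined distance matrix; undefined pairs are a
  hard error rather than being imputed.
- `classify` assumes the query is already aligned to reference
  coordinates; alignment of raw reads is out of scope.
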