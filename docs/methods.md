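# Methods

## The divergence rule

Given a multiple alignment containing two paralog groups across several
species, a column is a **group-diagnostic divergent site** when

1. every *criterion-species* row of group A carries the same residue `r_a`
   (no gap, no `X` — identity cannot be certified through ambiguity);
2. likewise group B yields `r_b`;
3. `r_a ≠ r_b`; and
4. the pair has significantly different properties: BLOSUM62(`r_a`,`r_b`)
   < 0 **or** the residues carry opposite net charge.

The criterion species default to the two fission yeasts whose group-B
(Tup12) proteins functionally substitute for each other — *S. pombe* and
*S. octosporus*; other species' rows (*S. japonicus*) are displayed and
polarized but do not gate conservation, because their functional
equivalence is weaker. Columns where any criterion row is gapped are
skipped rather than counted as mismatches: the rule compares residues, not
indels. Passing both clauses is recorded separately (`significant_by`), and
each reported site is classified against the outgroup residue at that
column: `A_matches_outgroup`, `B_matches_outgroup`, `both_differ`, or
`unclassified` when the outgroup is gapped.

Charge assignments are D,E → −1; K,R → +1; everything else 0. Histidine is
pH-dependent and is conservatively neutral by default
(`histidine_positive=True` flips it). Requiring `r_a ≠ r_b` is enforced at
the predicate level: calling `is_significant_pair` on an identical pair is
an error, keeping the predicate's domain honest.

## Alignment

Global Needleman–Wunsch/Gotoh with affine gaps: a gap of length L costs
`gap_open + (L−1)·gap_extend`, defaults 10 and 0.5 (the ClustalW-style
reading of "gap penalty of 10"; both are exposed in the config). End gaps
are penalized like internal ones. Traceback ties are broken
deterministically, preferring a substitution column over a gap in the
second sequence over a gap in the first.

The progressive MSA aligns profiles bottom-up along a neighbor-joining
guide tree (midpoint-rooted). The profile–profile column score is the mean
of all cross-pair substitution scores, with gap-versus-residue contributing
−`gap_extend` and gap-versus-gap 0; existing gaps are never removed. This
is deliberately a minimal progressive aligner — no sequence weighting,
position-specific penalties, or iterative refinement — because downstream
analysis needs a deterministic, scoring-transparent alignment, not maximal
accuracy on remote homologs.

Percent identity divides identical columns by columns where *both* rows
have residues, so the value is insensitive to terminal gap placement (the
denominator is reported choice, flagged in output headers). Zero comparable
columns returns 0 with a warning. Distances for trees are d = 1 −
identity/100 by default; a Poisson correction d = −ln(identity) is
selectable (`distance_model: poisson`) since the distance model used by
common NJ front-ends is rarely reported.

## Neighbor joining

Saitou–Nei NJ: join the pair minimizing Q(i,j) = (n−2)d(i,j) − Σd(i,·) −
Σd(j,·); ties go to the lexicographically smallest index pair for
determinism. Branch lengths use the standard formulas; negative estimates
are clamped to zero and flagged on the tree. The final three lineages are
resolved by the 3-taxon closed form. Rooting on an outgroup splits its
pendant edge at the midpoint. NJ provably recovers the generating topology
for additive distances; the test suite verifies this against random
additive trees with dendropy computing the Robinson–Foulds distance as an
independent check.

## Structure mapping and the clustering test

The k-th non-gap position of the designated reference alignment row maps to
author residue number `ref_start + k − 1` of the intact reference protein
(282 for the Tup1 WD40 alignment; author numbering is never rewritten).
Residue numbers inside the declared span but absent from the coordinate
records are disordered: they keep their blade assignment (a site in a
disordered stretch is still in that blade's sequence range) but are
excluded from the spatial statistic and from the viewer attribute file,
which can only colour residues that exist in the model. Blade/strand
residue ranges are supplied as a TSV config — the reference structure's
blade boundaries are a curation decision, not something the pipeline can
derive — with a packaged seven-blade toy default so everything runs and
tests without the crystal structure.

The permutation null places the same number of sites uniformly without
replacement among eligible residues: all annotated residues for
`max_blade_count` (upper tail), all resolved residues for
`mean_pairwise_ca_distance` (lower tail). Eligibility deliberately ignores
conservation; testing enrichment against an all-residue null is the
conservative default, and a user-supplied eligible set can restrict it.
When C(|eligible|, |sites|) ≤ 10⁵ the null is enumerated exhaustively and
p = m/N is exact (the observed subset is itself in the enumeration, so
p > 0); otherwise Monte-Carlo sampling uses the add-one correction
p = (1 + hits)/(1 + N). Identical seeds give bit-identical results.

## The synthetic generator

`simulate_paralog_families` draws a uniform ancestor, duplicates it into
two clades, and evolves each species lineage independently (a star species
tree — the real three-species topology is irrelevant to a column-wise
rule). Planted diagnostic sites give clade B a partner residue satisfying
the requested mode (`blosum_negative`, `opposite_charge`, or `both`)
relative to clade A's residue; when the ancestral residue admits no valid
partner (a neutral residue cannot have an opposite-charge partner), the
clade-A residue is resampled from those that do. Neutral substitutions hit
non-diagnostic positions with probability θ per site per lineage (uniform
over the 19 alternatives — the detector does not depend on the neutral
process), and with probability ε a criterion-species row is corrupted at a
diagnostic site, breaking within-group identity. Defaults mirror the study
conditions: 3 species, criterion on 2, outgroup included, L = 300,
k = 10 diagnostic sites, θ = 0.05, ε = 0.

The generator is indel-free, so truth labels are unambiguous columns; gap
handling is exercised by hand-built alignment fixtures instead. At ε = 0
recall is 1 by construction and at θ = 0 precision is 1; at θ > 0 false
positives can arise (neutral variation can by chance satisfy the rule —
the same is true of real data) but every reported site still satisfies the
rule, which the tests verify against a brute-force reimplementation.

`make_toy_structure` writes CA-only PDB text with blades as point clusters
on a wide ring (centroid separation ≥ 10× the intra-blade spread), so both
clustering statistics have signal when sites are planted in one blade;
`missing_spans` emulates disordered regions. What the toy structure does
*not* emulate: real propeller geometry (interleaved strands, a shared
central axis, loop excursions), so passing clustering tests demonstrates
the statistics and their calibration, not performance on subtle real-world
spatial patterns.

One genuine interaction surfaced by simulation: when planted divergent
sites are very dense (most of a short blade segment), the optimal global
alignment of cross-group pairs may insert compensating gaps through the
divergent block, shifting columns and hiding sites. This is a property of
parsimony alignment of locally dissimilar regions, not an implementation
artifact (scores were cross-checked against an independent aligner); the
shipped example uses 8 sites in a 20-residue segment, which aligns
gap-free.

## Pipeline and provenance

`run_pipeline` chains tree → domain identities → MSA (optionally of
configured segments) → divergent sites → structure map → clustering test,
writing tree (newick), alignment (aligned FASTA + Clustal), site table,
viewer attribute file, blade summary and clustering JSON. Every TSV/JSON
output begins with comment lines carrying the tool version, a SHA-256 hash
of the config (excluding the output directory, which is not an analysis
input) and the seed; FASTA/newick/Clustal do not tolerate comment lines,
so their provenance is carried by the MANIFEST.tsv written alongside.
Identical config + seed reproduce every artifact byte for byte. Exit
codes: 2 missing input file, 3 group member absent from the FASTA; on a
stage failure partial outputs are kept and the manifest marks them
INCOMPLETE.

## Problem sizes in the tests

The test and acceptance runs use deliberately small instances chosen to
make the oracles exact: exhaustive alignment enumeration on pairs ≤ 6
residues (200 pairs), additive trees of 4–8 leaves (100 trees), 6 × 50
random alignments against the brute-force rule (200), 50 simulation seeds
per corruption level, and a 70-residue toy propeller for the calibration
study (500 null datasets × 200 permutations). These sizes are the package's
own choices for exactness and reproducibility.

## Known limitations

- The divergent-residue set for the real Tup proteins cannot be produced
  without the accession sequences and the curated blade boundaries of the
  crystal structure; with them, agreement with previously reported sites is
  expected to be qualitative (the rule has no hidden manual-curation step).
- The progressive aligner is not a ClustalW/X replacement (no sequence
  weighting or secondary-structure-aware penalties), so alignment-sensitive
  columns may differ from alignments produced by those tools.
- `max_blade_count` has a discrete null; its permutation p-values are
  conservative. The spatial statistic is continuous and calibrates tightly.
- mmCIF, multi-model NMR files, B-factors and non-CA atoms are out of
  scope; non-standard residues in coordinate files are rejected rather
  than translated.
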