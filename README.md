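# parablade

Paralog-group-diagnostic divergent residues, mapped onto WD40 β-propeller
blades.

After a gene duplication, the two paralogs can divide up the ancestral
function. The fission-yeast transcriptional co-repressor subunits Tup11 and
Tup12 are such a pair: they are interchangeable for many targets but only
Tup12 supports the CaCl₂ stress response, and the determinants of that
specificity sit in the most *conserved* part of the protein — the
C-terminal WD40 β-propeller domain. `parablade` packages the comparative
analysis that localizes such determinants:

1. **Phylogeny** — neighbor-joining tree of the paralogs across species,
   rooted on an outgroup (*S. cerevisiae* Tup1), confirming the two-clade
   structure of the duplication.
2. **Domain cross-comparison** — per-domain (N-terminal / middle /
   C-terminal) percent-identity matrix over all protein pairs, from global
   pairwise alignments (BLOSUM62, affine gap cost 10 / 0.5).
3. **Divergent-site detection** — alignment columns where each paralog
   group is internally conserved (over designated *criterion species*) but
   the two groups differ by a residue pair with **negative BLOSUM62 score
   or opposite net charge** (D,E −; K,R +; H neutral). Sites are polarized
   against the outgroup: does Tup11, Tup12, or neither retain the ancestral
   residue?
4. **Structure mapping** — columns are mapped to author residue numbers of
   a reference crystal structure (Tup1 WD40 domain, chain C of 1ERJ,
   alignment segment 282–713), with unresolved (disordered) residues
   flagged, and per-blade occupancy of the seven-bladed propeller counted.
5. **Clustering test** — a permutation test asks whether the divergent
   sites concentrate spatially: the observed statistic (maximum per-blade
   count, upper tail; or mean pairwise CA distance, lower tail) is compared
   to draws of the same number of residues placed uniformly at random. The
   null is enumerated exhaustively when small, else Monte-Carlo sampled
   with the add-one correction p = (1 + hits)/(1 + N).

A synthetic-data generator plants ground-truth diagnostic sites in
simulated paralog families (plus toy propeller structures), so the entire
pipeline is testable end to end without downloading any accession.

## Worked example

Simulate a family of 2 × 3 orthologs plus outgroup (140 residues, 5%
neutral substitutions per lineage) with 8 diagnostic sites planted in the
segment that folds into blade 3 of a toy propeller, then run everything:

```sh
parablade simulate --seed 17 -o sim --length 140 --sites 8 --blade-cluster 3
parablade all -c sim/pipeline.yaml
```

The log reports:

```
INFO read 7 sequences from sim/family.fasta
INFO wrote sim/results/tree.nwk (7 leaves)
INFO aligned 7 sequences, 140 columns
INFO found 8 divergent sites
INFO clustering max_blade_count observed=8.000 p=0.0004998
```

`tree.nwk` recovers the two paralog clades around the outgroup root:

```
(outgroup_ref:0.013,((octosporus_Tup12,(pombe_Tup12,japonicus_Tup12))…,
 (japonicus_Tup11,(pombe_Tup11,octosporus_Tup11))…):0.013);
```

`divergent_sites.tsv` joins the detection and mapping results — e.g. column
47 carries D in every criterion-species Tup11 row and K in every Tup12 row
(BLOSUM62 −1 *and* opposite charge), the outgroup also has D (so Tup11
retains the ancestral state), and the column maps to structure residue 347
in blade 3:

```
alignment_column  residue_a  residue_b  blosum_score  ...  category            structure_residue  blade
47                D          K          -1                 A_matches_outgroup  347                3
```

`blade_summary.tsv` shows all 8 sites in blade 3, and `clustering.json`
quantifies the enrichment: observed max-per-blade count 8, permutation
p ≈ 0.0005 (2000 draws) — random placement essentially never concentrates
8 of 8 sites in one blade. Re-running with the same config and seed
reproduces every file byte for byte.

The packaged defaults include the BLOSUM62 matrix, the N/M/C domain
boundaries of the seven Tup proteins (e.g. Tup1 1–89 / 90–317 / 318–713),
the WD40 alignment segments (reference 282–713), and a seven-blade toy
annotation. A user with the real cDNA-derived sequences and 1ERJ can point
the same config at those files; see the annotated
`src/parablade/data/example_config.yaml` for every option.

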