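# Example pipeline configuration.
#
# Paths are resolved relative to this file's directory.  This layout is
# exactly what `parablade simulate` writes (as pipeline.yaml) next to its
# synthetic fixture, so the quickest way to a runnable copy is:
#
#   parablade simulate --seed 17 -o sim --length 140 --sites 8 --blade-cluster 3
#   parablade all -c sim/pipeline.yaml

fasta: family.fasta          # protein FASTA; headers may carry species=/group=
outdir: results              # every artifact is written here
seed: 17                     # drives the permutation test; recorded in outputs

groups:
  group_a: Tup11
  group_b: Tup12
  members_a:                 # species label -> sequence id
    pombe: pombe_Tup11
    octosporus: octosporus_Tup11
    japonicus: japonicus_Tup11
  members_b:
    pombe: pombe_Tup12
    octosporus: octosporus_Tup12
    japonicus: japonicus_Tup12
  criterion_species: [pombe, octosporus]   # rows that gate the divergence rule
  outgroup_id: outgroup_ref

# matrix: BLOSUM62.txt       # optional NCBI-format matrix; default = packaged BLOSUM62
# domains: domains.tsv       # optional N/M/C partition table (protein, domain, start, end)
# segments: segments.tsv     # optional per-protein (start, end) slices aligned instead
#                            # of the full sequences (e.g. the WD40 segments)

structure:
  path: toy.pdb              # PDB-format ATOM records; CA atoms are used
  chain: A
  seq_span: [301, 440]       # author-numbered span; absent numbers = disordered

blade_annotation: blades.tsv # TSV: blade, strand, start, end

reference:
  id: outgroup_ref           # alignment row mapped onto the structure
  start: 301                 # author number of its first aligned residue

alignment:
  gap_open: 10.0
  gap_extend: 0.5
  distance_model: identity   # or "poisson"

clustering:
  statistic: max_blade_count # or "mean_pairwise_ca_distance"
  n_permutations: 2000
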