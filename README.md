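# capcure

Curation of target-capture (hybrid-enrichment) loci and gene-tree
incongruence statistics, as a tested, reusable pipeline:

- **bait design** — fixed-length bait tiling with overlap over N-padded
  exons; removal of baits containing any soft-masked (lowercase) sequence
- **read curation** — replicate read-pair removal by mate-prefix identity
  (first 20 bp of both mates); binning of reads/contigs into per-locus gene
  bins with a self-contained seeded ungapped matcher (both strands)
- **orthology** — reading-frame prediction with stop trimming, intron
  splicing against the exon reference by collinear chaining, and a
  reciprocal-best-hit screen that flags contigs whose best hit is not the
  locus they were binned to
- **contamination** — cross-contamination screening: per-locus p-distances
  between taxa of different groups flagged at ≤ 0.002, aggregated to
  per-pair percentages against an alarm level
- **locus selection** — treelikeness by quartet four-point evaluation of
  p-distances, a minimum-four-taxa filter, and coverage-weighted selection
  of the most informative loci (a documented surrogate for matrix-reduction
  software)
- **supermatrix** — concatenation with 1-based inclusive partitions,
  distinct-site-pattern and gap/undetermined statistics, relaxed-PHYLIP and
  RAxML-style partition-file output
- **tree support** — internode certainty (IC/ICA) and tree certainty
  (TC / relative TC) from possibly partial gene trees, plus a deterministic
  neighbor-joining builder used to make gene trees from simulated loci
- **synthetic data** — a seeded simulator producing capture-like datasets
  (species tree, locus alignments, contigs with introns, paired reads with
  planted duplicates, paralogous contigs, contamination events, missing
  taxa) together with truth tables

## Command line

All stages are exposed under one `capcure` entry point:

```sh
capcure simulate --out-dir sim --seed 3
capcure baits --exons sim/exons.fasta --drop-softmasked --out baits.fasta
capcure dedup --r1 sim/reads/t01_R1.fastq --r2 sim/reads/t01_R2.fastq
capcure bin --seqs sim/contigs.fasta --baits baits.fasta --out-dir bins/
capcure ortho --bins bins/ --baits baits.fasta --report orthology.tsv
capcure contam --loci sim/loci --groups sim/groups.tsv --out contam.tsv
capcure select --loci sim/loci --n 10 --seed 42 --out selected.txt
capcure concat --loci sim/loci --out super.phy --partitions super.part
capcure support --ref ref.nwk --genetrees genes.nwk --out ic.tsv
capcure run --config run.yaml
```

`capcure run` executes the full stage sequence
(dedup → bin → orthology → contamination → min-taxa filter → selection →
supermatrix → support) and writes a JSON run manifest with stage-wise
counts. The YAML config maps input paths and per-stage parameters:

```yaml
out_dir: run
reads_dir: sim/reads        # optional
contigs: sim/contigs.fasta  # optional (with 'exons')
exons: sim/exons.fasta
loci_dir: sim/loci          # per-locus FASTA alignments (required)
groups: sim/groups.tsv      # optional contamination screen
reference_tree: ref.nwk     # optional support stage
gene_trees: genes.nwk
dedup: {prefix_len: 20}
match: {seed_k: 11, min_score: 50}
contamination: {p_threshold: 0.002, pct_alarm: 5.0}
selection: {rng_seed: 1, n_target: 10, min_taxa: 4}
```

## Notes on interpretation

- The contamination percentage denominator counts loci where both taxa of
  a pair are present with an evaluable distance.
- Distinct alignment patterns are plain unique column strings (no
  RAxML-style compression weights).
- The treelikeness `resolution_margin` defaults to 0 (pure four-point
  condition); a positive margin is needed for the score to discriminate
  noise alignments, since with margin 0 a unique minimum exists almost
  surely even for i.i.d. columns.
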