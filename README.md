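# senscall

Depth-calibrated single-nucleotide-variant (SNV) detection sensitivity for
targeted sequencing.

Exome capture leaves read depth highly uneven across targets, so real
polymorphisms are missed at predictable, depth-dependent rates — especially
heterozygous ones. `senscall` quantifies this: it down-samples deeply
sequenced alignments, classifies the resulting SNV calls against a
gold-standard truth set (full-alignment calls cross-referenced to a panel of
known polymorphic sites by position and alleles), estimates genotype-specific
sensitivity-by-depth curves, and applies those curves to score any genomic
partition (base, exon, gene, exome) for expected missed variants. A
synthetic-data module emulates a full exome-capture experiment (per-tile
capture-efficiency heterogeneity with a G+C-linked component, sequencing
error, diploid genotypes, reference-allele capture bias, read pairs), so the
whole pipeline is testable without external data.

## Layout

| module                   | role |
|--------------------------|------|
| `senscall.intervals_io`  | interval algebra, 100 bp tiling, depth profiles; SAM/VCF/BED/bedGraph/FASTA readers and writers (0-based half-open internally) |
| `senscall.simulate`      | synthetic reference, targets, truth genotypes and reads |
| `senscall.caller`        | pair-preserving down-sampling; diploid genotype-likelihood caller (Phred error model, θ-style priors, Q30 emission) |
| `senscall.calibration`   | truth sets, TP / partial-TP / FN classification, sensitivity curves (cumulative `≤ d` and exact-depth modes), naive binomial expectation, genotype concordance, recall-table TSV |
| `senscall.scoring`       | per-base sensitivity tracks, region reports, total sensitivity, required-mean-depth estimation, difficult/easy tile analysis |
| `senscall.cli`           | `senscall` subcommands tying the stages together |

## CLI workflow

```sh
# 1. synthesize an experiment (or bring your own SAM/BED/VCF/FASTA)
senscall simulate --seed 1 --out-dir sim/

# 2. estimate the sensitivity-by-depth calibration table
senscall calibrate sim/reads.sam sim/truth.vcf sim/targets.bed sim/reference.fasta \
    --out-table recall.tsv --seed 1

# 3. score a depth profile (bedGraph) over regions of interest
senscall score depth.bedgraph recall.tsv --regions genes.bed \
    --out-report report.tsv --out-track track.bedgraph --out-summary summary.json

# other stages
senscall downsample sim/reads.sam ds.sam -p 0.1 --seed 1
senscall call sim/reads.sam sim/reference.fasta sim/targets.bed calls.vcf
senscall tiles sim/reads.sam ds.sam sim/targets.bed sim/reference.fasta tiles.tsv
senscall report series.tsv --levels 0.8,0.9,0.95
```

Exit codes: 0 ok, 2 input error, 3 contract violation. All subcommands are
deterministic given `--seed` and log input digests.

The calibration table is a TSV with columns
`depth  genotype  n_tp  n_ptp  n_fn  sensitivity` (one row per depth 1–100
and genotype class; undefined rows are `NA`); a minimal
`depth  het_sensitivity  hom_sensitivity` dialect is also accepted.

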