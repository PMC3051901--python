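# splicetile

Supervised detection of intron retention (IR) and exon skipping (ES) from
whole-genome tiling-array hybridization data, with the unsupervised
baselines it is benchmarked against, a coverage-based RNA-seq IR caller,
sequence-confirmed benchmark-set construction, and a synthetic-data
simulator that makes the whole pipeline testable end-to-end without any
external data.

## Method overview

1. **Gene models & splicing graphs** (`splicetile.genome`) — gene/mRNA/exon
   structures from GFF3 (or a 6-column exon table), merged with transcript
   evidence into per-gene splicing graphs; IR and ES events are defined by
   exact interval containment on those graphs.
2. **Array data** (`splicetile.arraydata`) — probe-level intensity tensors
   (probe x sample x 3 replicates), quantile normalization, repetitive-probe
   masking by genome-wide 25-mer multiplicity, optional probe-effect
   (transcript) normalization, probe-to-segment assignment, and per-gene
   expression medians.
3. **Features** (`splicetile.features`) — per (segment, sample):
   five local intensity percentiles, a 5-bin soft histogram against global
   intensity percentiles, and a 10-bin soft histogram of probe distances to
   the spliced-transcript 3' end; plus the 10-bin expression stratification.
4. **Stage 1** (`splicetile.stage1`) — ten expression-stratified linear
   soft-margin SVMs (C grid-searched in 5-fold rotation), calibrated to
   inclusion probabilities by monotone piecewise-linear (isotonic) maps.
5. **Stage 2** (`splicetile.stage2`) — per segment, the descending-sorted
   inclusion probabilities concatenated with identically permuted
   flanking-exon expression; a linear SVM trained on the sequence-confirmed
   splicing (SCS) set; FDR and recall cutoffs; tissue (max-min) and stress
   (max paired difference) scores.
6. **Baselines** (`splicetile.baselines`) — the ANOVA splicing-index test
   and the modified Ner-Gaon intron scoring N(s) = max_a c(s,a) + (1-a).
7. **RNA-seq validation** (`splicetile.rnaseq`) — the three-clause coverage
   filter for retained introns and hypergeometric overlap statistics with
   representation factors.
8. **SCS construction** (`splicetile.scs`) — confirmation counting (cDNAs
   weighted twice), positive/negative pool selection, the class-ratio
   arithmetic, and negative resampling to the target ratio.
9. **Simulator** (`splicetile.simulate`) — synthetic genomes, 25-mer probes
   at ~35 bp spacing, a 24-sample x 3-replicate design (11 tissues, 10
   stress treatments, 3 controls), expression-dependent exon/intron signal
   with 3' decay, planted IR/ES events (basal, tissue- or stress-specific),
   confirmation counts, and merged coverage tracks, all with ground truth.

`splicetile.evaluation` provides ROC / partial auROC (FPR <= 0.3) /
precision-recall utilities, `splicetile.pipeline` ties the stages together,
and `splicetile.benchmarks` holds the self-contained simulation benchmarks.

## CLI

A single entry point `splicetile` with subcommands:

```sh
splicetile --seed 7 simulate --preset default --n-genes 200 --out data/
splicetile normalize --probes data/probes.tsv --samples data/samples.tsv --out data/norm.tsv
splicetile features --probes data/norm.tsv --samples data/samples.tsv --gff3 data/genes.gff3 --out data/features.tsv
splicetile train-stage1 --probes data/norm.tsv --samples data/samples.tsv \
    --gff3 data/genes.gff3 --model-out stage1.json --inclusion-out inclusion.tsv
splicetile scs-build --gff3 data/genes.gff3 --confirmations data/confirmations.tsv \
    --kind intron --out scs.tsv
splicetile predict-as --probes data/norm.tsv --samples data/samples.tsv \
    --gff3 data/genes.gff3 --scs scs.tsv --kind intron --out predictions.tsv
splicetile baseline-anova  --probes data/norm.tsv --samples data/samples.tsv --gff3 data/genes.gff3 --out anova.tsv
splicetile baseline-nergaon --probes data/norm.tsv --samples data/samples.tsv --gff3 data/genes.gff3 --out nergaon.tsv
splicetile rnaseq-ir --gff3 data/genes.gff3 --coverage data/coverage.bedgraph --out ir.bed
splicetile overlap --set1 a.txt --set2 b.txt --universe-size 125921 --out overlap.json
splicetile scs-composition
splicetile evaluate --scores scored.tsv --out eval.json
```

All tables are tab-delimited with headers; exit code 0 on success, 2 on
validation errors. Structured logs go to standard error.

## File formats

* **Gene models**: GFF3 (1-based inclusive on disk; 0-based half-open
  internally). Transcript evidence alternatively as a 6-column exon table.
* **Probe matrix**: TSV with `probe_id chrom start strand` then one column
  per sample:replicate named `<sample_id>.<r>`, linear fluorescence.
* **Sample sheet**: TSV `sample_id class control_id` with classes
  `tissue`, `stress_treatment`, `stress_control`.
* **Coverage**: bedGraph; called IR introns are emitted as BED6.
* **Models**: versioned JSON (binning limits, weights, standardization,
  calibration knots).
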