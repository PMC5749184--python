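# scduoqc

Quality-control and integration statistics for paired single-cell DNA/RNA
sequencing experiments, plus a ground-truth synthetic data generator that
emulates physically separated versus contaminated (co-amplified)
preparations so every analysis stage can be verified without external data.

## What it computes

- **genome_qc** — alignment/duplication/pairing fractions from SAM records,
  bin-to-bin coefficient of variation, Lorenz curves with trapezoidal AUC
  (diagonal = perfect uniformity), per-chromosome power spectra of
  normalized read depth with a large-scale (≥ 500 kb) band summary, and
  seeded read down-sampling.
- **cnv_profiling** — log2-ratio normalization of binned counts (optional
  GC-decile correction), circular binary segmentation with a
  permutation-calibrated arc-vs-complement statistic, profile averaging and
  Pearson/Spearman correlation, Ward/Euclidean clustering.
- **rna_metrics** — genes detected per cell, saturation by hypergeometric
  read subsampling, ensemble pooling, transcript-body coverage by
  expression tercile, ERCC spike-in input/output correlation,
  housekeeping-gene cell QC, marker-based cell-cycle staging.
- **integration** — expression binned on the DNA bin grid by TSS,
  copy-number/expression dosage correlation, adjusted-R² permutation
  regression of bulk on single cells, single-cell vs bulk SNV concordance,
  contamination metrics (exonic fraction, coding-region duplication rate),
  qPCR relative-quantity arithmetic.
- **synthetic_data** — binned WGS counts with AR(1)-lognormal amplification
  bias over a planted copy-number profile, scRNA-seq counts with logistic
  dropout/library-size variation/spike-ins, per-cell SNV call sets with
  set sensitivity and false-positive rates, and cross-fraction read
  contamination. Bit-reproducible from a single master seed.

## CLI

```sh
scduoqc simulate  --config config.yaml            # synthetic dataset + truth
scduoqc genome-qc --bins counts.bed --bin-size 1000000 --out metrics.tsv
scduoqc cnv       --bins counts.bed --alpha 0.01 --nperm 1000 --seed 7
scduoqc rna-qc    --matrix expression.tsv
scduoqc integrate --cnv segments.tsv --expr expression.tsv \
                  --coords gene_coords.tsv --bins counts.bed
scduoqc snv-concordance --cell cell.vcf --bulk bulk.vcf [--regions exome.bed]
scduoqc run       --config config.yaml            # full end-to-end pipeline
```

The config file (YAML or JSON) holds the `PipelineConfig` fields: seeds,
bin size, planted copy-number segments, cell/gene counts, and CBS
hyperparameters. Exit codes: 0 success, 1 user error, 2 internal error.

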