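# mirdx

A tested, reusable pipeline for downstream miRNA expression profiling:

* **I/O** — miRDeep2-style `read_count` tables, simplified Agilent
  `gProcessedSignal` exports, probe→mature-miRNA maps, sample metadata, and a
  canonical tagged TSV matrix format (platform + scale header lines).
* **Synthetic data** — a fully seeded generator of paired NGS/microarray
  expression with planted tumor/control differential structure, technical
  replicates, and novel-candidate call tables, so every downstream stage is
  testable without any external downloads.
* **Normalization** — log transform (base 10 by default, non-positive values
  become missing), per-sample z-scoring (mean 0, sample variance 1, n−1
  denominator), probe-to-miRNA averaging, and the positive common-subset
  restriction used before cross-platform log correlation.
* **Concordance** — Pearson correlation of log expression: per-sample
  cross-platform, differential (pairwise sample subtraction, averaged over
  all unordered pairs), and replicate-by-replicate correlation matrices.
* **Classification** — PCA-based unsupervised feature extraction (each miRNA
  embedded in 2-D; the M miRNAs farthest from the origin are selected,
  label-free) followed by PCA-based Fisher LDA on M′ sample-PC scores,
  validated leave-one-out; metrics: accuracy, sensitivity, specificity,
  rank-statistic AUC, and a one-sided Fisher exact p for the confusion table.
* **Differential testing** — per-miRNA two-sided Wilcoxon rank-sum tests
  (exact by enumeration for small tie-free samples, tie/continuity-corrected
  normal approximation otherwise) and boxplot-style group summaries.
* **Novel-candidate filtering** — retain candidates called at > 80% estimated
  true-positive probability in ≥ 4 distinct samples (both thresholds
  configurable, plus a relaxed any-sample probability mode).

## CLI

Every stage is a subcommand; `run` chains them end-to-end from a YAML config
and writes a provenance manifest (config hash, seed, versions, stage
timings).

```sh
# end-to-end on synthetic data
cat > config.yaml <<EOF
simulate:
  seed: 1
  n_mirna: 300
candidates: 10
EOF
mirdx run --config config.yaml --outdir out/

# individual stages
mirdx simulate --seed 1 --outdir sim/ --replicates 3 --candidates 10
mirdx average-probes sim/array_probes.tsv sim/probe_map.tsv --out sim/array_mirna.tsv
mirdx concordance --ngs sim/ngs_counts.tsv --array sim/array_mirna.tsv --out conc.tsv
mirdx classify --counts sim/ngs_counts.tsv --samples sim/samples.tsv \
    --out-prefix clf --m 11 --m-prime 2
mirdx difftest --counts sim/ngs_counts.tsv --samples sim/samples.tsv --out dt.tsv
mirdx filter-novel sim/candidate_calls.tsv --out novel.tsv
```

Classification defaults to log10(count + 1) followed by per-sample
z-scoring (`--no-log` z-scores raw values instead). The LDA threshold uses
equal class priors by default (`--priors proportional` weights by class
size).

## Layout

```
src/mirdx/
  matrix.py       ExpressionMatrix / SampleTable / ProbeMap containers
  io.py           readers and writers for all table dialects
  simulate.py     seeded synthetic-data generator
  normalize.py    log / z-score / probe averaging / positive common subset
  concordance.py  Pearson-based agreement measures
  features.py     PCA feature extraction, LDA, LOOCV, metrics, Fisher exact
  difftest.py     Wilcoxon rank-sum tests and group summaries
  novel.py        candidate-call filtering and reporting
  cli.py          click-based command-line interface
tests/            pytest suite (unit, property, and acceptance tests)
scripts/acceptance.py
```
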