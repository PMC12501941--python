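# spheroprot

Multi-batch isobaric-labeling (TMT-style) differential proteomics, built as a
tested, reusable pipeline. It covers the full analysis chain used to compare
3D spheroid and 2D monolayer cultures across several cell lines:

- **Synthetic data** (`spheroprot.simulate`) — ground-truth-labeled reporter
  signal-to-noise matrices with the multiplexed structure the analysis
  assumes: 4 cell lines × {2D, 3D} × 3 replicates randomly spread over 4
  18-plex batches, each carrying 3 pooled-reference channels; multiplicative
  per-(protein, batch) effects, sparse zeros, designated true differential
  proteins, and contaminant rows spiked only into 3D channels.
- **Ingest filters** (`spheroprot.ingest`) — unique-peptide S/N aggregation
  (mean reporter S/N strictly > 3), contaminant-group removal, and
  batch-support filtering (NA across a whole batch excludes a protein;
  literal zeros are kept as biological absence).
- **Normalization** (`spheroprot.normalize`) — zero floor (0.1), sample-wise
  median normalization, log2, per-batch reference-mean subtraction, row
  centering; PCA and correlation QC.
- **Differential analysis** (`spheroprot.differential`) — explicit row-wise
  one-way ANOVA (vectorized, NaN-aware), per-line 3D-vs-2D log2 fold
  changes, volcano filters (p < 0.01, |lfc| > 1 by default) and the
  significant + top-30%-by-SD heatmap selection.
- **Concordance & membrane annotation** (`spheroprot.concordance`) —
  cross-cell-line direction classes (common-up / common-down / discordant /
  not-common) and annotation-ratio tables with the baseline percentage.
- **Enrichment** (`spheroprot.enrichment`) — exact hypergeometric
  over-representation with Benjamini–Hochberg adjustment, and weighted
  running-sum GSEA with a seeded gene-label-permutation null (GMT I/O).
- **Dose–response** (`spheroprot.dose_response`) — background-corrected
  percent-of-control viability and multi-start 4PL fitting with a
  closed-form GI50.
- **Pipeline** (`spheroprot.pipeline`) — one-config orchestration with a
  hash-recording run manifest; fully deterministic for a fixed seed.

## CLI

```sh
spheroprot simulate --seed 11 --outdir out/
spheroprot ingest --quant out/quant.tsv --design out/design.tsv \
    --contaminants out/contaminants.txt --out out/filtered.tsv
spheroprot normalize --quant out/filtered.tsv --design out/design.tsv --out out/norm.tsv
spheroprot diff --norm out/norm.tsv --design out/design.tsv --out out/diff.tsv
spheroprot concord --diff out/diff.tsv --out out/concord.tsv
spheroprot membrane --diff out/diff.tsv --annot hpa.tsv --universe all.txt --out out/membrane.tsv
spheroprot enrich ora --query up.txt --gmt go.gmt --universe all.txt --out out/ora.tsv
spheroprot enrich gsea --rank ratios.tsv --gmt go.gmt -B 1000 --seed 7 --out out/gsea.tsv
spheroprot gi50 --plate plate.csv --out out/fits.tsv --seed 3
spheroprot run-all --config config.yaml --outdir run/
```

All tabular I/O is plain TSV/CSV/GMT. Quantification tables use one column
per channel keyed `<batch>:<channel>`; an empty cell is a missing value
(NA), a literal `0` is a measured zero — the two are distinct states and
are treated differently by the filters.

A minimal `run-all` configuration:

```yaml
seed: 11
thresholds:
  p_strict: 0.01
  p_relaxed: 0.05
  lfc_min: 1.0
  sd_top_frac: 0.3
  zero_floor: 0.1
  peptide_sn_min: 3.0
synthetic:
  replicates: 3
  n_batches: 4
  references_per_batch: 3
  params:
    n_proteins: 6000
    frac_de: 0.1
    n_contaminants: 50
```

Provide `quant`/`design` paths instead of the `synthetic` section to run on
real exported tables.

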