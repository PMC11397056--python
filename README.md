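# mircoex

Analysis pipeline for miRNA–mRNA co-expression screening on feature-by-sample
count matrices, built for small-RNA-seq profiles of extracellular-vesicle
miRNA paired with tissue mRNA expression. Starting from integer count tables
it provides:

- **Preprocessing** — low-count filtering (total across all samples strictly
  greater than a threshold, default 50), TMM normalization factors, CPM on
  effective library sizes, and the `log(x + sqrt(x^2 + 1))` (arcsinh)
  transform; top-k abundance-share summaries.
- **Differential abundance** — two independent negative-binomial tests per
  feature (a conditional exact test on library-equalized pseudo-counts and a
  Wald test from an NB log-linear model), each corrected by
  Benjamini–Hochberg, with a feature called DE only when *both* FDRs fall
  below the threshold (default 0.05).
- **Co-expression** — all miRNA×mRNA Pearson correlations with analytic
  p-values inside a (group, tissue) stratum, plus a permutation-based
  empirical FDR (default 10,000 randomizations of the sample pairing,
  threshold eFDR < 4e-5).
- **Target integration** — overlay of a predicted miRNA→gene target table
  (mature-name based, joined through a precursor→mature name map) on
  significant inverse-correlation pairs and on DE-miRNA/down-gene sets.
- **Enrichment** — hypergeometric category enrichment against the expressed
  background with Holm FWER control (significant at FWER ≤ 0.01).
- **Synthetic data** — an NB count simulator with heterogeneous library
  sizes, planted differentially abundant features and planted latent-factor
  co-expressed pairs with numerically calibrated correlation, emitting
  ground truth for every downstream stage.

## CLI

Each stage is a subcommand (`simulate`, `preprocess`, `de`, `coexpress`,
`integrate`, `enrich`) and `run-all` chains them, all driven by one YAML
config and a single master seed:

```bash
mircoex run-all --config config.yaml --outdir run --seed 1 [--n-rand 10000]
```

A config looks like:

```yaml
simulate:                      # optional; omit to analyse your own files
  n_samples_per_group: {AI: 7, IVP-ET: 7, NCP: 5}
  n_mirna: 263
  n_mrna: 500
  n_de: 10
  n_pairs: 20
  pair_rho: -0.9
data:                          # used when simulate is absent
  mirna_counts: counts/mirna.tsv
  mrna_counts: {EET: counts/eet.tsv, CAR: counts/car.tsv}
  sample_sheet: samples.csv    # sample_id,group,tissue
  target_db: targets.tsv       # mirna<TAB>gene<TAB>region (3UTR/5UTR/CDS)
  name_map: name_map.tsv       # precursor<TAB>mature
  annotation: annotation.tsv   # gene<TAB>category_id[<TAB>category_name]
contrasts: [[AI, NCP], [AI, IVP-ET]]
strata: [[AI, EET], [IVP-ET, EET]]
de_overlap_contrast: [AI, IVP-ET]
thresholds: {min_total: 50, alpha: 0.05, efdr: 4.0e-5, fwer: 0.01, n_rand: 10000}
```

Outputs land under `--outdir`: filtered counts and transformed expression
(`preprocess/`), per-contrast DE tables (`de/`), per-stratum co-expression
tables with eFDR (`coexpr/`), target-supported pairs and DE-target overlaps
(`integrate/`), enrichment tables (`enrich/`), and a machine-readable
`summary.json`. Identical config + seed reproduces identical outputs.

Count TSVs may be plain (`feature_id` + sample columns) or
featureCounts-style (annotation columns are dropped automatically); lines
starting with `#` are ignored.

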