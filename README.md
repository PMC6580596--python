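# panrx

A pan-cancer drug-response modeling benchmark: correlation-based feature
selection with matched controls, four regression families, and
histotype-structure diagnostics that quantify how much of a model's
apparent performance is driven by tissue of origin rather than
cell-specific response.

The package ships a synthetic-cohort generator with a controllable
histotype effect, so the full pipeline is testable without any external
download; it also ingests real cohorts provided as plain tables
(expression TSV, response CSV, annotation CSV).

## What it does

- **`panrx.synthetic`** — cohorts with histotype-structured expression
  (per-histotype centroids on a probe subset) and a response decomposed
  into a histotype mean effect, a gene-driven effect and noise. The
  fraction of signal variance carried by histotype (`hist_var_share`) is
  an explicit knob; censored-IC50 flags and replicate measurements are
  emulated. Ground truth is returned for recovery tests.
- **`panrx.cohort`** — loading/validation, replicate averaging,
  censored-cell filtering, and histotype-stratified 75/25 train/test
  splits (plus an optional disjoint-test-fold mode).
- **`panrx.features`** — the selection strategies: all probes (NOFS),
  Spearman screen at p < 0.05 (DEG), Bonferroni-corrected screen (BC),
  empirical-Bayes moderated-t on response tails with BH-FDR (MODT),
  bootstrap consensus screens (BS, BS_HIST), greedy
  max-relevance/min-redundancy (MRMR), size-matched random control
  (CTR1), DEG complement (CTR2), shuffled-matrix control (RCTR), and
  one-hot histotype encoding (HIST).
- **`panrx.models`** — principal-components regression, linear/RBF
  support vector regression, a single-hidden-layer neural net with
  dropout (optional numpy backend), and the histotype-mean baseline; all
  tuned by Monte Carlo cross-validation on training cells only.
- **`panrx.evaluate`** — Spearman rho with t-approximation p, mean
  absolute difference, the weighted-probability concordance index
  (0.5 under permutation; undefined — raised, not NaN — at zero
  prediction variance), its permutation null, and paired Wilcoxon
  method comparisons.
- **`panrx.histostruct`** — k-means cluster entropy S_c (0 for
  histotype-pure clusters) normalized by shuffled-matrix controls, and
  pairwise histotype F-tests of response with the fraction-significant
  summary.
- **`panrx.pipeline`** — the drugs x splits x methods x families grid
  with per-cell seeds, resumable output, and the feature-count sweep
  with a paired entropy audit.

## CLI

```bash
panrx simulate --spec spec.yaml --out cohort/ --seed 3
panrx split    --expr cohort/expression.tsv --response cohort/response.csv \
               --annotation cohort/annotation.csv --n-splits 6 --out splits.json
panrx select   --method deg --expr ... --response ... --splits splits.json --out deg.json
panrx fit      --family pcr --features deg.json --splits splits.json --split-index 1 \
               --expr ... --response ... --annotation ... --out pred.csv
panrx evaluate --pred pred.csv --metric spearman,mad,wpc --wpc-null 3000 --seed 1
panrx histotype-audit --expr ... --response ... --annotation ... --features deg.json
panrx run      --config experiment.yaml
panrx sweep    --counts 10,55,250,500,1000 --source deg --families pcr ...
```

`experiment.yaml` names the three cohort files plus `feature_methods`,
`families`, `n_splits`, `seed`, `out_dir` and optional per-family
`model_configs` overrides (grids, CV folds).

## Notes

- Default SVR grids match the published combination counts (210 RBF /
  30 linear) but the specific values are package choices; grids are
  fully configurable per family.
- The ANN backend is a deliberately small numpy implementation (20
  hidden units, inverted dropout, Adam); nothing downstream depends
  on it.
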