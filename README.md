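# m6ascore

Stratification of expression cohorts by the joint expression pattern of a
24-gene RNA-methylation regulator panel, and everything downstream of it:

- **Consensus clustering** of samples on the regulator panel (resampled Ward
  agglomerative clustering; k chosen by PAC, the proportion of ambiguous
  consensus entries).
- **Phenotype-associated genes**: pairwise Wilcoxon + fold-change contrasts
  between clusters, "core" genes significant in ≥2 of the 3 contrasts, and
  hypergeometric overlap testing against user-supplied target lists.
- **Signed prognostic score**: a univariate Cox screen over the core genes
  partitions them into risk (HR > 1) and protective (HR < 1) lists; the
  per-sample score is `sum(z of risk genes) − sum(z of protective genes)`.
  A companion regulator-panel signature uses the panel's fixed ±1 weights
  (20 positive, 4 negative).
- **Survival statistics** built from the partial likelihood up: Cox
  (Newton–Raphson, Efron ties), Kaplan–Meier, log-rank with hypergeometric
  variance, the maximally selected rank-statistic cutpoint, and rank-based
  ROC AUC.
- **Single-sample enrichment** (rank-weighted running-sum scores) for
  arbitrary GMT collections, 28 TIL subpopulation sets, 7 immunity-step
  sets, and immune/stroma summary scores.
- **Drug-sensitivity screen**: Spearman correlation of per-cell-line scores
  with IC50 per compound (exact permutation p for n ≤ 8), retained at
  |r| > 0.1 and p < 0.05, labeled resistant (r > 0) / sensitive (r < 0).
- **Synthetic cohorts** with planted cluster structure, proportional-hazards
  survival, ordinal grade/stage, immune/stroma signal and linked cell-line
  IC50s, so the entire pipeline is testable offline.

## CLI

Everything is driven either by subcommands or by one YAML config:

```bash
# full pipeline on a simulated cohort
cat > config.yaml <<EOF
seed: 1
out_dir: run1
simulate:
  n_samples: 300
EOF
m6ascore run --config config.yaml
m6ascore summarize run1
```

Individual stages: `m6ascore simulate | preprocess | cluster | score | apply |
enrich | drugs` (see `--help` on each). Run directories contain fixed-name
outputs (`clusters.tsv`, `degs.tsv`, `model.tsv`, `scores.tsv`,
`survival.tsv`, `enrichment.tsv`, `drugs.tsv`, `manifest.json` with SHA-256
hashes of every output). Identical config + seed reproduces byte-identical
outputs; the global seed is fanned out to per-stage sub-seeds so adding a
stage never perturbs earlier stages.

To run on real data, point `expression` (tab-separated counts, genes ×
samples), `clinical` (columns `sample_id`, `time_months`, `event`, `grade`,
`stage`), optional `drug_table` / `cell_line_expression`, and GMT gene-set
paths at the config instead of the `simulate` block. Expression is expected
as raw counts; it is filtered (≥3 reads in more than one third of samples),
CPM + log2 normalized, and z-scored per gene internally.

## Notes and caveats

- The maximally-selected cutpoint is reported with a plain log-rank p
  downstream; no selection correction is applied, which is optimistic.
- ssGSEA ties are broken by a seeded shuffle recorded in the log.
- ImmuneScore/StromaScore are plain enrichment of user-supplied immune and
  stromal sets, not the published coefficient-based estimator.
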