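# breathdiscrim

Discovery and validation of exhaled-breath volatile organic compound (VOC)
biomarker panels for detecting compensated liver cirrhosis (CIR) among
patients with chronic liver disease (CLD), from GC-MS breath profiles
("breathograms"). The package is aimed at breathomics / metabolomics
researchers who need the full statistical chain — preprocessing, supervised
panel selection, and honest resampling-based validation — as tested,
scriptable building blocks rather than point-and-click chemometrics.

## What it does

* **Synthetic cohorts** (`breathdiscrim.synthetic`): generates feature
  matrices (default 34 CIR / 87 CLD / 31 healthy controls × 3718 compounds)
  with a planted 11-compound discriminatory panel of known signed directions,
  block-correlated compounds, realistic covariates, and optionally raw
  chromatograms (Gaussian peaks + drift + column bleed + noise), so the whole
  pipeline is testable without any instrument data.
* **Preprocessing** (`breathdiscrim.preprocess`): Savitzky–Golay smoothing,
  asymmetric-least-squares baseline/bleed correction, segment-wise
  retention-time alignment, prominence-based peak integration into a samples
  × compounds matrix.
* **PLS-DA** (`breathdiscrim.plsda`): NIPALS partial least squares
  discriminant analysis in the standard two-equation form

      X = T P' + E        y = T q + f        (equivalently  y = X b + r)

  with orthogonal latent-variable scores T, loadings P/q and regression
  vector b = W(P'W)⁻¹q; class probabilities from class-conditional Gaussians
  on the continuous prediction (they sum to 1 by construction); score-plot
  and bi-plot data.
* **sMC selection** (`breathdiscrim.smc`): significant multivariate
  correlation — each compound's scaled column is regressed on the model's
  prediction direction ŷ = Xb, giving F = (SSR/1)/(SSE/(n−2)) against
  F(1, n−2); panels by Benjamini–Hochberg FDR (or fixed top-k).
* **Validation** (`breathdiscrim.validate`): repeated stratified holdout
  (default 27+27 train, 7+7 validation-1, 1000 repeats, plus a fixed
  hold-back validation-2 set), pooled probability-based ROC with Youden
  optimal cutoff, sensitivity/specificity/NPV/PPV, and a label-permutation
  test (p = max(1, #{null ≥ observed})/B).
* **Cohort statistics** (`breathdiscrim.cohortstats`): Mann–Whitney U and
  Pearson chi-square group comparisons ("table one"), and a
  shrinkage-regularized MANOVA (rMANOVA) screen of the selected panel against
  confounders (etiology, drug therapy, smoking).
* **Orchestration** (`breathdiscrim.report`, CLI `breathdiscrim`): one YAML
  config drives simulate/ingest → select → fit → validate → cohort stats →
  plain-text figure/table exports with a checksummed manifest.

## Worked example

```sh
cat > config.yaml << 'YAML'
out_dir: results
seed: 7
generator:
  n_compounds: 500
  effect_magnitude: 1.5
  n_per_class: {CIR: 34, CLD: 87, HC: 31}
n_repeats: 200
n_perm: 200
rmanova_n_perm: 499
YAML
breathdiscrim run --config config.yaml
```

This simulates a 152-sample cohort with 11 truly discriminatory VOCs among
500, selects a panel by sMC at FDR 0.05 inside the first training split,
validates it by 200 stratified holdout repeats and a 200-iteration
permutation test, and writes `results/`. With the config above the run
prints `wrote 12 artifacts to results`, and the key outputs are:

* `validation.json` — pooled AUC 0.997 (95% CI across repeats 0.980–1.000),
  sensitivity 0.981 / specificity 0.966 at the optimal pooled cutoff,
  NPV 0.980, PPV 0.967, validation-2 accuracy 0.992, permutation p = 0.005
  (= 1/200, the smallest attainable value: the observed AUC beat every
  permutation).
* `panel_table.tsv` — the sMC table (F, p, q, selected, signed direction);
  here all 11 planted compounds and nothing else are selected.
* `rmanova.json` — the panel separates the classes (p = 0.002 = 1/499 floor)
  but shows no etiology, smoking or drug effect (p = 0.43 / 0.38 / 0.69),
  i.e. the discrimination is not explained by those confounders.
* `score_plot.tsv`, `biplot_loadings.tsv`, `roc_points.tsv`,
  `table_one.tsv` — figure/table data for external plotting.

Numbers are exactly reproducible given the config and seed. Stage-wise
commands (`simulate`, `preprocess`, `discover`, `validate`) expose the same
machinery for user-supplied delimited feature tables or chromatograms — a
five-column serology table runs through the identical pipeline.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the permutation-test floor: on a synthetic cohort
with a very strongly planted 11-compound panel the observed holdout AUC
exceeds all 1000 label-permutation statistics, and the count-over-iterations
convention with a one-count floor yields the reported p-value.

## Documentation

`docs/methods.md` describes the model, the reconstruction choices (number of
latent variables, probability transform, sMC selection rule, permutation
convention, rMANOVA regularization), what the synthetic generator does and
does not emulate, and known limitations.
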