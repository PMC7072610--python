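# immunomet

Baseline immune-metabolomics analysis of plasma ¹H NMR fingerprints for
two-arm clinical contrasts, built for translational metabolomics studies in
which a binned CPMG plasma spectrum, a cytokine panel and a handful of
clinical labels (receptor status, treatment response, relapse) have to be
related to each other with small sample sizes.

The package implements, as a tested and reusable pipeline:

* **Spectral preparation** — fixed-width bucketing of processed 1D spectra
  (default 0.2–10.0 ppm in 0.02-ppm buckets), removal of buckets overlapping
  solvent/additive windows (residual water 4.39–6.00 ppm; dextrose and
  citrate windows), trapezoidal integration on the native ppm grid, and
  total-integral normalization. With the default plasma CPMG profile the
  490 buckets reduce to exactly 368.
* **PCA-CA-kNN classification** — projection into a principal-component
  subspace, canonical (Fisher) analysis of the PC scores
  (the generalized eigenproblem **B**v = λ**W**v of the between/within
  scatter matrices, ridge-regularized), and k-nearest-neighbour voting in
  canonical score space. Performance by leave-one-out or Monte-Carlo
  cross-validation with the whole pipeline refit per fold; significance by a
  label-permutation test on the LOOCV accuracy,
  p = (#{null ≥ observed} + 1)/(N + 1); loading back-projection of the first
  canonical axis into bucket space to name the discriminating ppm regions.
* **Univariate biomarker screening** — Wilcoxon–Mann–Whitney per feature
  (exact for small tie-free samples), Benjamini–Hochberg FDR across the
  tested family, Cliff's delta δ = (#{x>y} − #{x<y})/(n₁n₂) with the
  0.147/0.33/0.474 magnitude convention, rank-based AUROC (= U/(n₁n₂)), a
  Youden-optimal threshold, and Pearson correlation for independence checks.
* **Biomarker fusion** — a two-feature weighted linear combination
  w₁z₁ + w₂z₂ on training-standardized, orientation-corrected features
  (weights by exhaustive AUROC grid scan or two-feature Fisher
  discriminant, reported as percentages with |w₁| + |w₂| = 1), and a
  "logic OR" of two binary predictors with confusion-table summary.
* **Cohort characteristics tests** — Pearson chi-square (no continuity
  correction) for categorical arm comparisons, pooled/Welch t-tests from
  raw values or printed (mean, sd, n) summaries.
* **A synthetic cohort generator** — because studies of this kind rarely
  deposit patient-level data, the pipeline ships a generator that emulates
  their statistical structure: a synthetic plasma template profile with
  multiplicative log-normal bucket noise and arm-dependent fold changes in
  named lipoprotein ppm windows, log-normal cytokine panels with
  class-dependent shifts and arm-wise block missingness, and deterministic
  or logistic clinical labels. Every analysis stage is exercised end to end
  on these cohorts.

## Worked example

```python
from immunomet import simulate, pipeline

cohort = simulate.generate(simulate.default_cohort_spec(), seed=1)
bundle = pipeline.run_full_analysis(
    cohort.matrix, cohort.meta, cohort.markers, seed=1, n_perm=1000
)
```

The default cohort has 21 ER(−) and 22 ER(+) samples, fold-1.3 intensity
shifts in five lipoprotein windows of the ER(+) arm, and a marker panel in
which valine is higher in partial responders, TNF-α higher in complete
responders (and unmeasured in 38% of the ER(−) arm), and IL-2/IL-10 lower
in relapsers. Summarizing the bundle prints:

```
ER contrast: LOOCV accuracy 0.814 (sens 0.773, spec 0.857), permutation p = 0.0010, n_pc = 8
top CV1 loading buckets (ppm): 1.25, 1.31, 1.27, 0.83, 1.23
valine (GR vs PR): delta = -0.80 (large), AUROC = 0.90, p = 0.0016, q = 0.0065
TNFa+valine fusion: 62.0% TNFa + 38.0% valine, AUROC = 0.98
relapse logic-OR: sens 87.5%, spec 100.0%, acc 95.5%
```

Reading: the spectral classifier separates the arms well above chance
(81.4% LOOCV accuracy; none of 1000 label permutations did better), and the
top-ranked loadings sit inside the spiked 1.23–1.37 and 0.83–0.91 ppm
windows. Valine discriminates responders with a large negative Cliff's
delta (lower in complete responders), the cytokine–metabolite fusion
improves on either feature alone, and OR-ing the cytokine model with the
spectral relapse classifier trades specificity for sensitivity exactly as
the truth table dictates.

The same analyses are available from the shell:

```bash
immunomet simulate --seed 1 --out-dir cohort/
immunomet run-all --matrix cohort/matrix.csv --meta cohort/meta.csv \
    --cytokines cohort/cytokines.csv --seed 1 --out bundle.json
immunomet classify --matrix cohort/matrix.csv --meta cohort/meta.csv \
    --label er_status --n-pc auto --perms 1000 --seed 1 --out er.json
```

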