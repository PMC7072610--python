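# Methods

This note documents the models, numerical choices and limitations of the
immunomet pipeline, module by module, and states what the synthetic-data
tests do and do not demonstrate about real data.

## Spectral preparation

Input spectra are assumed fully processed upstream: Fourier-transformed,
phased, baseline-corrected and chemical-shift calibrated. The pipeline
starts at bucketing.

Buckets are left-closed/right-open intervals on the lattice
`range_low + i·bin_width`, tiling `[range_low, range_high)`. The shipped
`plasma_cpmg` profile uses 0.2–10.0 ppm and 0.02-ppm buckets (490 buckets)
with five exclusion windows: 4.39–6.00 ppm (residual water) and the
dextrose/citrate windows 3.71–3.91, 3.23–3.55, 2.51–2.69 and 1.15–1.19 ppm.
A bucket is removed iff it overlaps an exclusion window with positive
measure — boundary touching does not remove — which leaves exactly 368
buckets. This edge convention is the one under which the positive-measure
overlap rule yields that count; exclusion windows quoted in descending ppm
order are normalized internally to (low, high).

Integration is trapezoidal on the native ppm grid (spectra treated as
piecewise linear; bucket edges between grid points handled by linear
interpolation), so it is exact for the piecewise-linear model, additive
across adjacent buckets, and requires no resampling. Axes stored in
descending ppm order (the usual NMR display convention) are reversed on
load. Negative intensities from baseline artifacts are integrated as-is; a
negative bucket area triggers a logged warning, never clipping.

Total-integral normalization divides each sample's bucket vector by its own
sum, removing dilution and receiver-gain scale. It is idempotent and
invariant to positive rescaling of a spectrum. Note the closure it
introduces: raising true intensity in some buckets necessarily lowers the
normalized values of all others, which matters for interpreting loadings
(below).

## PCA-CA-kNN classifier

PCA is column-mean-centred SVD; components are ordered by explained
variance. Canonical analysis solves the generalized symmetric eigenproblem
**B**v = λ(**W** + εI)v on the PC scores, with between/within scatter
matrices **B**, **W** and ridge ε = 1e-8·trace(**W**)/p to guard against a
singular within-scatter; for g groups at most g−1 canonical directions have
nonzero criterion, so a two-group contrast yields a single canonical axis.
Classification is a Euclidean k-nearest-neighbour vote in canonical score
space; vote ties fall back to the single nearest neighbour's label. k is a
free parameter (default 5, odd); when a training fold is smaller than k it
is clipped with a warning. k = 5 is a robustness choice for cohorts of
roughly 20 per arm — small enough to stay local, large enough not to be
dominated by one neighbour.

Cross-validation refits the entire pipeline — centering, PCA, CA — on each
training fold, so the held-out sample never influences the model that
predicts it (verified in a unit test against a naive fold-wise refit).
Sensitivity, specificity and accuracy are pooled over out-of-fold
predictions; positive-class conventions are ER(+), complete response (GR)
and relapse. A stratified Monte-Carlo CV (default 80% train, averaged over
repetitions) is provided as a consistency check on the LOOCV figures.

The permutation test recomputes the LOOCV accuracy under uniformly
permuted labels and reports the add-one estimator
p = (#{null ≥ observed} + 1)/(N + 1), which is never exactly zero and is
bounded below by 1/(N+1). Because PCA is unsupervised, each fold's
centering and loadings are label-invariant; they are computed once and
cached, and only the CA directions and kNN vote are refit per permutation.
This is an exact optimization, not an approximation (a test asserts
equality with the uncached path).

The number of retained components is chosen as the smallest candidate whose
whole-data LOOCV accuracy attains the maximum over the candidate range
(default 1–8). Selecting on the same LOOCV that is afterwards reported is
optimistic; `loocv_nested_selection` re-selects the component count inside
every training fold and reports the honest out-of-fold metrics plus the
per-fold choices, so the optimism gap can be quantified when it matters.

Loading analysis back-projects the first canonical direction through the
PCA loadings into bucket space and ranks buckets by absolute weight; each
bucket also carries the group whose mean normalized intensity is higher.
Because of normalization closure, buckets outside a truly perturbed region
acquire a compensatory anti-signal proportional to their intensity share.
Consequently "recovery" of perturbed regions is read at the head of the
ranking — in this package's tests, recovery means that the majority of the
ten highest-|weight| buckets fall inside the perturbed windows — rather
than demanding that every perturbed bucket outrank every unperturbed one,
which closure makes unattainable for low-intensity buckets.

## Univariate screening

The Wilcoxon–Mann–Whitney test is two-sided, exact (full null enumeration)
when n₁+n₂ ≤ 20 with no ties, otherwise normal approximation with tie and
continuity corrections. Benjamini–Hochberg q-values use the step-up rule
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j capped at 1; the FDR family is the set of features
tested in one call (one contrast's full panel). Cliff's delta is computed
through the U identity δ = 2U/(n₁n₂) − 1 (ties contribute zero net
dominance) and labelled negligible/small/medium/large at the conventional
0.147/0.33/0.474 cuts; |δ| = |2·AUROC − 1| holds identically, and both are
computed by independent routes and cross-checked in tests. Missing values
are deleted pairwise per feature, with per-group n reported — this is what
allows a cytokine unmeasured in a third of one arm to remain testable.
Youden thresholds scan midpoints of consecutive sorted unique values (plus
open ends), call "positive" above the threshold, and break J-ties toward
the higher-specificity cut.

## Fusion models

The two-feature linear model z-scores each feature on training data and
orients it toward the positive class (a feature with training AUROC < 0.5
enters negated), so fitted weights are reported as positive percentages.
The default "grid" method scans w₁ ∈ [0,1] in steps of 0.001 and maximizes
training AUROC of w₁s₁ + (1−w₁)s₂; since the scan includes both endpoints
the combination can never score below either single feature on the
training data. A "lda" method (two-feature Fisher coefficients, normalized
to |w₁|+|w₂| = 1) is provided as the model-based alternative; how the
percentage weights of published two-feature panels were derived is
generally not stated, so both routes are exposed and the published weight
pairs (78.4/21.6 and 96.1/3.9) ship as fixture constants usable without
refitting. Training AUROC of the fitted combination is reported as
resubstitution; it is labelled as such in the output because with ~11 per
arm it is optimistic.

The AUROC grid surface is flat near its optimum, so the single-draw argmax
has substantial sampling spread; the weight-recovery check therefore runs
as a simulation, comparing the mean recovered weight over seeded draws of
n = 200 against the generator's known population optimum (for independent
equal-variance Gaussian features the optimal weights are proportional to
the standardized mean shifts).

Logic-OR fusion calls a sample positive if either input model does. A
missing vote counts as negative in that input (logged per sample), so a
sample covered by only one model can still be predicted; fully disjoint
sample sets are an error. OR-fusion can only raise sensitivity and lower
specificity relative to its inputs, which the tests assert as an
invariant.

## Cohort characteristics tests

Chi-square is Pearson's statistic without Yates continuity correction —
the convention that reproduces the reference cohort table's printed
p-values (0.432 response, 0.443 stage, 0.097 recurrence) exactly; expected
counts below 5 produce a logged warning only. t-tests are two-sided,
pooled or Welch, from raw values or from printed (mean, sd, n) summaries.
The reference table's BMI row prints p = 0.19, but the printed summaries
(24.1 ± 9.0, n = 21 vs 26.6 ± 6.1, n = 22) give p ≈ 0.29 pooled and ≈ 0.30
Welch; the computed value is the one asserted. The age row (medians and
ranges only) and the grade row are not reproducible from the printed
numbers and are not asserted.

## Synthetic cohort generator

The generator produces the structure the analysis assumes, not a forward
physical model of NMR acquisition.

* **Spectra.** The template is a synthetic profile — Lorentzian bumps at
  common plasma metabolite and lipoprotein shifts (lipid CH₃/CH₂, lactate,
  alanine, acetate, glutamine, citrate, creatinine, choline, glucose,
  aromatics) over a small constant baseline — not a measured spectrum.
  Bucket values are template × class fold × mean-one log-normal noise with
  coefficient of variation `bin_noise_cv` (default 0.25); additive Gaussian
  noise is available as an option. Log-normal multiplicative noise is the
  default because plasma bucket intensities are positive and right-skewed.
  The estrogen-receptor contrast raises five lipoprotein windows
  (3.55–3.57, 3.17–3.19, 2.05–2.23, 1.23–1.37, 0.83–0.91 ppm) in the ER(+)
  arm by fold 1.3 — about one noise SD per bucket on the log scale, spread
  over ~27 buckets, i.e. individually weak but multivariately clear.
* **Markers.** Log-normal per analyte with class-keyed log-mean shifts and
  arm-wise Bernoulli missingness (TNF-α missing with probability 0.38 in
  the ER(−) arm). Shifts are sized analytically through the normal-theory
  link AUROC = Φ(d/√2), δ = 2·AUROC − 1: valine d = 1.6 (δ ≈ −0.75, lower
  in complete responders), TNF-α d = 1.5 (higher in complete responders),
  IL-2 d = 1.2 and IL-10 d = 0.4 (lower in relapsers). Real cytokine panel
  distributions were not available to calibrate against; these parameters
  are declared synthetic.
* **Labels.** Deterministic mode draws exact per-arm counts
  (21 ER(−)/22 ER(+); responses 13/8 and 11/11; relapses 3 and 8) for
  golden tests; logistic mode draws response/relapse from a logistic model
  on named markers for power and recovery studies.
* **Reproducibility.** One integer seed drives a single generator stream;
  the same seed reproduces the cohort bitwise, and the generating spec
  round-trips through `truth.json`.

What passing tests show: the pipeline detects and localizes effects of the
designed kind (regional multiplicative shifts, log-scale marker shifts) at
the designed sizes, controls type-I error on null cohorts, and keeps its
cross-validation honest. What they do not show: performance on real plasma
spectra, whose bucket correlation structure (shared lipoprotein envelopes,
peak-position jitter, baseline drift correlated across neighbouring
buckets) is richer than independent per-bucket noise; real effect
topologies; or calibration of cytokine distributions to any actual cohort.

## Problem sizes and tolerances

Statistical guarantees are verified at desk scale: type-I control on 200
null cohorts of n = 20 with 30 noise features and 99 permutations each;
chance-level behaviour on 100 null cohorts; loading recovery on 50 seeded
study-like cohorts; weight recovery averaged over 20 draws of n = 200.
Numerical tolerances: PCA orthonormality and reconstruction at 1e-8;
normalization row sums at 1e-9; the δ/AUROC identity and BH oracle at
1e-12; printed-value reproductions at the printed precision (±0.001 for
the chi-square p-values, one decimal for percentages).

## Known limitations

* Canonical analysis is implemented for the two-group case in anger;
  multi-group contrasts are supported structurally (g−1 axes) but not
  exercised by the studies this pipeline targets.
* Whole-data component selection reproduces common practice but is
  optimistic; the nested variant is the honest alternative and is the one
  to report when the selection matters.
* The resubstitution AUROC of fusion models is not cross-validated;
  out-of-sample assessment of a fused pair requires an outer loop the
  package leaves to the caller.
* No DeLong confidence intervals for AUROC and no survival modelling; the
  relapse analysis is a fixed-horizon binary contrast.
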