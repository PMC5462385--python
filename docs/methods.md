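# Methods

## Model

The core model is a latent class growth analysis (LCGA): a finite mixture
of polynomial growth curves with no within-class random effects. Subject
*i* belongs to one latent class *c*ᵢ ∈ {1, …, K} with prior probabilities
π = (π₁, …, πₖ); given *c*ᵢ = k, every score is

  yᵢₜ = β₀ₖ + β₁ₖ t\*ᵢₜ + β₂ₖ t\*ᵢₜ² + εᵢₜ,  εᵢₜ ~ N(0, σₖ²) i.i.d.,

with t\* = t − t̄ the time (years since the subject's first retained score)
centered at the mean observation time of the cohort. The centering
constant is stored on the fitted model so predictions are reproducible.
The subject, not the observation, is the mixture unit: all scores of a
subject share one class, so EM responsibilities are computed per subject
from the product of its per-observation densities (log-sum-exp over
classes for stability).

Key assumptions: conditional independence of scores within subject given
class; Gaussian residuals with class-specific variance on a bounded (0–30)
instrument; a quadratic mean path; no informative dropout (follow-up
length is independent of class).

Parameter count per full K-class model is 3K growth coefficients + K
residual SDs + (K − 1) free mixing proportions = 5K − 1 (29 at K = 6).
AIC = −2ℓ + 2p; BIC = −2ℓ + p·ln(n_obs) with n_obs the number of score
observations, not subjects — both conventions back out exactly from the
published model-comparison table this pipeline mirrors.

## Fitting and numerical choices

* **EM** with responsibility-weighted least squares per class in the
  M-step (β̂ₖ from weighted normal equations, σ̂ₖ² as the weighted mean
  squared residual, π̂ from mean responsibilities). The observed-data
  log-likelihood is asserted non-decreasing at every iteration;
  convergence at relative change < 1e-8 or 1000 iterations.
* **Initialization.** Default: per-subject (level, slope) least-squares
  summaries, standardized, partitioned by k-means with random (++)
  seeding per restart; initial responsibilities are 0.9 one-hot + 0.1
  uniform. 20 restarts, best final log-likelihood wins. Symmetric
  Dirichlet(1) responsibility draws are available (`init="dirichlet"`)
  but are a poor default at this scale: with K = 6 and thousands of
  subjects they are nearly uniform, so all restarts start from almost the
  same (class-collapsed) point and EM reliably lands in degenerate optima
  with one near-empty, high-variance component.
* **Degeneracy handling.** σₖ is clamped at 0.1 MMSE points (prevents
  likelihood blow-up on clusters with near-constant scores); a class
  whose mixing share drops below 1/n_subjects is removed and the fit
  continues with fewer classes, so the effective class count can be
  smaller than requested — mirroring the behaviour of the standard
  mixture software for over-specified K.
* **Coefficient SEs** come from the per-class responsibility-weighted
  least-squares covariance at convergence. They ignore classification
  uncertainty, the same approximation class as the mixture-of-regressions
  software this mirrors.
* **Labels** are canonicalised in strictly descending intercept order, so
  class 1 is always the highest-functioning trajectory.
* **BLRT.** Observed statistic 2(ℓₖ − ℓₖ₋₁), clamped at 0 with a warning
  if the larger model lands on a worse optimum. Null replicates are drawn
  from the fitted (k−1)-class model on the observed per-subject time
  grids; both models are refitted with 5 restarts per replicate (cheaper
  than the main fit — a documented approximation), and
  p = (1 + #{LR\* ≥ LR}) / (B + 1) with B = 99 by default. Note the
  smallest attainable p is 1/(B+1), so sequential selection at p < 0.05
  needs B ≥ 39.
* **Selection rule.** Walking up from k = 2, the selected K is the
  largest k with BLRT p < 0.05 before the first non-significant step,
  even if BIC keeps falling for larger k.
* **Relative entropy** (classification certainty):
  EIC = 1 − Σᵢₖ(−pᵢₖ ln pᵢₖ)/(n ln K), with 0·ln 0 := 0; undefined at
  K = 1.
* **Multinomial logit** (class characterisation): in-package Newton
  iterations with analytic gradient and observed information, per-row
  weights (needed for the posterior-weighted sensitivity fit, where each
  subject contributes one pseudo-observation per class weighted by pᵢₖ),
  backtracking line search, convergence at gradient max-norm < 1e-6, SEs
  from the inverse information. Coefficients |β| > 15 are flagged as
  possible separation. The unweighted fit matches statsmodels' MNLogit to
  ~1e-11 (tested).
* **Multiplicity.** Benjamini–Hochberg over all class-contrast ×
  covariate coefficients of the final model (m is computed and logged);
  FCR-adjusted Wald intervals at two-sided level 1 − Rα/m for the R
  BH-selected coefficients, i.e. the Normal quantile at 1 − Rα/(2m).
* **Stepwise selection** is backward over whole variable blocks (a
  categorical variable enters or leaves with all its levels), with the
  adjusters (age, education, gender, ethnicity, baseline MMSE) forced in;
  the per-step AIC ledger is emitted.
* **Prediction harness.** Stratified 80:20 split; training majority class
  down-sampled to balance (the conservative reading of "sampled to give
  an equal proportion"); near-zero-variance filter with the standard
  frequency-ratio > 95/5 and unique-fraction < 10% thresholds;
  continuous features centered/scaled by training statistics only.
  RFE ranks features within each resample (default ranking: distance of
  the univariate AUC from 0.5, which applies to any classifier) and picks
  the subset size with the best mean CV accuracy. Accuracy CIs are exact
  Clopper–Pearson; AUC is the Mann–Whitney rank statistic on the SVM
  decision values (recorded as such).

## Synthetic cohorts

The generator emulates a memory-clinic EHR extract at its published
scale: 3441 subjects, six quadratic trajectory classes with the published
coefficients and shares (14/22/22/9/18/14 %, renormalised from their
rounded sum of 99), 3–8 visits per subject, and follow-up drawn from a
log-normal calibrated to median 1.70 y (IQR 0.79–2.99) and capped at the
8-year observation window of the emulated study design (referral and all
scores fall in one 8-year period; without the cap the log-normal tail
produces multi-decade follow-ups whose extrapolated trajectories distort
everything downstream). First and last visit anchor the follow-up span;
interior visits are uniform.

Residual SD defaults to 2.5 MMSE points for all classes (configurable).
The published table reports coefficient SEs, not residual SDs; 2.5 is a
realistic repeat-measurement spread for MMSE and, at this cohort size,
leaves all six intercepts recoverable within ±0.5 (tested over seeded
replicates).

Scores are truncated to [0, 30] after noise (the truncation rate is
recorded on the cohort); numerators are stored as integers with
denominator 30. Artifact injection then reproduces the recording quirks
the preprocessing rules exist for: 7% of records get a denominator drawn
from 20–29 (numerator rescaled so the re-weighted score stays close to
the underlying value), a small configurable fraction gets a denominator
below 20 (exclusion material), and a configurable fraction of
subject-dates gains a same-day duplicate differing by 1–2 points with a
later record sequence.

Baseline covariates are linked to class by multinomial-logit inversion:
covariates are drawn marginally (binary drugs, 4-level HoNOS items,
continuous age), then the class label is drawn from a logit whose
covariate effects are the published log relative-risk ratios (reference
class 4) and whose intercepts are tuned by fixed-point iteration so the
marginal class shares hit their targets. This makes multinomial parameter
recovery well-posed. Drug covariates materialise as prescription
episodes overlapping baseline (sometimes split into chained scripts ≤ 42
days apart, so episode merging is exercised); HoNOS covariates as ratings
near baseline, with moderate/severe draws recorded as raw "Moderate" or
"Severe" so the category collapse is exercised.

### What the generator does *not* emulate

* Mortality and informative dropout (41% of the real cohort died during
  follow-up); follow-up length is class-independent here.
* Floor/ceiling measurement dynamics beyond simple truncation — the real
  instrument's non-linearity across severity is not modelled.
* The feature asymmetry that made the fast-declining class hard to
  detect in the real data: with the generator's symmetric
  class-conditional covariate shifts, the prediction harness achieves
  sensitivity ≈ specificity, not the strong sensitivity deficit reported
  on real data. Passing harness tests therefore validate the machinery,
  not that real class-4 patients are predictable.
* Free-text clinical notes and diagnosis adjudication.

## Known limitations and observed behaviour

* **Modal-assignment bias.** Maximum-posterior assignment inflates the
  modal class share when classes overlap (classification entropy ~0.8):
  ambiguous subjects funnel into larger classes. On cohorts simulated at
  the default conditions the largest assigned share runs ~23.8–25.5%
  against a generating share of 22.2%; the fitted mixing proportion
  itself stays near 22%. Analyses that need shares should use π̂ or
  posterior-weighted quantities, not assignment counts.
* **Attenuation under misclassification.** Multinomial effects estimated
  on assigned (rather than true) classes are attenuated toward 1 —
  visible in the README example — which is exactly why the
  posterior-weighted sensitivity fit exists.
* **Refit stability.** A K-class ML solution on data generated from an
  overlapping K-class mixture is not guaranteed to reproduce the
  generating partition; recovery here was verified for the default
  conditions, and gets fragile as residual SD grows or follow-up
  shortens.
* The BLRT's bootstrap refits use fewer restarts than the main fit; with
  very unlucky optima this can inflate bootstrap LRs (conservative p).

## Problem sizes used in the shipped experiments

Recovery experiments run at the emulated study's full size (3441
subjects; ~19k observations) — 3 replicates for the growth-mixture refit
and 10 for the multinomial recovery, the latter reported as a
geometric-mean RRR because a single replicate's log-RRR carries a
Monte-Carlo SE of ~0.24 at 10% covariate prevalence. Unit and property
tests run on 120–4000-subject cohorts with reduced restart/bootstrap
counts, chosen so the full suite completes in a few minutes.
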