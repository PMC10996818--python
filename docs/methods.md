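# Methods

This note documents the statistical models implemented in `neurosync`, the
parameterization of the synthetic-data generators, the numerical choices that
affect results, and the limitations of each component.

## 1. Shared-response model

Multi-subject time courses are generated as

&nbsp;&nbsp;X_s(t) = α_s · C(t) + β_s · I_s(t) + ε_s(t)

where C is a common component shared by all subjects, I_s is a subject-unique
structured component, and ε_s is white Gaussian noise with standard deviation
σ.  C and I_s are low-pass-filtered Gaussian noise standardized to unit
variance, so the expected Pearson correlation between two subjects has the
closed form

&nbsp;&nbsp;r = α_i α_j / √((α_i² + β_i² + σ²)(α_j² + β_j² + σ²)),

which reduces to α²/(α² + σ²) for homogeneous weights with β = 0.  This
closed form is the oracle used by the generator's validation tests.

**Behavior-coupled cohorts.**  Given per-subject scores s_i, the generator
modulates synchrony in one of two ways:

- *Anna Karenina (AnnaK)*: each subject's shared weight becomes
  α_i = α + κ·(rank(s_i) − ½)/n, so high scorers load more on the common
  component and are therefore more alike, while low scorers are dominated by
  their idiosyncratic components.
- *Nearest-neighbor (NN)*: subjects receive signals mixed across a Gaussian
  process over the score axis with covariance exp(−|s_i − s_j|/ℓ)
  (default length scale ℓ = 20 rating units), so subjects with nearby scores
  share signal regardless of where they sit on the scale.

Setting the coupling strength κ to zero reproduces the base cohort exactly,
draw for draw; this exact-reduction property is tested.  The NN structure
uses a dedicated random substream so that changing the coupling does not
perturb the base draws.

## 2. Optical forward model and preprocessing

**Forward simulation.**  Chromophore concentration changes (ΔHbO, ΔHbR) are
mapped to two-wavelength intensities by the modified Beer–Lambert law
(MBLL): ΔOD(λ) = (ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR) · d · DPF(λ), with
I = I₀·10^(−ΔOD).  Defaults: wavelengths 760/850 nm, source–detector
distance 3 cm, differential pathlength factor 6 at both wavelengths, and a
standard extinction-coefficient table.  Saturation segments clamp the
intensity at the ADC ceiling; white-noise channels replace the signal with
unstructured noise.

**Inversion.**  `mbll` recovers concentrations by solving the 2×2 extinction
system per time point.  The forward/inverse round trip reproduces
concentrations to < 1 nM (tested at 1e-9), limited only by floating-point
error.  Non-positive intensities are flagged as missing (NaN) rather than
propagated through the logarithm.

**Channel quality control.**

- *Spectral rule*: the quartile coefficient of dispersion,
  QCoD = (Q3 − Q1)/(Q3 + Q1), of the Welch power spectral density.  A flat
  (white-noise) spectrum gives a small QCoD; a physiologically structured
  spectrum concentrates power at low frequencies and gives a large QCoD.
  Channels with QCoD < 0.1 at either wavelength are flagged.  The estimator
  uses a boxcar window with nperseg = max(16, min(32, T//8)): heavy segment
  averaging is essential, because with few segments the χ² sampling
  variability of the periodogram inflates the QCoD of white noise above the
  0.1 threshold.  With this estimator the white/structured separation is
  roughly 0.08 vs. 0.6 on the generator's channels.
- *Saturation rule*: a channel is unusable if any contiguous run at the ADC
  ceiling lasts strictly longer than 2 s.  A run of exactly 2 s passes; one
  extra sample fails (tested at the boundary).

**Chain.**  `preprocess_raw` applies, in fixed order: condition trimming →
QC → band-pass → PCA motion correction → MBLL → z-scored total hemoglobin
(HbO − HbR).  The band-pass is a 3rd-order Butterworth (0.005–0.5 Hz)
applied forward-backward (`sosfiltfilt`, zero phase, squared magnitude
response).  PCA motion correction removes leading principal components up to
a target variance fraction (capped at n−1 components).  The provenance list
on the output records the steps actually applied.

## 3. Intersubject correlation

- *Pairwise ISC*: the n×n Pearson correlation matrix of one channel's time
  courses; constant subjects are excluded with a warning.
- *Leave-one-out ISC*: each subject against the mean of all others.  Time
  courses are z-scored before averaging, making the statistic invariant to
  per-subject gain and offset.
- *Two-sample statistic*: mean within-group leave-one-out ISC minus the mean
  correlation of each subject with the other group's mean time course.
  Inference is by subject-wise permutation: group labels are randomly
  reassigned (preserving group sizes) and the statistic recomputed.  For
  z-scored rows every within/between correlation is a function of the Gram
  matrix G = ZZᵀ alone, so each permutation costs O(n²) independent of T;
  the observed statistic uses the identical code path.
- *One-sample test*: circular time-shift null — each subject's series is
  rotated by an independent random offset, destroying alignment while
  preserving autocorrelation.  Requires T ≥ 100 to give the offsets room.

All permutation p-values use the add-one rule
p = (1 + #{null ≥ observed}) / (n_perm + 1), which can never return zero.

## 4. Intersubject representational similarity analysis

Behavioral similarity structures:

- *NN distance*: squared Euclidean distance between scores (or score time
  courses).  On z-scored time courses the algebraic identity
  D = 2T(1 − r) links it to Pearson correlation (tested to 1e-8).
- *AnnaK similarity*: (rank_i + rank_j)/(2n) with average ranks for ties —
  invariant to any strictly increasing transform of the scores.  All-tied
  scores are rejected as degenerate.

The second-order fit is the Spearman (default) or Pearson correlation
between the upper triangles of the neural and behavioral matrices; distances
are negated so that positive correlations always mean "similar behavior,
similar brains".  Inference options:

- *subject-wise permutation*: rows and columns of the behavioral matrix are
  jointly permuted (the identity permutation is excluded), which preserves
  its value multiset, so rank matrices are precomputed once;
- *Mantel test*: the classical simple Mantel permutation test.

`compare_similarity_models` runs a paired t-test across channels on the
AnnaK − NN fit differences.  A zero-variance nonzero difference vector has
no finite t-statistic; it is reported as ±∞ with an explanatory note rather
than as a spuriously enormous number (detected with a relative 1e-12
threshold, since constant differences rarely survive floating-point
subtraction exactly).

## 5. Emotion-rating models

**Transforms.**  Negative emotions (anger, disgust, sadness):
t = ln(101 − raw), so the ceiling response raw = 100 lands exactly at t = 0.
Joy: t = ln(raw + 1), so the floor response raw = 0 lands at t = 0.  Fear
passes through untransformed.  The transforms are bijective on [0, 100]
(round-trip tested to 1e-12) and isolate *extreme* responses (t = 0) from
graded ones (t > 0).

**Two-part zero-inflated Gaussian mixed model.**  Fixed effects
time + group + time × group, subject random intercepts throughout:

1. a logistic mixed submodel for the indicator of a *non-extreme* response,
   fitted by maximum likelihood with 30-node Gauss–Hermite quadrature over
   the random intercept (BFGS with a Nelder–Mead fallback; Wald standard
   errors from the numerical Hessian).  An odds ratio below 1 therefore
   means more extreme responding.  The latent-scale residual variance is
   fixed at π²/3.
2. a Gaussian linear mixed submodel for t on the non-extreme rows, fitted by
   ML (`statsmodels` MixedLM).

If no (or all) responses are extreme, the logistic part is skipped with a
note and the model reduces to the plain LMM on the same rows (tested).

**Fear** uses a single REML Gaussian mixed model on the raw 0–100 scale.

**Summaries.**  ICC_gaussian = τ₀₀/(τ₀₀ + σ²); ICC_logistic =
τ₀₀/(τ₀₀ + π²/3); marginal R² = var_fixed/(var_fixed + τ₀₀ + σ²) and
conditional R² = (var_fixed + τ₀₀)/(var_fixed + τ₀₀ + σ²), with var_fixed
the sample variance (n−1 denominator) of the fixed-effect linear predictor.
These satisfy conditional = marginal + (1 − marginal)·ICC identically.
Group-difference outcomes use the Mann–Whitney U test (exact enumeration for
small tie-free samples, normal approximation otherwise).

**Ratings generator.**  Defaults mimic a 72-subject, 8-videos × 2-sessions
design: logistic fixed effects (2.2, −0.54, −0.41, −2.2) with random-intercept
SD 2.0, Gaussian fixed effects (2.78, 0.22, −0.05, 0.21) on the log scale
with random-intercept SD 0.57 and residual SD 0.62.  Extremes are emitted
exactly at the boundary (100 for negative emotions, 0 for joy); graded
values are drawn on the log scale, clipped to the transform's range, and
mapped back.  Over 50 replicates at these defaults, the 95% Wald intervals
of every fixed effect in both submodels achieve coverage in [0.85, 1.0]
(validation suite, criterion 4).

## 6. Validation suite

`tests/test_acceptance.py` states the package's own quantitative claims:

1. worked-example ICC/R² arithmetic (e.g. τ₀₀ = 0.28, σ² = 0.35 →
   ICC 0.444; τ₀₀ = 4.27 → latent ICC 0.565);
2. the two-sample permutation test rejects a true null at α = 0.05 with
   rate in [0.03, 0.07] (500 Monte-Carlo repetitions, n = 8+8, T = 500,
   1000 permutations);
3. IS-RSA model-structure recovery ≥ 95% in both directions (100 seeds each,
   n = 30, five channels);
4. two-part model coverage and exact OR = exp(coefficient);
5. MBLL round trip < 1e-9 and exact QC boundary behavior;
6. the distance/correlation identity to 1e-8.

## 7. Limitations

- The shared-response generator uses stationary Gaussian components; it does
  not model hemodynamic nonlinearity, serial-dependence differences between
  subjects, or non-Gaussian artifacts other than the explicit saturation and
  white-noise channels.
- The QCoD threshold of 0.1 is calibrated to the boxcar/nperseg≤32 Welch
  estimator described above; with other spectral estimators the same
  threshold will classify differently.
- The logistic mixed submodel supports a single random intercept only, and
  its standard errors are Wald approximations; small-sample or
  boundary-variance situations (τ₀₀ → 0) deserve profile or bootstrap
  intervals the package does not provide.
- Subject-wise permutation of the two-sample ISC statistic assumes
  exchangeability of subjects under the null; it does not protect against
  group differences in noise variance.
- The Mantel and subject-wise IS-RSA tests treat the behavioral matrix as
  fixed; uncertainty in the scores themselves is not propagated.
- With a single observation per subject, τ₀₀ and σ² are not separately
  identifiable in the fear model; the fit carries an explicit note and the
  variance split should not be interpreted.
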