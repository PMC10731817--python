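# Methods

## Protocol and preprocessing

The pipeline targets supine force-plate recordings of infants in the
fidgety-movements age window (roughly 9–20 weeks post-term): 3 minutes,
sampled at 50 Hz — a decade above the < 3 Hz band that contains infant
spontaneous-movement energy. The first 10 s are treated as acclimation to
the plate and discarded; the last 170 s (8500 samples) form the analysis
window.

Noise is removed with a fourth-order low-pass Butterworth filter at 10 Hz.
The filter is applied **zero-phase** (forward–backward, `sosfiltfilt` with
even-reflection padding) by default: the dual pass squares the magnitude
response and cancels phase, so velocity estimates carry no lag. A causal
single-pass variant is available through `PreprocessConfig(zero_phase=False)`
for strict causality. Filtering precedes trimming so that any startup
transient falls inside the discarded lead; this order is fixed and covered
by a regression test rather than asserted as an equivalence.

Raw force/moment exports are converted by the standard plate mechanics
COPx = −(My + Fx·z₀)/Fz, COPy = (Mx − Fy·z₀)/Fz with a configurable
plate-surface offset z₀ (default 0 m — measurement at the plate surface,
foam padding ignored, since plate geometry is rarely exported). Samples with
|Fz| below 1 N (a loose liveness check against an infant's ~50–70 N weight)
are flagged invalid and held at the last valid COP value: holding preserves
series length for the window arithmetic and does not invent motion the way
interpolation would.

## The movement-parameter battery

All parameters are computed in three directions: X (medial–lateral), Y
(caudo-cephalic) and R (resultant). Two distinct resultant conventions are
used deliberately:

* for **displacement**, R is the distance from the window-mean COP,
  r_i = √(x_c,i² + y_c,i²);
* for **velocity**, R is the magnitude of the planar velocity vector,
  √(vx² + vy²) — the dominant stabilometric convention for "resultant
  velocity", not the derivative of r. The alternative reading is available
  by computing statistics of `np.diff(r_disp)` directly.

Velocities use forward differences scaled by the sampling rate. This makes
mean resultant speed × window duration telescope exactly to the planar path
length, which the tests exploit as a cross-check.

Conventions, in the package's own terms:

* standard deviations use the N−1 denominator everywhere (velocity SD, the
  ApEn tolerance, the ellipse covariance);
* skewness is the adjusted Fisher–Pearson sample skewness; a zero-variance
  series has skewness 0 by convention so degenerate fixtures cannot crash
  the battery;
* the 95% ellipse is a **prediction ellipse** for the scatter of COP
  samples (area = π·χ²₂(0.95)·√det Σ, χ²₂(0.95) ≈ 5.991), not a confidence
  ellipse for the mean; axes are 2·√(χ²₂·λ) for each covariance eigenvalue
  λ and the orientation is the leading eigenvector's angle folded into
  (−π/2, π/2]. A rank-deficient covariance yields area 0 plus a degeneracy
  flag instead of an exception;
* approximate entropy is the Pincus estimator ApEn(m, r, N): Chebyshev
  distance, self-matches included, r = 0.2 × sample SD and m = 2 by default
  — the de facto physiological-series standard. The implementation is
  vectorized with chunked distance blocks (bounded memory at N = 8500) and
  is tested to 1e−12 against a naive O(N²) double-loop reference. Two edge
  properties worth knowing: a zero-variance series is defined to have
  ApEn 0, and although self-matches keep the statistic essentially
  nonnegative, an exactly periodic short series can land a few parts in
  10⁵ *below* zero because Φ^m and Φ^(m+1) average over different template
  counts — the package reports the faithful value rather than clamping.

**Anthropometric normalization** divides each length-dimensioned parameter
by current height (cm) and/or current weight (kg); parameters carrying
length² (the ellipse area) are divided by the square of the divisor.
Dimensionless parameters — skewness, approximate entropy, the ellipse
orientation — are never rescaled. The default scheme is `height_weight`
because group differences in both quantities motivate the correction; every
report records the scheme used, since the scale on which downstream model
coefficients were estimated is not recoverable and users may need to
recalibrate against their own plate and cohort.

## Prediction equations

The fidgety-movements classifier is a fixed logistic equation in the
normalized resultant velocity variability (IVstdR) and resultant
approximate entropy (ApEnR):

    P(absent FMs) = 1 / (1 + exp(−(−3.354 − 0.010·IVstdR + 0.895·ApEnR)))

with classification threshold 0.15. A probability exactly at the threshold
classifies as `absent_FM`: in a screening context the tie goes to
sensitivity. The implied odds ratios are exp(−0.010) ≈ 0.990 (each unit of
velocity variability protects) and exp(0.895) ≈ 2.447 (each unit of
entropy raises risk); interval bounds follow as exp(B ± 1.96·SE).

The MOS-R estimator is log-linear:

    log(MOS-R) = 1.294 + 0.172·log(IVstdR) − 0.219·log(IVskewR) − 0.265·log(ApEnR)

The logarithm base is taken as 10: under base 10 an all-ones predictor
vector maps to 10^1.294 ≈ 19.7, inside the legal MOS-R range [5, 28],
whereas the natural-log reading (e^1.294 ≈ 3.6) cannot reach the scale at
all; `MosrLinearModel(log_base=math.e)` preserves the alternative.
Back-transformed estimates are clamped to [5, 28] with a flag. Because the
predictors enter through logarithms, a non-positive predictor — typically a
negative velocity skewness — is a hard domain error naming the offending
predictor; an explicit `positive_shift` must be opted into, since any
silent shift changes the estimate unaccountably. In the full pipeline this
domain error degrades gracefully: the report carries the classification and
a flag, with the MOS-R estimate absent.

Both equations ship as versioned, human-readable JSON model files and can
be replaced by refitted files with the same schema.

## Screening, refitting, diagnostics

Predictor screening keeps parameters whose |correlation| with the outcome
exceeds 0.25 at p < 0.05 — point-biserial (Pearson against the 0/1
indicator) for a dichotomous outcome, rank correlation otherwise — then
scans survivors in descending relevance and drops any candidate correlated
above 0.70 in absolute value with an already-kept one, so each collinear
cluster contributes one predictor. Rank correlation is the default between
features because normality-based switching cannot be automated defensibly;
Pearson is available by argument.

Refitting uses maximum likelihood (statsmodels Logit, Newton iterations,
tolerance 1e−8, at most 100 iterations). Reported diagnostics are the
likelihood-ratio statistic −2(LL_null − LL_model) and the Nagelkerke
pseudo-R², i.e. the Cox–Snell R² rescaled by its maximum attainable value.
Perfect separation raises a dedicated error (whether statsmodels signals it
explicitly or the Hessian collapses after coefficient divergence).

The Hosmer–Lemeshow test groups observations into deciles of predicted
risk (stable sort, so ties keep input order) and sums (O − E)²/(E(1 − E/n_g))
with df = groups − 2; a group whose expected count is degenerate is merged
with its neighbour and the merge count is reported.

## Diagnostic accuracy

Sensitivity, specificity, accuracy, PPV and NPV are simple ratios of the
2×2 counts with `absent_FM` as the positive class; each carries an exact
Clopper–Pearson interval in its Beta quantile form (lower = 0 at s = 0,
upper = 1 at s = n). The exact method is used because it reproduces the
reference sensitivity and specificity intervals for the reconstructed
cohort counts and is conservative (coverage at least nominal) at the small
positive-group sizes typical of screening studies. One caveat is
documented: predictive-value intervals published alongside such studies do
not always match an exact interval on the raw counts (predictive values
depend on prevalence, and some software reports adjusted intervals);
`copsway` reports the same exact method for all five metrics. Display
rounding is half-up to integer percent; full precision is kept internally.
A metric with an empty denominator is reported as undefined with an
explanatory flag rather than raising.

## The simulator

No public recordings exist for this protocol, so the simulator generates
surrogate stabilograms with the protocol's gross properties: 180 s at
50 Hz, millimetric sway, ≥ 95% of spectral power below 3 Hz. Per axis,

    cop(t) = A · envelope(t) · bandlimited(t) + c · broadband(t)

where `bandlimited` is seeded Gaussian noise band-passed to 0.1–3 Hz and
rescaled to unit variance, `envelope` is a slow (0.05–0.2 Hz) random
amplitude modulation with mean ≈ 1 whose depth is 0.6 × the
velocity-variability gain (clipped to stay positive), `broadband` is white
noise with SD 2 mm, A = 15 mm, and c is the complexity gain. The two
regimes differ only in the gains: normal FMs use velocity-variability gain
1.0 and complexity gain 0.2; absent FMs use 0.35 and 0.6. The broadband SD
of 2 mm is the one free constant: it is small against the 15 mm sway scale,
so it perturbs sample-scale regularity (what ApEn sees) without dominating
gross sway velocity. Subject anthropometrics are drawn from plausible
infant ranges (height 55–68 cm, weight 4.5–8.0 kg). Cohorts derive
per-recording child seeds from a master seed, so everything is bit-for-bit
reproducible.

This generator is an engineering stand-in, not a biomechanical model. It
emulates the band limitation, amplitude scale, amplitude-modulation
contrast and regularity contrast of the two clinical groups; it does not
emulate real infants' spectral fine structure, posture shifts, behavioural
state changes, or the joint distribution of parameters across infants.
Passing tests therefore demonstrate that the pipeline is correct and that
the published equations respond to the intended contrasts — not that the
published classification accuracy would be attained on real infants.

## Problem sizes and numerical choices in the test battery

* Oracle equivalence for ApEn runs on series of N ≤ 300 against the O(N²)
  double-loop reference at 1e−12 absolute tolerance.
* Regime sign-recovery cohorts use 60 s recordings (5 s lead + 50 s
  window); the regime contrast lives in stationary gains, so window length
  affects only estimator variance, and 200 + 200 recordings give
  comfortable margins (the velocity and complexity coefficients recover
  their signs at several standard errors).
* Recovery from the published equation itself uses 2000 simulated infants
  with predictor spreads wide enough to identify all three coefficients;
  the acceptance check is agreement within 3 standard errors.
* The isotropic-Gaussian ellipse check uses 10 000 points against the
  closed form π·χ²₂(0.95)·√det Σ at 5% relative tolerance.
* Filter verification measures sine attenuation by quadrature demodulation
  over an integer number of periods and compares against the squared
  magnitude of the designed digital response (`sosfreqz`), the correct
  analytic reference for a bilinear-transform design — the analog-prototype
  formula 1/√(1+(f/fc)^8) is accurate in the passband but overestimates the
  response near Nyquist, where frequency prewarping dominates.

## Known limitations

* The absolute scale of the prediction-equation inputs depends on the
  normalization scheme and plate calibration; out-of-the-box probabilities
  on a new plate should be treated as relative until recalibrated.
* The abnormal-FMs pattern (a third clinical class) is outside the model's
  scope; the classifier is binary.
* MOS-R sub-category scores are not modelled, only the total.
* No frequency-domain sway parameters, sample/multiscale entropy, or
  sway-density analysis; the battery is fixed to the documented parameter
  list.
* Vendor binary formats (Kistler proprietary files, C3D) are not read;
  export to delimited text first.
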