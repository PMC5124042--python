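# Methods

This note records the models implemented in `t2contrast`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
phantoms can and cannot tell you about real data.

## Signal model and phantom generator

A voxel of tissue with proton density PD and transverse relaxation time
T2 produces, at echo time TE of a multi-echo spin-echo train,

    S(TE) = PD · exp(−TE / T2).

No T1 saturation term is included: the emulated acquisition uses
TR = 4500 ms, long enough relative to tissue T1 that longitudinal recovery
is treated as complete, and the analysis concerns only the echo-train decay.
The first echo is additionally multiplied by `first_echo_gain`
(default 1.10) to emulate stimulated-echo contamination from imperfect
refocusing pulses.  The contamination magnitude in real acquisitions is not
well characterised; the default is a stand-in whose only purpose is to make
the first echo inconsistent with the mono-exponential so that the
exclusion logic is genuinely exercised — any value ≠ 1 would do.

Age enters through a linear per-tissue drift
T2(age) = t2_ms + t2_age_slope · (age − reference_age), with the reference
age defaulting to 67.3 years so that injected slopes pivot around the
centre of the emulated cohort (37 subjects, ages 49–87, drawn uniformly;
only the range and mean of the emulated study population are known, so a
uniform draw is the least-structured choice).

**Noise** is Rician: the magnitude of (signal + complex Gaussian noise)
with σ per channel, the standard model for magnitude MRI.  Background
(unlabelled) voxels therefore carry Rayleigh noise with mean σ√(π/2), which
the test suite checks directly.  **Bias fields** are seeded Gaussian white
noise smoothed to a chosen correlation length, normalised so that the
`amplitude` parameter is the *peak* deviation from 1 and the spatial mean
is exactly 1.  Peak normalisation (rather than scaling to a standard
deviation) was chosen so the field's bounds are guaranteed for every seed,
not just typically; real coil-sensitivity shading is similarly bounded.

**Geometries** are deliberately schematic: layered slabs inside a one-voxel
background border — a two-compartment split, a three-strip arrangement
emulating the CA1 | SL/SR/SM | DG ordering of hippocampal subfields (gray,
white-like, gray), and a gray-over-white pair emulating cingulate cortex
and its adjacent white matter.  Each layout guarantees face-connected
adjacency between declared compartment pairs, which the boundary
perturbation relies on.  The phantoms make no attempt at anatomical realism
(no curvature, no partial-volume mixing, no coil-array profiles); passing
recovery tests on them demonstrates the *estimators* are correct under the
stated noise model, not that the pipeline is robust to anatomy-specific
artefacts.

Every generator is driven by `numpy.random.default_rng` seeds; cohort
manifests record the per-subject child seeds (kept below 2³¹) so any volume
can be regenerated bit-identically.

## Relaxometry

T2 maps are fitted voxel-wise by unweighted OLS of ln S on TE over the
retained echoes; T2 = −1/slope, S0 = exp(intercept).  Decisions:

- **Echo selection.**  Default policy drops exactly the first echo (window
  24–120 ms for 10 echoes at 12 ms); `keep_all` is available.  At least two
  echoes must remain.
- **Unweighted log-space OLS.**  No variance weighting of late echoes is
  applied.  Weighting would down-weight the noisiest (latest) echoes, but
  the unweighted fit is the plain reading of "fit in logarithmic space",
  is exact on noiseless data, and agrees with nonlinear least squares to
  2 % down to last-echo SNR 10 (verified against `scipy.optimize.curve_fit`
  in the suite).
- **Validity.**  Voxels with any retained intensity ≤ `intensity_threshold`
  (default 0 — the logarithm needs positive input) or fitted T2 outside
  `t2_bounds` (default (1, 2000] ms) are marked invalid and carry NaN —
  never 0, which would silently corrupt ROI means downstream.
- **Diagnostics.**  The log-space coefficient of determination is stored
  per voxel as a cheap goodness-of-fit map; it is not used for exclusion.
- **No multi-component or extended-phase-graph modelling.**  The
  mono-exponential constant is an *effective* T2 mixing true relaxation
  with dynamic dephasing; modelling those components separately is out of
  scope.

The T2-weighted image is the sum over the *entire* train including the
first echo (the stimulated-echo contribution is part of the weighted
image's contrast, only the quantitative fit excludes it).

## Contrast statistics

CNR and GWR are computed from ROI sample moments with the n−1 (unbiased)
variance by default; whether the underlying convention was n or n−1 is not
determinable from the formulas alone, so `ddof` is exposed.  Further
conventions:

- GWR orientation (which ROI is the numerator) is fixed by the ordered
  region-pair declaration, never inferred from intensities, so the ratio
  keeps one meaning across modalities where relative brightness flips.
- T2-map contrasts use only valid voxels; weighted-image contrasts use all
  in-mask voxels (validity is a concept of the fit, not of the image).
- Contrasts are computed per subject over the whole ROI; masks sharing a
  label are pooled rather than analysed per hemisphere.
- Degenerate inputs raise: zero pooled variance (CNR) and zero
  white-matter mean (GWR) are explicit errors, not infinities.  In cohort
  tables an undefined metric skips that row with a logged warning rather
  than aborting the run — noiseless phantoms legitimately produce
  zero-variance T2 samples whose GWR is still meaningful.

## Reliability

**Dice** is the plain set-count statistic.  **ICC** is computed from the
ANOVA mean squares of a targets × raters matrix; all six McGraw–Wong-style
variants (one-way / two-way-consistency / two-way-agreement × single /
average) are implemented with their F statistics, F-quantile 95 % CIs
(Satterthwaite df for the agreement model) and upper-tail p-values, and are
cross-checked in the suite against both a from-scratch sums-of-squares
oracle and `pingouin.intraclass_corr`.  The default is two-way consistency,
average measures: with two raters its F test has equal numerator and
denominator degrees of freedom — the pattern seen in intra-rater
re-segmentation designs — and it satisfies the exact identity
ICC = 1 − 1/F, which the implementation preserves bit-exactly by computing
the estimate through that identity.

**Boundary perturbation** toggles voxels of the 6-connected boundary shell
(face connectivity matches the phantom adjacency guarantee).  Calibration:
each boundary site has two flip candidates — its inner (erosion) and outer
(dilation) voxel — and a flipped candidate displaces the local boundary by
one voxel, so flipping every shell voxel independently with probability p
gives an expected displacement of 2p per site; magnitude m maps to
p = m/2, applied in ceil(m) rounds of p = m/(2·ceil(m)) when m > 1 so the
operator stays stochastic.  Magnitude 0 is the exact identity.  This
operator is a documented stand-in for "computational boundary
perturbation" in general: it honours the intent (random, boundary-local,
magnitude-calibrated, topology-preserving away from the shell) without
claiming to reproduce any particular published operator.

`perturbation_analysis` re-computes a registered contrast metric (CNR or
GWR) under n independent perturbations of both masks per magnitude and
reports the metric's mean and SD plus the mean Dice to the original masks.
On the noiseless two-compartment phantom the GWR shifts toward 1 under
perturbation (cross-boundary voxels contaminate both samples); at
magnitude 1 the shift is ≈ 4 %, i.e. the metric is stable at the scale of
realistic labelling discrepancies.

## Age trends

Point estimates are OLS via `statsmodels`; the p-value for the zero-slope
null is the parametric two-sided t test with n − 2 df (bootstrap intervals
accompany, rather than replace, the standard regression p).  Uncertainty:

- **Case resampling** of (age, value) pairs, default 500 replicates —
  robust to heteroscedasticity across age, which residual resampling would
  assume away.  Resamples with degenerate (all-equal) ages are redrawn and
  logged.
- **Bias-corrected (BC) percentile intervals** for slope and intercept:
  the median-bias correction z₀ is estimated from the fraction of
  bootstrap estimates below the full-sample estimate (ties counted half);
  acceleration is 0 by default, with BCa (jackknife acceleration) as an
  option.  Degenerate bootstrap distributions (zero spread, e.g. on
  zero-residual data) collapse to a width-0 interval.
- **Functional prediction interval**: the pointwise BC interval of the
  fitted line over an age grid (default 100 points spanning the observed
  range) — uncertainty of the mean trend.
- **Observation bounds**: the functional interval widened by the 2.5/97.5 %
  quantiles of the full-sample residuals (clamped to keep the prediction
  band inside), approximating where individual subjects fall.  Classical
  normal-theory prediction intervals would be the parametric alternative;
  the bootstrap-plus-residual-spread construction is used so both bands
  derive from the same resampling machinery, and the two bands are always
  labelled distinctly.
- Measured behaviour (recomputed by `scripts/acceptance.py`): type-I error
  of the p < 0.05 rule ≈ 0.05 on pure noise; the 95 % BC slope interval
  covers a true slope in ≈ 93 % of replicates at n = 37 (slight
  under-coverage is characteristic of percentile-family intervals at this
  n).
- No multiple-testing correction is applied across regions or metrics by
  default, matching single-comparison reporting conventions; callers can
  correct externally.

## End-to-end study and problem sizes

`t2contrast.pipeline.t2_age_study` chains the whole package: a 37-subject
uniform-age cohort on a 16³ two-compartment phantom (GM 90 ms flat,
WM 70 ms + 0.3 ms/yr, PD 1000, Rician σ = 14 ≈ SNR 50 at the first
retained echo), per-subject T2 fits, ROI-median extraction, and per-tissue
age regression.  With these settings the injected WM drift is detected
(p < 0.05, positive slope) and the flat GM compartment is not flagged in
essentially every seeded run; the acceptance script reports both rates over
25 runs.  The 16³ grid keeps a full 25-study battery in tens of seconds
while leaving ≈ 1400 voxels per compartment — enough that ROI medians are
noise-free to well under 1 %.

## Known limitations

- Phantom anatomy is schematic; no partial-volume effects, curvature,
  motion, or slice-profile imperfections are simulated, so robustness to
  those is untested by construction.
- The stimulated-echo model (a single multiplicative gain on echo 1) does
  not emulate the echo-to-echo oscillations a full extended-phase-graph
  treatment would produce.
- Bias fields are generated but not estimated or corrected; the analysis
  assumes shading-corrected inputs as its validity condition, consistent
  with computing CNR from anatomically close ROI pairs.
- ICC confidence intervals use the standard F-quantile constructions,
  which assume balanced, complete rating matrices.
- Observation bounds are an empirical-quantile approximation and inherit
  the residual quantiles' small-sample noise at n < ~20.
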