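# t2contrast

Quantitative T2 relaxometry and gray/white contrast analysis for
cross-sectional brain-ageing studies.

Normal ageing changes not only the size of brain structures but the MR
signal of the tissue itself: the spin-echo T2 of myelinated white matter
drifts upward with age while cortical and hippocampal gray-matter T2 stays
nearly constant, so the contrast between adjacent gray and white
compartments — the very contrast segmentation protocols rely on — erodes in
older subjects.  `t2contrast` implements the full analysis chain needed to
quantify this from multi-echo spin-echo data, and a seeded digital-phantom
generator to validate every stage against known ground truth:

1. **Relaxometry.**  A voxel-wise mono-exponential fit in logarithmic space:
   for retained echo times *TE* and signal *S*, OLS of ln *S* on *TE* gives
   T2 = −1/slope and S0 = exp(intercept).  The first echo of the train is
   excluded by default because stimulated echoes from imperfect refocusing
   pulses inflate it; with the emulated acquisition (10 echoes, 12 ms
   spacing) the fitting window is 24–120 ms.  The entire train (first echo
   included) is summed to form the T2-weighted image, and R2 = 1/T2 maps are
   derived for registration-style use.
2. **Contrast statistics.**  For a gray-matter sample *S*<sub>G</sub> and
   white-matter sample *S*<sub>W</sub> drawn from anatomically adjacent ROIs,

   CNR = |E(*S*<sub>G</sub>) − E(*S*<sub>W</sub>)| / √(σ²(*S*<sub>G</sub>) + σ²(*S*<sub>W</sub>)),  GWR = E(*S*<sub>G</sub>) / E(*S*<sub>W</sub>),

   computed per subject on T2-weighted intensities or quantitative T2 values.
3. **Reliability.**  Dice kappa 2|A∩B|/(|A|+|B|) between repeated
   segmentations; intraclass correlation from one- or two-way ANOVA mean
   squares with F statistics, 95 % CIs and p-values; and a Monte-Carlo
   boundary-perturbation analysis that toggles the 6-connected boundary
   shell of each mask to measure how stable CNR/GWR are against plausible
   labelling discrepancies.
4. **Age trends.**  Each metric is regressed on age (OLS, two-sided t test
   with n − 2 df); a case-resampling bootstrap (500 replicates,
   bias-corrected percentile) yields slope/intercept CIs, pointwise
   functional prediction intervals over an age grid, and 95 % observation
   bounds.  Fit lines render solid when p < 0.05 and dashed otherwise.
5. **Phantoms.**  Seeded synthetic cohorts on layered geometries
   (two-compartment, hippocampal-subfield-like strips, cingulate-like
   pairs) with per-tissue proton density, base T2, an injectable T2-vs-age
   slope, Rician magnitude noise, smooth multiplicative bias fields, and
   first-echo stimulated-echo contamination — plus ground-truth manifests
   that regenerate every volume bit-identically from seeds alone.

## Worked example

A complete in-silico study — simulate a 37-subject cohort aged 49–87 on a
two-compartment phantom (GM-like T2 90 ms, flat with age; WM-like T2 70 ms
drifting +0.3 ms/yr; Rician noise at SNR ≈ 50 for the first retained echo),
fit T2 maps with the first echo excluded, extract ROI-median T2 per tissue,
and regress on age:

```python
from t2contrast.pipeline import t2_age_study

trends = t2_age_study(seed=1)
for name, fit in trends.items():
    fit.metric = f"{name} median T2 (ms)"
    print(fit.summary())
```

```
Age trend: GM median T2 (ms)
  n               37
  slope           -0.00048352 per year (SE 0.00188)
  intercept       90.081
  p (slope=0)     0.7989  [dashed: p >= 0.05]
Age trend: WM median T2 (ms)
  n               37
  slope           +0.29951 per year (SE 0.00144)
  intercept       49.911
  p (slope=0)     9.716e-56  [solid: p < 0.05]
```

The fitted WM slope (+0.2995 ms/yr) recovers the injected +0.3 ms/yr drift;
the flat GM compartment is correctly not flagged (p ≈ 0.8).  The intercepts
are the extrapolated T2 at age 0 (the WM line passes through 70 ms at the
cohort reference age of 67.3 years).

The same chain is scriptable from the shell:

```sh
t2contrast run --config examples/demo.yaml --seed 1 --out demo_out
```

which writes per-subject echo trains, T2/R2/T2-weighted NIfTI maps, the
per-subject CNR/GWR cohort table, a perturbation-stability report, the
age-trend report with bootstrap CIs, and a manifest of seeds and output
checksums sufficient to replay the run bit-identically.

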