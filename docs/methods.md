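# Methods

This document states the models, parameter choices, generator scope,
numerical decisions, and known limitations of the package. Every numeric
claim below is either a definition or is computed by the test suite /
`scripts/acceptance.py`.

## Signal models

**Spoiled gradient echo.** The steady-state magnitude signal is

```
S = PD · sinα · (1 − E1) / (1 − cosα · E1) · exp(−TE / T2*),   E1 = exp(−TR / T1)
```

with proton density PD, flip angle α, repetition time TR, and echo time TE.
This is the standard incoherent-spoiling approximation; no slice-profile,
B1, or chemical-shift effects are modeled.

**Inversion recovery (MOLLI).** The apparent recovery is
`S(TI) = A − B·exp(−TI/T1*)`. The simulator sets A to the tissue proton
density and `T1* = T1/(B/A − 1)` so that the standard Look-Locker
correction `T1 = T1*·(B/A − 1)` recovers the tissue T1 exactly; the default
`B/A = 1.9` reflects imperfect inversion plus readout-driven apparent
shortening. Scanner output is magnitude-only, so the simulator returns
`|S|`.

**Noise.** All images carry Rician noise: `|S + n₁ + i·n₂|` with
`n₁, n₂ ~ N(0, σ²)`. At zero signal this reduces to a Rayleigh magnitude
with mean `σ·√(π/2)` (verified by test).

## Iron → tissue-parameter link

A subject's liver at LIC `L` (mg Fe/g dry weight) has

- `R2* = max(inverse of the linear calibration at L, 2.5 Hz)`, i.e.
  `T2* = 1000/R2*` — the floor keeps T2* finite (≤ 400 ms) at near-zero
  iron;
- `R1 = 1000/576 + 0.1·L` Hz, a linear rate increase over the baseline
  liver T1 of 576 ms.

The default R2*↔LIC calibration profile is the published linear biopsy
calibration `LIC[mg/g] = 0.0254·R2*[Hz] + 0.202` (profile name
`"hankins"`); any positive-slope linear profile can be substituted. Unit
conversion between mg/g and µmol/g uses the molar mass of iron,
55.845 g/mol.

## Acquisition protocols (package defaults)

- **mGRE (T2*)**: 12 echoes evenly spaced TE 1.3–16.9 ms (step ≈ 1.418 ms),
  TR 200 ms, flip 20°.
- **SIR set**: TR 120 ms throughout; sequence 1 TE 4 ms / flip 90°
  (T1-weighted), sequences 2–5 flip 20° with TE 4, 9, 14, 21 ms.
- **MOLLI**: 5(3)3 scheme at 60 bpm, base TIs 100 and 180 ms, giving the
  8-point ladder 100, 180, 1100, 1180, 2100, 2180, 3100, 4100 ms.

## Phantom and cohort generator

The scene is a 2-D abdominal slice: one large liver ellipse and two small
paraspinal-muscle ellipses on a square grid (default 64×64 in the study
runner; geometry scales with grid size). Muscle does not accumulate iron
and keeps fixed parameters (PD 112, T1 870 ms, T2* 30 ms), tuned so a
normal-iron liver yields SIR ratios near 1. The generator's scope is
method-comparison structure, not anatomical realism: homogeneous tissues,
no motion, no field inhomogeneity beyond the T2' already folded into T2*.

The default cohort is 53 patients (true LIC lognormal, median 6 mg/g,
σ_log 0.8, truncated to (0, 43)) and 21 controls (normal 1.0 ± 0.4 mg/g,
truncated to (0.2, 2)). Rater reads are the subject's image-derived
estimate perturbed by per-method multiplicative and additive noise; rater 1
reads twice (intraobserver), rater 2 once. The T1 channel carries a 5×
noise scale relative to the T2* channels — this encodes the empirically
higher dispersion of R1 readings and is what produces the study's expected
ordering (T1 strictly lower AUC and ICC than every T2*-based method), which
the acceptance suite checks rather than assumes.

## Numerical choices

- **T2* fitting**: closed-form log-linear OLS for pixelwise maps (fast,
  vectorized); nonlinear least squares (initialized from the log-linear
  fit) for ROI series. Fits with T2* ≤ 0 or > 500 ms are invalid (the cap
  excludes water/background).
- **Truncation**: dropped echoes are always a suffix; at least 3 echoes are
  kept. `best_fit` drops the last echo while R² (signal scale) strictly
  improves; `threshold` drops the trailing run below `factor ×
  noise_floor`. The pixelwise map evaluates all suffix truncations
  vectorized and reproduces the scalar rule exactly (verified by test).
- **MOLLI polarity**: exhaustive search over flipping the first k points,
  k = 0..n/2; lowest residual sum of squares wins. Fits with B/A ≤ 1 or
  T1* ≤ 0 are flagged non-physical.
- **SIR calibration**: self-generated by evaluating the noiseless signal
  model over a LIC grid (5–450 µmol/g, 90 points); monotonicity is enforced
  by a decreasing isotonic fit and any adjustment beyond 1e-6 relative
  raises. Validity bounds on the ratio are [0.1, 1.1]; estimates outside
  every sequence's range carry `saturated`/`below_range` flags.
- **ICC**: two-way random-effects, absolute-agreement, single-measures
  (`A-1`) by explicit mean squares, with the F-based confidence interval
  (Satterthwaite degrees of freedom); consistency (`C-1`) available. Cross
  -checked against pingouin and a hand-computed ANOVA in tests.
- **AUC**: trapezoid over the empirical ROC, which equals the tie-corrected
  Mann-Whitney statistic exactly (asserted at runtime); variance and paired
  contrasts by DeLong's midrank method, cross-checked against bootstrap.
- **Chi-square**: Yates continuity correction by default, the convention
  for 2×2 tables at these sample sizes.
- **Group tests**: Shapiro-Wilk at α = 0.05 on each group gates Student's t
  (equal variances) versus Mann-Whitney.
- **Seeding**: every stochastic routine takes an explicit seed;
  `run_study` spawns independent `SeedSequence` children for cohort,
  subjects, and raters, so a config+seed pair regenerates the report
  bit-identically (verified by test). Derived seeds are reduced mod 2³¹.

## SNR definition for recovery experiments

Parameter-recovery error is measured through the actual pipeline: simulate
a noisy image series, average the liver ROI per frame, fit. "SNR" is
*image* SNR on the reference frame — the noiseless liver signal at the
first echo (mGRE) or last inversion time (MOLLI) divided by the Rician σ.
ROI averaging then raises the effective SNR of the fitted series by roughly
the square root of the ROI pixel count, which is what makes sub-percent
median recovery errors attainable even at T2* = 1 ms; per-pixel fitting at
the same image SNR would be far noisier. Measured medians are written by
`scripts/acceptance.py` and bounded (≤ 2% for T2*, ≤ 3% for T1) by the
acceptance tests.

## Limitations

- The phantom is 2-D, homogeneous per tissue, and motion-free; it cannot
  probe segmentation error, fat-water interference, or susceptibility
  artifacts.
- The SIR calibration is simulation-derived, not the published patient
  -derived table; absolute SIR estimates therefore agree with the package's
  own signal model by construction, and the method's saturation point
  (~300–390 µmol/g depending on the sequence) emerges from the model rather
  than being fitted to clinical data.
- The iron→R1 link is a simple linear rate model; no validated R1→LIC
  conversion is implemented, matching clinical practice of reporting T1/R1
  descriptively.
- Rater noise is parametric (multiplicative + additive Gaussian), not a
  model of human ROI placement.
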