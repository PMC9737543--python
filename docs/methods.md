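# Methods

## Problem setting

A vibroarthrogram (VAG) is an acceleration time series recorded over a
moving joint. For the temporomandibular joint (TMJ), clicks during jaw
opening/closing mark disc displacement; the analysis chain here asks (a) how
repeatable spectral descriptors of such signals are across two recording
sessions with sensor replacement, and (b) how well those descriptors
separate symptomatic from asymptomatic joints.

## Signal simulator

`simulate_recording` models one joint recording as

```
x(t) = exp(u + v) * [ sigma_0 * env(t) * n(t) + clicks(t) ]
```

- `env(t)` is a raised-cosine envelope with exactly `n_cycles` maxima over
  the recording (floor 0.3, peak 1.0) — the jaw's cyclic motion modulates
  baseline vibration. The protocol default is 10 cycles per 20 s (0.5 Hz
  cycle rate); the cycle count, not any external pacing rate, governs the
  waveform.
- `n(t)` is unit Gaussian noise, `sigma_0` the baseline noise SD (default
  0.05 signal units).
- `clicks(t)` appears only in symptomatic recordings: per cycle,
  Poisson(`click_rate`, default 2) bursts at uniform times, each a damped
  sinusoid `A * exp(-t/tau) * sin(2*pi*f_c*t + phi)` with carrier
  `f_c = 150 Hz` (below the 300-Hz feature boundary, so clicks load IB3) and
  decay chosen so the burst falls to 1% of its peak at `click_duration`
  (default 20 ms). Burst amplitude is log-normal around
  `click_amplitude_mean` (default 1.0, i.e. 20× the noise SD — a clearly
  symptomatic cohort; lower it for harder classification problems).
- `u ~ N(0, subject_sd^2)` is drawn once per subject and persists across
  sessions; `v ~ N(0, session_sd^2)` is drawn per recording. Multiplicative
  (log-normal) effects keep amplitudes positive and translate into
  between-subject and between-session variance of the energy features,
  the structure the ICC estimates. Defaults 0.3 and 0.1 give high but not
  degenerate repeatability.

Every generator output is a pure function of its parameters and an explicit
seed; cohorts derive per-recording seeds from a `SeedSequence` so results do
not depend on generation order.

What the simulator does **not** emulate: sensor-placement error as a
physical process (only its variance through `session_sd`), broadband
crepitus morphology, muscle/swallowing artifacts, amplifier coloration, or
any calibrated physical unit. Tests passing on this generator demonstrate
the correctness of the statistical machinery, not clinical performance on
real recordings.

`simulate_feature_matrix` skips the signal layer entirely and draws
`X[i,j] = mu + r_i + c_j + e_ij` from the two-way crossed model, for which
ICC(A,1) has the closed form `sigma_r^2 / (sigma_r^2 + sigma_c^2 +
sigma_e^2)`. This gives exact ground truth for validating the estimator and
its interval at the study scale (n = 94, k = 2).

## Spectra

The one-sided amplitude spectrum of the mean-removed signal uses the scaling
`|DFT| * 2/N` for all non-DC bins (the Nyquist bin included, so a single
constant is documented rather than a per-bin exception); the DC bin is
excluded and the grid starts at one resolution step, `1/duration` Hz. The
constant cancels in IBAR, PF and MF and scales TI/IB3/IA3/PA linearly. No
window is applied before the FFT: tapering would change the integral
features, and the analysis chain being modeled applies none. Resampling to
the norm1/norm2 grids uses `numpy.interp` (piecewise-linear, exact on source
grid points); grid points below the source minimum take the first source
value (no extrapolation).

## Features

Integrals use the trapezoidal rule, treating the spectrum as a curve. The
trapezoid straddling 300 Hz is split at exactly 300 Hz, making
TI = IB3 + IA3 an identity rather than an approximation; mass at exactly
300 Hz counts as "below". IA3 integrates to the spectrum's band maximum
(2500/1000/500 Hz depending on normalization) — the "above" integral is
band-relative by construction. PF ties resolve to the lowest frequency
(deterministic, order-independent). MF inverts the cumulative trapezoidal
integral by linear interpolation; a zero spectrum leaves MF undefined
(NaN + flag), and a band ending at or below 300 Hz makes IBAR +infinity
(flagged), which the decision tree treats as exceeding any threshold.

## Reliability

`icc_a1` computes ICC(A,1) from the two-way ANOVA without replication
(mean squares MSR/MSC/MSE) and the McGraw–Wong absolute-agreement interval:
F-quantiles at level (1−alpha/2) with Satterthwaite denominator degrees of
freedom. When those degrees of freedom collapse toward zero (point estimate
near its negative boundary) the F-quantile diverges and the code substitutes
the analytic limits of the bounds. The estimator and interval are verified
in tests against hand-computed ANOVA oracles, a brute-force loop
implementation, and `pingouin.intraclass_corr`'s ICC(A,1) row; Monte-Carlo
checks confirm <0.03 mean bias and 90–98% interval coverage at n = 94,
k = 2 for true ICCs of 0.3/0.6/0.9.

Although "multiple measurement" phrasing sometimes accompanies the A,1
notation in the literature, A,1 is the single-measurement form and that is
what is computed; `average=True` gives ICC(A,k) (Spearman–Brown stepped-up
bounds) for users who want the reliability of the session mean.
Interpretation uses left-closed Koo–Li bands (an exact 0.5 is "moderate",
an exact 0.9 "excellent"); negative estimates are "poor". The reliability
report uses one joint per subject as the unit of analysis (the simulator
generates a single side by default); subjects missing a session are excluded
with a warning.

## Classification

Features are standardized to zero mean and unit SD (ddof = 1);
zero-variance columns are dropped with a warning. Standardization is fit
inside each training fold of the stratified, seeded 10-fold CV — fitting it
globally before splitting leaks test information, though a
`global_standardize` flag provides that variant for comparison. KNN uses
k = 10 Euclidean neighbors; a 5–5 vote tie (possible with two classes and
even k) goes to the single nearest neighbor's label, keeping predictions
deterministic and distance-respecting.

The JVA-style decision tree ships as an editable YAML configuration
(`vagkit/data/jva_tree_default.yaml`). Its default structure — total
integral > 80 device units at the root, then low-frequency dominance
(IBAR > 1) and peak amplitude (> 0.5) checks — is a **synthetic
approximation** reconstructed from the published behaviour of JVA
classification (high TI, high PA, high sub-300-Hz energy in symptomatic
joints); the original tree's exact form is proprietary. Thresholds live in
the JVA device's units, so a `scale` factor (default 1) converts local
amplitude units before traversal; with accelerometer-unit features and the
default scale the tree classifies nearly everything asymptomatic, which is
the expected behaviour of fixed cross-device thresholds and the reason the
adaptive KNN dominates it in the comparison table.

## Problem sizes and numerical choices

- Monte-Carlo validation of the ICC uses 500 replicates at the full study
  design (n = 94, k = 2); feature-space simulation makes this cheap.
- The packaged test suite exercises the signal pipeline at 12–15 subjects
  per group and 1–4-s recordings where full scale adds nothing; the
  acceptance script runs the complete 47+47, two-session, 20-s protocol.
- Tolerances: TI = IB3 + IA3 asserted at 1e-9 relative; trapezoid oracles at
  1e-12; ICC vs brute force at 1e-10; spectra grids at 1e-12 relative.
- All CSV outputs are written deterministically; rerunning a pipeline config
  reproduces them byte-for-byte.

## Known limitations

- Signal morphology is generic (noise + damped-sinusoid bursts), not a
  biomechanical TMJ model; crepitus-like broadband signals are out of scope.
- The shipped decision tree is a stand-in configuration: comparisons against
  it measure the cost of fixed, cross-device thresholds, not the published
  tree's clinical accuracy.
- One recording per subject/side/session; bilateral designs must choose a
  unit of analysis (rows per joint vs per subject) explicitly.
- ICC forms beyond (A,1)/(A,k), Bland–Altman analysis, and ICC power
  planning are not implemented.
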