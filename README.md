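# vagkit

Toolkit for **vibroarthrography (VAG)** — the analysis of vibroacoustic
signals emitted by a moving joint, recorded with skin-mounted
accelerometers. The package targets the temporomandibular joint (TMJ)
workflow in which joint clicks (a sign of disc displacement) separate a
symptomatic from an asymptomatic group, and the central scientific question
is **test–retest repeatability**: if the sensor is removed and replaced and
the recording repeated, do the signal's features come back the same?

It is written for biosignal researchers who need a reproducible,
fully-seeded pipeline covering:

- **Synthetic cohorts** with controllable group differences and a known
  variance structure (10 jaw open/close cycles per 20-s recording at 5 kHz;
  Poisson click bursts in symptomatic joints; log-normal per-subject and
  per-session amplitude effects), plus direct feature-space simulation from
  the two-way ANOVA model so the true ICC is known exactly.
- **Spectral features**: the one-sided FFT magnitude spectrum (0.05 Hz bins
  up to 2500 Hz for the standard protocol) and its band-limited variants
  *norm1* (≤1 kHz @ 0.1 Hz) and *norm2* (≤500 Hz @ 1 Hz), from which seven
  features are computed — total integral TI, integrals below/above 300 Hz
  (IB3, IA3), their ratio IBAR, peak amplitude PA, peak frequency PF and
  median frequency MF.
- **Reliability**: the single-measurement, absolute-agreement intraclass
  correlation from a two-way model,

  `ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))`

  with McGraw–Wong F-based 95% confidence intervals and Koo–Li
  interpretation bands (poor < 0.5 ≤ moderate < 0.75 ≤ good < 0.9 ≤
  excellent).
- **Classification**: 10-neighbor Euclidean KNN under stratified 10-fold
  cross-validation with fold-wise standardization, compared against a
  configurable JVA-style threshold decision tree, reporting TPR/TNR/ACC per
  session and normalization (8 setups).

## Worked example

```python
from vagkit import TwoWayModelParams, icc_a1, simulate_feature_matrix

model = TwoWayModelParams(n=94, k=2, sigma_r=3.0, sigma_c=0.0, sigma_e=1.0)
print(f"theoretical ICC: {model.theoretical_icc:.3f}")
x = simulate_feature_matrix(model, seed=5)
res = icc_a1(x)
print(f"ICC(A,1) = {res.icc:.3f}  95% CI [{res.lci:.3f}, {res.uci:.3f}]  "
      f"-> {res.category}")
```

prints

```
theoretical ICC: 0.900
ICC(A,1) = 0.865  95% CI [0.804, 0.908]  -> good
```

i.e. with 94 subjects measured twice, a feature whose between-subject SD is
3× its residual SD is estimated at ICC ≈ 0.87 with an interval that covers
the true 0.9 — "good" repeatability on the Koo–Li scale. The scripts in
`examples/` walk through each capability (cohort simulation, spectra and
features, reliability, classifier comparison) and print annotated output;
`vagkit run --out results/` executes the whole
simulate → features → reliability → classify pipeline from the shell and
writes `manifest.csv`, per-normalization feature tables, a 7-feature ×
3-group reliability report and an 8-row classification report, all
byte-reproducible for a fixed config.

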