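# sononeedle

Simulation and readout of **ultrasound-readable glucose-sensing hydrogel
microneedle patches** — an in-silico twin of an enzyme-free continuous
glucose monitoring (CGM) measurement chain.

The device concept: a patch of millimetre-scale microneedles made of a
phenylboronic-acid (PBA) functionalised polyacrylamide hydrogel is worn
under a standard B-mode ultrasound probe.  Boronate groups in the gel bind
glucose from interstitial fluid; binding shifts the boronate ionisation
equilibrium, raising the gel's fixed charge and its Donnan osmotic
pressure, so the needles swell in proportion to the glucose level.  Silica
microspheres embedded in the needle tips make them echogenic, so the
needle length — and hence the **swelling ratio**
SR = (l₁ − l₀)/l₀ — can be read from ordinary ultrasound images and
converted to a glucose estimate.

This package implements every stage of that chain as tested, seedable
code, for researchers who want to analyse, extend or stress-test the
measurement principle without bench hardware:

- `chemo_mechanics` — Flory–Rehner swelling model with an ideal-Donnan
  ionic term and a two-equilibrium boronate binding model.  Equilibrium
  swelling solves
  Π_mix(φ) + Π_el(φ) + Π_ion(c_f) = P_conf(J) with
  Π_mix = −(RT/V₁)[ln(1−φ) + φ + χφ²],
  Π_el = −RTν_c s[(φ/φ₀)^⅓ − φ/2φ₀],
  Π_ion = RT(√(c_f² + 4c_s²) − 2c_s), and
  c_f = f·c_B/J where f = K_a(1+K_b c_g)/([H⁺]+K_a(1+K_b c_g)).
  Swelling kinetics follow a collective-diffusion (Tanaka) series with
  τ₁ = L²/(π²D).  Includes parameter fitting to SR–glucose tables and a
  1-D axial discretisation for tissue-confined needles.
- `ultrasound_sim` — seeded synthetic B-mode frames: Rayleigh speckle
  background, triangular needle echoes with silica-enhanced tips, dB
  log-compression to 8-bit gray at 0.015 mm/pixel.
- `needle_metrology` — Sobel edge detection, tip localisation, pixel
  length calibration, multi-frame temporal averaging, SR computation.
- `glucose_calibration` — linear SR-vs-glucose calibration (sensitivity,
  detection limit, saturating inverse above the physiological range),
  Pearson validation statistics.
- `synthetic_data` — ground-truthed cohorts: diabetic glucose schedules
  (4/12/6/20 mM states), first-order ISF lag (~20 min), per-device
  baselines (1.2 mm ± 20 µm), SR noise; emits frames + truth tables.
- `cgm_pipeline` / `cli` — end-to-end orchestration and a `sononeedle`
  command-line tool (`simulate`, `readout`, `calibrate`, `validate`,
  `report`).

## Worked example

The package ships the printed in vivo validation table (eight animals,
SR vs blood glucose) and a calibrated model fitted to the measured
quasi-free swelling curve:

```text
$ sononeedle validate
Pearson r = 0.942 (n = 8), t = 6.871, two-tailed p = 0.0005
```

The correlation of ultrasound-read SR with reference blood glucose is
0.942 with a two-tailed p of 0.0005 — strong evidence that needle length
tracks glycaemia.

```python
>>> import numpy as np
>>> from sononeedle import load_default_model
>>> m = load_default_model()
>>> np.round(m.sr_percent([5., 10., 20., 30., 40.]), 1)
array([19.5, 22.6, 26.5, 28.9, 30.4])
```

These equilibrium SRs reproduce the measured quasi-free values (19.4,
22.9, 26.3, 28.7, 30.6 %) to within a fraction of an SR point.  The
headline calibration numbers:

```text
$ sononeedle report
{
  "sensitivity_pct_per_mM": 0.507,   # slope of SR vs glucose, 0-20 mM
  "detection_limit_mM": 1.97,        # 1 % SR resolution / sensitivity
  "in_vivo_pearson_r": 0.942,
  "in_vivo_p_two_tailed": 0.0005,
  "fit_residual_rms": 0.236          # SR points, model vs measured curve
}
```

A full synthetic study — simulate an 8-subject cohort, render three
frames per reading, read the lengths back and estimate glucose:

```sh
sononeedle simulate --seed 3 --out study/
sononeedle readout --bundle study/
```

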