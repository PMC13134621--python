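# Methods

This note documents the models behind `sononeedle`, the parameter choices
that matter, what the synthetic data do and do not emulate, and the
numerical conventions.

## Chemo-mechanical swelling model

The needle hydrogel is treated as a Flory–Rehner network in equilibrium
with a physiological bath (pH 7.4, 150 mM 1:1 salt, 310 K).  The state
variable is the volumetric swelling ratio `J` relative to the as-stored
reference state of the device; the polymer volume fraction is
`phi = phi0 / J` with `phi0 = 0.2` for the as-prepared network.

**Glucose sensing term.** PBA boronate groups participate in two fast
equilibria: acid ionisation (`Ka`, default 10^-8.9 M, the order of
magnitude for arylboronic acids) and 1:1 glucose–boronate association
(`Kb`, fitted).  Because the glucose adduct is anionic, binding shifts the
population toward the charged form; the charged fraction is

    f = Ka (1 + Kb c_g) / ([H+] + Ka (1 + Kb c_g)),

monotone and saturating in glucose.  The gel's fixed-charge density in
the swollen state is `c_f = f * c_B / J` with `c_B` the boronate density
per reference volume (800 mol/m^3, set by the ~19.5 mol % PBA monomer
fraction; its exact value trades off against `Kb` in the fit and is held
fixed).  Fixed charge enters through the ideal-Donnan ionic pressure
`Pi_ion = RT (sqrt(c_f^2 + 4 c_s^2) - 2 c_s)`.  Competing diols
(fructose, galactose) and lactate are not modelled: their measured effect
on SR is below one point at physiological levels.

**Mechanics.** Mixing pressure is Flory–Huggins
(`-(RT/V1)[ln(1-phi) + phi + chi phi^2]`, `V1 = 1.8e-5 m^3/mol`);
elasticity is affine Gaussian
(`-RT nu_c s [(phi/phi0)^(1/3) - phi/(2 phi0)]`) with `nu_c` the chain
density per reference volume and `s >= 1` a stiffening factor for the
silica filler.  Tissue confinement is a clamped linear spring,
`P_conf = k_t max(J - J_baseline, 0) / J_baseline`: the simplest closure
that lowers the confined SR while leaving the SR-vs-glucose slope nearly
unchanged, which is exactly the measured behaviour (0.252 vs 0.255 %/mM).
The shipped `k_t = 5 kPa` is calibrated to that slope ratio.  A 1-D
axial discretisation (`solve_axial_profile`) solves the same local
balance per element for depth-dependent confinement; elements are
independent because axial stress transfer along a slender needle is
neglected.

**Length observable.** Swelling is taken isotropic, so the length
swelling ratio is `sr = (J / J_baseline)^(1/3) - 1`.  `J_baseline` is
the swelling state of the needle when its baseline length l0 is imaged,
i.e. at insertion.  It is a *fit parameter* rather than the glucose-free
equilibrium: devices are stored dry after washing, and the measured
glucose-free SR is well above zero (a dry-stored needle swells in any
bath), which forces the l0 reference below the glucose-free equilibrium.
The fitted value sits at the reference state itself (`J_baseline = 1`).

**Kinetics.** Swelling relaxation uses the collective-diffusion slab
series: the approach to a new equilibrium after a step is
`g(t) = 1 - sum_k a_k exp(-(2k-1)^2 t / tau1)`, `a_k ∝ 8/((2k-1)^2 pi^2)`
renormalised over the truncation (10 modes) so `g(0) = 0` exactly, and
`tau1 = L^2 / (pi^2 D)`.  Defaults `D = 1.2e-10 m^2/s` on the needle
height `L = 1.2 mm` give `tau1 ≈ 20 min`, so a reading 60 minutes after
a step captures ≈ 96 % of the equilibrium SR and glucose levels are
already distinguishable at 30 minutes — the device's stated 30–60 min
response window.  For piecewise-constant glucose profiles each mode
tracks its own deficit, which is exact for that forcing class and makes
cyclic schedules return SR to the cycle-start value (reversibility).

**Fitting.** `fit_parameters` runs bounded trust-region least squares on
(log10 Kb, nu_c, chi, J_baseline) from eight seeded multistart points,
minimising SR-point RMS.  The shipped calibration is fitted to the five
measured quasi-free SR values (5–40 mM); including the 5 mM point pins
the low-glucose curvature and yields the physiological-range sensitivity
of ~0.5 %/mM.  RMS of the shipped fit: 0.24 SR points.  With only four
points above 10 mM the fit is still below 0.5 points RMS but the
extrapolated low-glucose slope flattens — four points do not constrain
the binding saturation knee.  (chi, J_baseline) and (Kb, nu_c) trade off
against each other near the optimum, so parameter-recovery studies pin
chi and J_baseline; the *sensitivity* of the fitted curve is well
identified regardless.

## Synthetic ultrasound and its limits

The renderer is an incoherent envelope model, not an acoustic solver:

- Background speckle is the continuum fully-developed-speckle limit:
  per-pixel circular complex Gaussian reflectivity with variance
  proportional to scatterer density, filtered by a Gaussian PSF (axial
  sigma 1.7 px, lateral 3.3 px at 0.015 mm/px), envelope-detected.  The
  envelope is exactly Rayleigh.  A discrete scatterer sum is *not* used:
  at this pixel pitch realistic surface densities put far less than one
  scatterer per resolution cell, which would produce spiky, non-Rayleigh
  fields.
- Needles render as solid triangles (the cross-section of a pyramidal
  needle) with apex at the tip; the top quarter of a silica-loaded
  needle carries elevated source amplitude (tip aggregation of the
  microspheres).  Mild per-needle (±3 dB) and per-pixel (1 dB) texture
  emulates frame-to-frame echo variation.
- Display mapping is standard dB compression:
  `gray = clip(255 (20 log10(gain·A/REF) + DR) / DR)` with gain 30 and
  dynamic range 65.  `REF = 1175` anchors a unit reflector to gray 130,
  centring the silica tip band; amplitude constants are chosen so that,
  by construction, silica needles render in gray 80–180 and pristine
  hydrogel in 0–100 against a speckle background with median gray ≈ 30 —
  the contrast contract the readout relies on.  Scanner gain/dynamic
  range units are vendor-specific, so this mapping is a stand-in
  calibrated to those output ranges only.

Not modelled: attenuation, refraction, reverberation, probe-angle
artefacts, RF beamforming, oblique needles.  Consequently, passing tests
show that the *readout logic* is correct under the stated image
statistics; they do not certify performance on real scanner data.

## Length readout

Measurement follows the edge-detection protocol: 3×3 Sobel gradient
magnitude (unnormalised kernels, reflective borders), Otsu threshold,
connected components, tip = topmost supra-threshold pixel (ties broken
toward the component centroid column), length = (base_row − tip_row) ×
0.015 mm, averaged over three frames acquired in a short interval, and
SR always computed against the same needle's own baseline.

Two rejection cues harden detection against speckle, both derived from
the device design rather than tuned to data: edge pixels must border
pixels brighter than gray 75 (the silica contract guarantees needle
echoes ≥ 80 while the Rayleigh speckle tail stays below ~70; the gate is
disabled automatically for pristine arrays, which are genuinely hard to
detect — as the bench comparison of the two compositions shows), and a
component must span at least one third of the expected needle height
(speckle grains are PSF-sized).  Because the Sobel response peaks on the
background pixel adjacent to a bright edge, the raw topmost pixel sits
above the physical tip; the tip is refined to the first half-maximum
gray crossing within a ±2-column window, restoring pixel-exact
localisation on clean frames.  Measured accuracy: exact to the pixel
grid on noiseless frames, and within one pixel of truth for 100 % of
600 needle measurements across 200 speckled three-frame trials.

## Calibration and inversion

The SR–glucose calibration is ordinary least squares restricted to the
physiological 0–20 mM range, where the response is near-linear
(sensitivity ≈ 0.51 %/mM for the shipped model).  The detection limit is
SR resolution / sensitivity; one pixel on a 1.2 mm needle is 1.25 % SR,
and the stated 1 % resolution gives the 2 mM limit.  Inversion is linear
inside the range; when a measured SR exceeds the model's SR at 20 mM the
saturating model curve is inverted numerically instead (the linear
inverse compresses high readings).  Estimates at or above 20 mM carry a
hyperglycemia alert.  Readings taken at 60 minutes are inverted against
the model curve evaluated at 60 minutes, which removes the
non-equilibrium bias of the protocol.

## Synthetic studies

Cohort generation mirrors the animal protocol: per subject a baseline
length (1.2 mm ± 20 µm fabrication spread) and a device SR offset are
drawn once; blood glucose follows either a per-subject constant exposure
(single-reading design: baseline image at t = 0, reading at 60 min) or a
stepwise diabetic day (4/12/6/20 mM states, 10-min ramps, 60–90 min
postprandial plateaus); ISF glucose lags blood through a first-order
20-min filter; SR truth comes from the transient swelling model; frames
are rendered three per time point.  Noise structure: per-reading
Gaussian SR noise of 0.3 points (the measured cycle-to-cycle
repeatability) and a per-device offset of 0.7 points (the measured
long-term dispersion).  All draws descend from one root seed.

Under these conditions the expected correlation between measured SR and
blood glucose in an 8-subject, 5–22 mM cohort is ≈ 0.94 — consistent
with the in vivo validation — but a single 8-subject draw scatters by
roughly ±0.04, so the end-to-end check reports the mean correlation over
ten seeded replicate cohorts rather than one draw.  Likewise the
noise-free glucose RMSE is compared to the 2 mM detection limit as a
mean over seeds: above 20 mM the response saturates, so a single pixel
of length error is locally worth several mM and individual draws
straddle the limit.  In the daily-schedule (trend-tracking) design,
glucose estimates during fast excursions read low by construction: the
ISF lag and swelling relaxation are physical delays of the device, and
no inversion at a single time point can remove them.  The study design
emulates neither insulin pharmacokinetics nor the unexplained offset
between in vitro and in vivo SR magnitudes; the cohort generator's
glucose span (5–22 mM) simply reproduces the validation study's range.

## Numerical conventions

- Equilibrium root finding: Brent's method on log J over [1, 30],
  xtol 1e-13; the returned residual is asserted below 1e-6 · RT/V1.
  The vectorised curve evaluator uses 80 fixed bisection steps on the
  same bracket and agrees with the scalar solver to < 1e-6 SR points.
  Absence of a sign change raises a diagnostic error carrying the
  bracket-end pressure components.
- The confinement spring is clamped at the baseline so an infinitely
  stiff environment pins J at J_baseline instead of compressing the gel.
- Image coordinates: row 0 at top, needle axis vertical, tips above the
  substrate row; lengths in mm, pixel pitch in mm/px, all indices
  0-based.
- Reported correlation statistics round half-up (three decimals for r,
  four for p).
- Seeds: every stage derives child seeds below 2^31 from one root via
  `numpy` SeedSequence hashing of (root, stage tag, index).

## Known limitations

- The binding model is a lumped two-equilibrium description; pH is fixed
  and boronate–diol 2:1 complexes, competing analytes and buffer
  specifics are out of scope.
- Donnan electrostatics are ideal (no Poisson–Boltzmann corrections);
  elasticity is Gaussian (no finite-extensibility stiffening at large J).
- The axial profile solver neglects shear coupling between elements.
- The renderer's gray calibration is a display-referred stand-in; only
  the gray-level geometry it guarantees is meaningful.
- Sub-pixel length estimation is deliberately not attempted: the readout
  is quantised to the 15 µm pixel grid, which bounds single-reading
  glucose resolution at roughly the stated detection limit.
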