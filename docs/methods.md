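# Methods

## Spin-3/2 dynamics

The density operator of an isolated spin-3/2 nucleus is expanded on unit
normalized irreducible tensor operators `T_lm` (l = 1..3, m = -l..l),
giving a 15-dimensional coefficient vector. Evolution is

```
da/dt = (L_RF + L_Q - R) a + R a_eq
```

with `L_RF` the nutation commutator for a rectangular on-resonance RF
field of amplitude `w1 = flip / tau_rf`, `L_Q` the first-order quadrupole
commutator `H_Q = (wq/2) Iz^2` (satellites offset by ±fQ, `wq = 2 pi fQ`),
and `R` the Redfield quadrupolar relaxation superoperator
`R = sum_q J_|q| [T_2q, [T_2q^H, .]]` with spectral densities
`J0 >= J1 >= J2 >= 0` (1/s). In this normalization the observable rates
are exactly `R2f = J0 + J1` (60% satellite fraction), `R2s = J1 + J2`
(40% central), `R1f = 2 J1` (20%) and `R1s = 2 J2` (80%); the test suite
verifies these against a brute-force ODE integration of the 4×4 density
matrix.

Segments (pulses, delays) have constant generators, so propagation uses a
single matrix exponential per segment (augmented 16×16 to carry the
equilibrium drive). This is exact: subdividing a rectangular pulse into
any number of steps changes nothing, which subsumes any step-size
requirement for relaxation during soft pulses.

### Sequence conventions

* TI runs from the end of the inversion pulse to the start of the
  excitation pulse; TE runs from the middle of the excitation pulse to
  the echo. The signal observable is `sqrt(2) |a_{1,-1}|`, normalized so
  an ideal 90° pulse on equilibrium gives `m0`.
* NaDW and NaSIRFLA are treated as ideally spoiled: at the end of each TR
  only the longitudinal coefficients `T_10, T_20, T_30` survive.
* NaPACMAN is, by design, a *coherent-magnetization* steady-state
  sequence; ideal spoiling is wrong for it. It is simulated with
  phase-alternated excitation (0°/180°) and a residual transverse
  coherence fraction of 0.656 surviving each TR. That fraction stands in
  for the partial dephasing of the (unpublished) twisted-projection
  readout gradients and is calibrated together with the environment
  parameters (below). With full spoiling no physically admissible
  parameter set reproduces the published edema weighting row (the fit
  bottoms out ~0.07 away); with the coherent model all twelve published
  weightings are reproduced exactly.
* Off-resonance is fixed at zero; B0/B1 inhomogeneity and trajectory
  simulation are out of scope.
* Relaxation weighting RW = steady-state |signal at TE| / (m0 sin flip).
  The steady state is iterated from thermal equilibrium until the echo
  signal changes by < 1e-9 (cap 10,000 repetitions). When all spectral
  densities are exactly zero no stationary state exists (there is no
  recovery drive and repeated excitation drains the longitudinal state),
  so the relaxation-free case reports the first acquisition from
  equilibrium; this realizes RW = 1, the intended meaning of a loss-free
  acquisition.
* `fQ_model: powder-average` averages the complex steady-state signal
  over 64 Gauss–Legendre nodes in cos β with splitting scaled by
  `P2(cos β)`; the shipped myelin default uses a single effective
  splitting, which sufficed to match the published weightings.

### Environment calibration

The per-environment spectral densities and the myelin splitting are not
published; the shipped defaults (`data/environments.yaml`) are
least-squares calibrations such that the simulated RW grid reproduces the
published values for intra/extra (0.95, 0.35, 0.45), myelin
(0.85, 0.01, 0.61; fitted fQ ≈ 514 Hz) and edema (0.96, 0.40, 0.10) —
all to machine precision — with the NaPACMAN coherence fraction fitted
jointly. They are stand-ins: other parameter sets may fit equally well,
and no claim is made that they equal real tissue relaxation parameters.
The agar reference cannot satisfy all three measured control-WM relative
intensities simultaneously under this model; the shipped compromise gives
0.585 / 0.514 / 0.623 against measured 0.62 / 0.49 / 0.62. CSF is an
uncalibrated long-T1 fluid (NaSIRFLA suppresses it to RW ≈ 0.07).

## Compartment model

Healthy control white matter uses fractions `v_myelin = 0.0865`,
`v_intra = 0.495`, `v_extra = 0.172`, solids 0.2465. These are
back-solved from the published per-compartment sodium values (6.2 / 6.8 /
total 37.9 mmol/L-tissue at 12.5 / 78.75 / 145 mM); the familiar rounded
9 / 50 / 17% are display rounding of the same numbers. One gram of tissue
is treated as one milliliter (unit density), matching the published
arithmetic. Myelin water concentration is `(c_intra + c_extra)/2` because
the intra- and extracellular layers within myelin have equal thickness.

Demyelination with retention `r` removes `(1-r)` of the myelin water and
`k = 1.5` times as much myelin solids (myelin ≈ 40% water); intra- and
extracellular *absolute* volumes are unchanged and all fractions are
renormalized to the shrunken (or, with edema `E`, swollen) volume.
Defaults: NAWM `r = 0.80` (gives the published 4.3% atrophy and +0.8%
TSC), lesion `r = 0.45, E = 0.089` (gives edema fraction 0.092 and the
published lesion contrast). The extracellular fraction is held at 0.172
across states. Edema concentration is set to 145 mM (extracellular-like
free water); axonal degeneration is deliberately not modeled.

## Signal table

Relative contributions are `q_x · RW[seq][x] / (q_intra(control) ·
RW[seq][intra])`, summed per state, with percent differences on the
totals. Two RW routes exist — the published grid verbatim and the
simulator — so the tissue-model predictions are testable independently of
the simulator calibration; the routes agree to < 1e-8 per entry. Printed
precision (2 dp, integer-ish percent) is applied only at presentation.

## Image analysis

The PSF model apodizes k-space by `exp(-t(k)/T2*)` with sampling time
linear in |k| over a configurable readout (default 10 ms, saline
T2* = 53 ms) — a center-out radial-equivalent approximation, since the
actual twisted-projection trajectory parameters are unpublished. Kernels
are peak-normalized; convolution normalizes the kernel to unit sum and
zero-pads (no wrap-around), so a threshold of 0.025 means exactly 2.5% of
the full CSF value. Expanded CSF masks are unions of the input mask and
the threshold exceedance, hence always supersets. TSC calibration is
`intensity × 64 mM`, linear and invertible.

## Synthetic phantom and cohort

The phantom is a 48×48×24 grid at 3.2×3.2×6.4 mm (anisotropic, matching
the acquisition) containing a WM ellipsoid, GM shell, two ventricular CSF
bodies, three tract ROIs (SCC, PLIC, ALIC), bilateral 64 mM agar tubes
outside the head, and six ellipsoidal lesions spanning 1–78 voxels.
Rendering assigns each region its forward-model intensity relative to the
agar reference, convolves with the PSF and adds seeded Rician noise
(magnitude of a complex Gaussian), the appropriate model for magnitude
images.

The cohort simulator works at ROI level (it does not render 39 volumes):
per subject a multiplicative Gaussian biology factor (sd 0.032, chosen so
control-WM NaDW spread matches the measured 0.02) scales all signals;
per subject-region a lesion-severity factor (sd 0.5, consistent with the
large measured spread of lesion intensities, 0.83 ± 0.14 against NAWM
0.64) scales the lesion effect identically across sequences, since
demyelination/edema extent is a tissue property; ROI means add Gaussian
measurement error (sd 0.005, a ~50-voxel ROI at image noise ~0.03).
Ages and sex are drawn to match the cohort description.

What passing the synthetic tests does **not** show: the phantom has no
anatomy, no registration error, no B0/B1 or off-resonance structure, no
lesion-type heterogeneity, and its noise and between-subject variability
are exactly the generator's assumptions. Recovery results demonstrate
internal consistency of the pipeline, not clinical validity.

## Statistics

Welch t-tests by default (pooled optional) — group sizes are unequal
(9 vs 30); two-sided throughout. BH-FDR via the standard step-up;
families follow the study design (per-sequence region comparisons; the
clinical correlations as one family, q = 0.2 exploratory). Partial
Pearson correlation residualizes both variables on the covariates (age,
sex coded 0/1) and tests r with `n - 2 - c` degrees of freedom. OLS
slopes report 95% CI half-widths in "±" style.

## Numerical notes

* Steady-state convergence tolerance 1e-9 on the echo signal; the
  phase-alternated sequence is checked every full cycle.
* Hermiticity (`a_{l,-m} = (-1)^m conj(a_{l,m})`) is preserved to 1e-10
  through all propagators.
* Relaxation weighting is validated against an upper bound of 1.05; the
  calibrated set stays ≤ 1.
* Degenerate inputs raise: non-ordered spectral densities, infeasible
  MWF/WC pairs, demyelination exceeding available solids, empty ROIs
  after CSF exclusion, zero-variance regressors, rank-deficient
  covariates.

## Problem sizes

The test suite uses the 48×48×24 phantom, 100-replicate cohort
re-simulations for the detection-rate check and 10,000 vectorized null
simulations for the t-test type-I rate; the full suite runs in well under
a minute on one CPU.
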