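# Methods

This note documents the model, the numerical choices, and the design
decisions behind `capnoflow`, together with what the simulation studies do
and do not establish.

## Transport model

Four compartments stacked along z (blood-irrigated tissue 0.3 cm, stratum
corneum 16 µm, measurement cell 0.25 cm, collection cell 0.25 cm; exchange
area 10 cm²) each carry a 1D convection–diffusion equation for the CO2
concentration. All parameters are taken at a regulated skin temperature of
42 °C. Key values and where they come from:

| parameter | value | origin |
|---|---|---|
| β_blood (Ostwald) | 2.7467e-2 mol·m⁻³·mmHg⁻¹ | linear extrapolation of 3.08e-2 @37 °C, 2.88e-2 @40 °C |
| H_blood | 0.54 | β·R·T with R = 0.0623637 m³·mmHg·K⁻¹·mol⁻¹, T = 315.15 K |
| skin conductance | 121e-9 mL·s⁻¹·cm⁻²·mmHg⁻¹ | interpolation of 77e-9 @37 °C, 130e-9 @43 °C |
| kp_sc | 1.0e-6 m·s⁻¹ | conductance × P_air × 1e-2 |
| Kr | 1.9e-10 cm²·s⁻¹·mmHg⁻¹ | kp·Δz_skin/P_air |
| α (Bunsen) | 19.2e-4 /mmHg | H_skin/P_air with H_skin = 1.6, P_air = 831.21 mmHg |
| D_skin | 1.0e-7 cm²·s⁻¹ | Kr/α |
| D_blood, D_air | 2.2e-5, 0.18 cm²·s⁻¹ | literature |
| u_blood | 1.83e-4 cm·s⁻¹ | published table value; Q/A gives 1.80e-4, the table value is used for simulation |
| u_coll | Q_air/(ΔxΔy), 1.67e-3 cm·s⁻¹ at 1 mL/min | air pump flow |

The *unrounded* extrapolated solubility is used for every
pressure↔concentration conversion (40 mmHg ↔ 1.0987, 50 mmHg ↔ 1.3733
mol·m⁻³); the rounded 2.75e-2 is display-only. Internal units are cm, s,
mol·m⁻³, mmHg; quantities published in m·s⁻¹ or mL-based units are
converted at ingestion.

### Interfaces and through-flows

At each compartment interface only the diffusive flux is conserved. The
interface concentration pair solves flux continuity together with Henry
partial-pressure continuity:

    c⁻ = (D⁻/δz⁻·c_below + D⁺/δz⁺·c_above) / (D⁻/δz⁻ + (H⁺/H⁻)·D⁺/δz⁺),
    c⁺ = (H⁺/H⁻)·c⁻.

This is the unique closure that satisfies both continuity conditions and
reduces to the arithmetic average for identical media (a form of this
closure with a sign defect in the denominator would divide by zero in that
limit; the form above is the re-derived one).

Convection never crosses an interface. The blood stream enters through the
Dirichlet boundary (steering coefficient D/δz² + u/(2δz)) and leaves
laterally just below the skin, modelled as a −u/(2δz) diagonal term on the
last blood row. The collection-cell air stream enters just above the
measurement-cell interface carrying the *ambient inlet concentration* (an
exogenous input, 0 by default — an inlet CO2 filter is assumed; the
unfiltered ambient value 0.01613 mol·m⁻³ is available as a constant) and
leaves at the top. This fresh-air through-flow is what dilutes the device
concentration: without it, axial advection alone cannot remove mass from a
Neumann-closed column (its steady state is flow-independent), and the
speed-versus-level compromise of the open-chamber design would disappear.

### Discretization

3 interior points per compartment at spacing δz = Δz/4, plus the outer
collection-boundary point carrying the Neumann closure: 13 states. The
central second-order stencil is used for both diffusion and advection; the
largest cell Péclet number at the default parameters is 0.31 (blood), safely
below the oscillation threshold of 1, and the assembler warns if a
configuration exceeds it. Implicit Euler with δt = 1 s (configurable)
integrates the system; A = I − δt·F has all eigenvalue magnitudes above 1
for any δt, so the scheme is unconditionally stable, and the trajectory
converges at first order to the matrix-exponential solution (verified
against a `scipy.linalg.expm` oracle). δt = 1 s resolves the ~600 s
transport delay and ~10³ s rise times at sub-percent granularity.

Boundary kinds are fixed for the device (Dirichlet blood inlet, Neumann
top); the assembler also supports a sealed bottom and a Dirichlet top, used
by the validation suite (mass conservation in a sealed column; analytic
piecewise-linear Henry-jump steady profile on a two-compartment toy).

## Inversion

The unknown blood-inlet concentration becomes state element 0 with an AR(1)
prior dC_in/dt = φ·C_in + w; the Dirichlet steering coefficient becomes the
coupling from the input state into the first blood point, and the only
remaining exogenous input is the collection-cell inlet. A standard Kalman
filter on the implicit-Euler discretization (covariance extrapolation
P ← A⁻¹PA⁻ᵀ + Q, Joseph-form measurement update) runs one
predict–correct cycle per sample; element 0 of the filtered state is the
blood estimate and P = C/β its pressure.

Defaults: model-noise variance 1e-8 (mol·m⁻³)², observation-noise variance
R = 1e-6 (mol·m⁻³)² (deliberately independent of the noise actually in the
data), φ = 0, zero initial state, identity initial covariance. φ is in s⁻¹
and enters through the implicit scheme (input self-transition
1/(1 − φδt)).

**Structure of Q.** In the augmented model the only stochastic forcing is
the white noise driving the input state, so Q carries the 1e-8 variance on
that element alone by default. An unstructured full-state Q (same variance
on every element) is available but makes the input estimate much slower and
almost independent of the Q magnitude: process noise attributed to the fast
measurement-cell states absorbs the innovations, and the blood element is
corrected only through its weak cross-covariance. With the input-only
structure the noiseless step study yields a settled hypercapnia estimate of
1.3744 mol·m⁻³, direct delay 598 s, inverse delay 0 s and aligned RMSE
0.028 mol·m⁻³; the 10–90 % rise time of the estimate is ≈ 805 s, i.e. the
filter partially deconvolves the ~1600 s rise of the measurement signal.
A slower, non-deconvolving tracker (rise time near the measurement's own)
would require an input-noise rate near 5e-10 (mol·m⁻³)²·s⁻¹, inconsistent
with the 1e-8 default; the package keeps the stated noise settings.

## Scenarios

**Step study.** The input steps from 40 to 50 mmHg. The column starts from
a zero state and runs 12000 s at normocapnia so that both the transport
profile and the filter settle; the analysis window spans the final 6000 s
of normocapnia and 9000 s of hypercapnia (δt = 1 s, 15000 samples).
Observation noise at variances {0, 1e-8, 1e-6} is injected on the scalar
measurement only, from a seeded generator. Performance factors: per-phase
settled means (90 % settling rule — the mean is taken after the signal has
covered 90 % of the gap between its phase-start level and the equilibrium
estimated from the final tenth of the phase; short phases therefore yield
under-estimated means rather than errors), relative performance
100(μ−μ̂)/μ, RMSE after aligning the signals at the lag of maximum
cross-correlation, the global ratio 20·log₁₀(rms/RMSE) in dB, 10–90 % rise
time with sub-sample linear interpolation (falls handled symmetrically),
and cross-correlation delays on the δt lattice for the direct
(input→measurement), inverse (measurement→estimate) and global
(input→estimate) paths.

**Air-flow sweep.** Q_air over 0.1–10 mL·min⁻¹; for each flow the steady
hypercapnia level at the top of the collection column, and the delay and
rise time of its step response starting from the normocapnia steady state
(30000 s horizon, enough for the slowest flow to settle). The level falls
monotonically with flow while both response times shrink — the open-chamber
compromise.

**Clinical chronogram.** A realistic phase sequence (initialization
1–1188 s at normocapnia, then normocapnia/hypocapnia 30 mmHg/normocapnia/
hypercapnia 45/hypercapnia 50/normocapnia, with a 990 s extension; end at
4654 s). The run starts from the normocapnia steady state — the
initialization phase stands for the settling time on the patient.
Observation noise variance 1e-6; inversion with φ = 0 and φ = −0.0036 s⁻¹.
The model-mismatch variant re-simulates the chronogram with both tissue
diffusivities scaled ×5 while inverting with the nominal model. This
emulates generating the data with a *well-mixed compartmental* simulator
(no diffusive bottleneck in the tissues): the measured signal becomes ~3.6×
larger than the inverse model expects and the φ = 0 estimate overshoots by
200–350 % per phase, the regime in which the damped prior is useful.
The ×5 factor was fixed from that target overshoot regime; the
skin-only knob saturates at 1.57× amplification (blood-side diffusion
dominates the column resistance) and cannot reach it.

## What the synthetic studies show — and what they don't

The generator *is* the forward model: matched-model results (step study)
demonstrate the identifiability of the blood input through the column and
the filter's noise adaptability, not robustness to real physiology. Real
recordings add inter-individual skin parameters, temperature drift, sweat
and VOC interference, sensor drift and contact losses — none are modelled.
The mismatch study probes exactly one structured error (tissue transport
too slow in the inverse model) chosen to reproduce the qualitative
overshoot-plus-regularization behaviour; the residual shrinkage bias of the
damped prior (the estimate retains only a few percent of the level at
φ = −0.0036 with the default gain) shows that φ trades bias for variance
and must be tuned jointly with Q in any deployment.

## Numerical details and edge cases

- Linear solves use a one-time LU factorization of A per configuration.
- The Joseph covariance form keeps P symmetric PSD over ≥ 1e5 cycles
  (verified); non-finite measurements are skipped with the prediction
  carried forward and a warning.
- The NDIR calibration fit is bounded (m, n, u ≥ 0) trust-region least
  squares started from the linear limit (u = 1, n = 0, (ℓ, m) by ordinary
  least squares); gradient tolerance 1e-10. The intercept can be fitted or
  fixed from blank measurements — both modes are first-class. The main
  pipeline operates on concentrations directly; the NDIR front end converts
  synthetic voltages when a full sensor chain is wanted.
- Metrics flag undefined cases (flat signals, uncrossed thresholds,
  settling never reached against a *nominal* equilibrium) as NaN with a
  warning rather than raising mid-report.
- Degenerate geometry (non-positive heights/counts, identical calibration
  concentrations, gapped chronograms) raises typed errors at construction.

## Known limitations

- 1D axial geometry; the physical transverse air flow is represented as an
  axial advection with the same volumetric throughput. A 2D model is out of
  scope.
- Central advection without flux limiting: valid for the device's Péclet
  numbers, not for strongly advective regimes.
- Fixed Q/R Kalman filter: no adaptive noise estimation, smoothing, or
  nonlinear filtering.
- The Neumann-at-blood "inverse model" boundary formulation (an alternative
  to state augmentation) is not implemented; only the Kalman route is.
- The clinical mismatch study is an emulation; the original compartmental
  clinical simulator is not public and its exact outputs are not
  reproduced.
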