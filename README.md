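# capnoflow

Dynamic modelling of transcutaneous CO2 transport for an open-chamber
capnometry wristband, with real-time Kalman inversion of the blood CO2
level.

## The problem

Arterial CO2 pressure (PCO2) tracks respiratory sufficiency, so continuous
capnometry matters for COPD follow-up, home ventilation monitoring and
anaesthesia recovery. A wristband that senses the CO2 diffusing through the
skin avoids masks and cannulas, but an *open-chamber* design — a continuous
air flow flushing the sensing volume — means the device never reaches the
static equilibrium that classical transcutaneous sensors rely on. Relating
the measured gas concentration back to the blood level then requires a
*dynamic* transport model and an on-line inverse method. That is what this
package implements, for researchers designing such sensors or the signal
processing behind them.

## The model

CO2 moves along the axis z normal to the skin through four compartments —
blood-irrigated tissue, stratum corneum, NDIR measurement cell, collection
cell — each governed by a 1D convection–diffusion equation

    ∂C/∂t = ∂/∂z ( D ∂C/∂z − u C ),

with a prescribed blood concentration at the bottom (Dirichlet), zero
diffusive flux at the top (Neumann), and Henry-law interface conditions
(flux continuity plus partial-pressure continuity C⁻/H⁻ = C⁺/H⁺) between
compartments; only diffusive flux crosses an interface, while the
convective streams (blood flow, collection air flow) enter and leave at the
compartment edges. A finite-difference discretization (3 interior points
per compartment + the outer boundary point, N = 13) gives a linear
state-space model

    A c_{k+1} = c_k + δt G q_{k+1},   A = I − δt F,      (implicit Euler)
    y_k = hᵀ c_k + v_k,                                   (NDIR observation)

which is unconditionally stable because every eigenvalue of F has
non-positive real part. For the inverse problem the unknown blood input is
promoted to a state with an AR(1) prior dC_in/dt = φ C_in + w (regularity
parameter φ ≤ 0), and a Kalman filter with Joseph-form updates estimates it
recursively; the Ostwald solubility β converts the estimate to pressure,
P = C/β. An NDIR module models the dual-wavelength (4.26/3.91 µm)
thermopile measurement, −ln[U_λ1/U_λ2] ≈ ℓ + m C^u + n C^{2u}, and its
supervised calibration.

All physical parameters (solubilities, Henry coefficients, skin
conductance chain, geometry) are derived in `capnoflow.params` from the
published primary constants at 42 °C.

## Worked example

```python
from capnoflow import run_step_study
from capnoflow.workbench import format_step_table

print(format_step_table(run_step_study()))
```

```
parameter              var=0   var=1e-08  var=1e-06
mu_hyper (mol/m3)      1.3733  1.3733     1.3733
mu_hat_hyper (mol/m3)  1.3744  1.3744     1.3742
rmse aligned (mol/m3)  0.0282  0.0282     0.0284
perf_rel (%)           -0.076  -0.076     -0.067
rsb_global (dB)        33.09   33.08      33.02
t_r (s)                805     806        808
td_dir (s)             598     605        605
td_inv (s)             0       0          0
td_global (s)          614     614        609
```

The blood input steps from normocapnia (40 mmHg, 1.0987 mol/m³) to
hypercapnia (50 mmHg, 1.3733 mol/m³). The signal needs ~600 s (`td_dir`) to
propagate to the measurement cell, where it arrives diluted ~12× by the
1 mL/min collection air flow. The Kalman estimate tracks the measurement
with no added delay (`td_inv` = 0) and recovers the hypercapnia plateau to
better than 0.1 % (`mu_hat_hyper`) at every observation-noise level —
the filter adapts from noiseless data up to σ² = 1e-6 (mol/m³)² with
almost no degradation of the aligned reconstruction error.

The `examples/` directory holds one short script per capability:
parameter derivation, the step study, the air-flow speed/level trade-off,
the clinical chronogram with the φ regularizer under model mismatch, and
NDIR calibration. A thin CLI wraps the scenario runners:

```sh
capnoflow run step --out results/step
capnoflow run airflow --out results/airflow --flows 0.1 1 10
capnoflow run clinical --out results/clinical --phi 0 -0.0036
```

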