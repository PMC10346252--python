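"""Calibrate the dual-wavelength NDIR front end on synthetic voltages.

Synthetic thermopile read-outs are generated from a known linear-quadratic
response (non-integer power of the CO2 concentration), perturbed with
measurement noise, and the calibration parameters are re-estimated by
bounded nonlinear least squares.
"""

import numpy as np

from capnoflow.ndir import (CalibrationModel, CalibrationSample,
                            fit_calibration, forward_logratio,
                            synthesize_voltages)

true = CalibrationModel(intercept=0.12, m=0.65, n=0.07, u_cal=0.75)
C = np.linspace(0.05, 4.0, 20)          # known gas compositions, mol/m3
U1, U2 = synthesize_voltages(C, true)   # thermopile voltages at 4.26/3.91 um

rng = np.random.default_rng(0)
log_ratio = np.log(U1 / U2) + rng.normal(0, 5e-4, size=len(C))
samples = [CalibrationSample(c, lr) for c, lr in zip(C, log_ratio)]

fitted, psi = fit_calibration(samples)
print(f"{'parameter':>10} {'true':>8} {'fitted':>10}")
for name in ("intercept", "m", "n", "u_cal"):
    print(f"{name:>10} {getattr(true, name):8.3f} {getattr(fitted, name):10.4f}")
print(f"residual cost Psi = {psi:.2e}")
print()
print("With 5e-4 voltage noise the four calibration parameters are recovered")
print("to a few percent; Psi is the sum of squared log-ratio residuals.")
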