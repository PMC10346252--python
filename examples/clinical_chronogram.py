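"""Realistic clinical chronogram and the role of the regularity parameter φ.

A sequence of capnia phases (hypocapnia 30 mmHg, normocapnia 40, two
hypercapnia steps 45/50) is simulated with a deliberately mismatched
simulator — tissue diffusivities relaxed to emulate a well-mixed
compartmental model — and inverted with the nominal transport model.  With
φ = 0 the unconstrained input estimate inherits the full model-mismatch
bias; the AR(1) prior with φ = −0.0036 s⁻¹ damps it.
"""

import numpy as np

from capnoflow import ClinicalConfig, run_clinical_study
from capnoflow.workbench import WELL_MIXED_MISMATCH

cfg = ClinicalConfig(mismatch_dblood_factor=WELL_MIXED_MISMATCH,
                     mismatch_dskin_factor=WELL_MIXED_MISMATCH, seed=0)
reports = run_clinical_study(cfg)

print(f"{'phase':>16} {'true mol/m3':>12} {'phi=0 %err':>11} {'phi=-0.0036 %err':>17}")
r0, rd = reports[0.0], reports[-0.0036]
for label in r0.perf_rel_pct:
    print(f"{label:>16} {r0.mu[label]:12.3f} {r0.perf_rel_pct[label]:11.1f} "
          f"{rd.perf_rel_pct[label]:17.1f}")
print()
print(f"aligned rmse: phi=0 -> {r0.rmse_aligned:.3f},"
      f" phi=-0.0036 -> {rd.rmse_aligned:.3f} mol/m3")
print("The damped prior trades a uniform shrinkage of the level for a large")
print("reduction of the mismatch-induced overshoot on every capnia phase.")
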