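"""Simulate a capnia step and recover the blood CO2 level by Kalman inversion.

The blood CO2 input steps from normocapnia (40 mmHg) to hypercapnia
(50 mmHg); the transport column delays and dilutes it by the time it reaches
the NDIR measurement cell, and the augmented-state Kalman filter inverts the
measurement back to blood concentration.  Runs the study at three
observation-noise levels and prints the performance-factor table.
"""

from capnoflow import run_step_study
from capnoflow.workbench import format_step_table

result = run_step_study()
print(format_step_table(result))
print()
print("Reading the table: mu_hat_hyper is the settled blood estimate on the")
print("hypercapnia plateau (true level 1.3733 mol/m3); td_dir is the transport")
print("delay from blood to the measurement cell; td_inv = 0 s means the")
print("estimate tracks the measurement without added lag; rmse/rsb score the")
print("aligned reconstruction error of the blood input.")
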