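"""The open-chamber compromise: response speed versus signal level.

Sweeping the collection-cell air flow over 0.1–10 mL/min shows that faster
flushing shortens the delay and rise time of the measured signal but dilutes
the CO2 concentration (and hence the signal-to-noise ratio) in the device.
"""

from capnoflow import run_airflow_sweep

sweep = run_airflow_sweep()
print(f"{'flow mL/min':>12} {'hyper level mol/m3':>20} {'delay s':>9} {'rise s':>9}")
for f, lvl, d, r in zip(sweep.flows_ml_min, sweep.hyper_level,
                        sweep.delay_s, sweep.rise_time_s):
    print(f"{f:12.1f} {lvl:20.5f} {d:9.0f} {r:9.0f}")
print()
print("Level falls monotonically with flow while delay and rise time shrink:")
print("the operating point (1 mL/min) balances the two.")
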