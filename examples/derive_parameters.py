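"""Recompute the physical parameters of the transport model from primaries.

All tabulated constants of the device model are derived from a handful of
published primary values (solubilities at two temperatures, skin conductance
at two temperatures, geometry) — run this to see the whole chain at 42 °C.
"""

from capnoflow import ModelParams, blood_solubility_42C

p = ModelParams()

print("Blood at 42 °C")
print(f"  Ostwald solubility beta  = {blood_solubility_42C():.5g} mol/m3/mmHg"
      f"  (rounded: {blood_solubility_42C(rounded=True):.3g})")
print(f"  Henry coefficient H      = {p.blood.H_blood:.4f}  (~0.54)")
print(f"  normocapnia 40 mmHg     -> {p.to_concentration(40):.4f} mol/m3")
print(f"  hypercapnia 50 mmHg     -> {p.to_concentration(50):.4f} mol/m3")

s = p.skin
print("Stratum corneum at 42 °C")
print(f"  conductance/area         = {s.G_cond_per_area:.4g} mL/s/cm2/mmHg")
print(f"  mass transfer kp         = {s.kp_sc:.3g} m/s")
print(f"  Krogh constant Kr        = {s.Kr:.3g} cm2/s/mmHg")
print(f"  Bunsen solubility alpha  = {s.alpha_bunsen:.3g} mL(STPD)/mL/mmHg")
print(f"  diffusivity D = Kr/alpha = {s.D_derived:.3g} cm2/s")

# Each line reproduces the corresponding tabulated device constant; the
# diffusivity ~1e-7 cm2/s makes the 16 µm stratum corneum the main barrier.
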