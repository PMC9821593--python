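"""Hydrodynamic radius, shape ratio and swelling from solution data.

Converts a measured self-diffusion coefficient into a Stokes-Einstein
hydrodynamic radius, classifies the molecular shape from Rg/RH and
quantifies the pH-induced swelling of the carrier as percent changes.
"""

from dendrikit import percent_change, shape_ratio, stokes_einstein_rh

# DOSY-style measurement: D at 30 C in a 50:50 H2O/D2O mixture whose
# viscosity here is chosen to reproduce RH = 2.97 nm
d = 8.10e-11          # m^2/s
temperature = 303.15  # K
eta = 9.231e-4        # Pa s

res = stokes_einstein_rh(d, temperature, eta, rg=1.87)
print(f"RH = {res.rh:.2f} nm from D = {d:.2e} m^2/s "
      f"(T = {temperature} K, eta = {eta:.3e} Pa s)")

# SAXS/DLS pairs at three pH values: (Rg, RH) in nm
pairs = {10.2: (1.87, 2.45), 7.0: (2.11, 2.67), 4.3: (2.17, 2.79)}
for ph, (rg, rh) in pairs.items():
    ratio, label = shape_ratio(rg, rh)
    print(f"pH {ph:5}: Rg/RH = {ratio:.3f} -> {label}")

print(f"RH swelling pH 10.2 -> 4.3: {percent_change(2.45, 2.79):.2f}%")
print(f"Rg swelling pH 10.2 -> 4.3: {percent_change(1.87, 2.17):.2f}%")
print()
print("Rg/RH in the 0.7-0.8 band marks a homogeneous sphere-like particle")
print("(a uniform sphere sits at sqrt(3/5) ~ 0.775); the percent increases")
print("quantify the electrostatic swelling as the carrier protonates at")
print("acidic pH.")
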