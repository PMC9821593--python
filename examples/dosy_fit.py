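"""Diffusion coefficient from a pulsed-field-gradient NMR decay.

Simulates a BPPLED-style DOSY decay (25-step linear gradient ramp,
2-95% of maximum strength) with 1% noise and fits the Stejskal-Tanner
model I(g) = I0 exp(-D (gamma delta g)^2 (Delta - delta/3)) to recover
the self-diffusion coefficient.
"""

from dendrikit import fit_dosy_diffusion, make_dosy_decay, stokes_einstein_rh

d_true = 8.10e-11  # m^2/s, a G4-dendrimer-scale diffusivity
decay = make_dosy_decay(d_true, noise_sd=0.01, seed=1)
fit = fit_dosy_diffusion(decay)

print(f"true D    = {d_true:.3e} m^2/s")
print(f"fitted D  = {fit.d:.3e} m^2/s  ({(fit.d / d_true - 1) * 100:+.2f}%)")
print(f"I0        = {fit.i0:.4f}   r^2 = {fit.r_squared:.5f}")
print(f"residual signal at max gradient: "
      f"{decay.intensity[-1] / decay.intensity[0] * 100:.1f}%")

rh = stokes_einstein_rh(fit.d, 303.15, 9.231e-4).rh
print(f"Stokes-Einstein RH at 30 C: {rh:.2f} nm")
print()
print("The pulse timings (delta = 2.8 ms bipolar pair, Delta = 350 ms)")
print("attenuate the signal into the few-percent residual regime a DOSY")
print("experiment is tuned to; the fitted D feeds straight into the")
print("hydrodynamic-radius estimate.")
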