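"""How diffusion time shapes the decay of a biphasic sample.

Evaluates the forward model on the standard grid and prints, per diffusion
time Delta, the large-gradient plateau (naively read as the condensed
fraction) and the mono-exponential diffusion coefficient fitted to the
curve.  Both drift with Delta -- the signature of interphase exchange and
restricted diffusion that the global fit exploits, and the reason a plateau
at a single Delta underestimates the condensed fraction.
"""

import redifine as rd

params = rd.CondensateParams(
    D_dil=8.0e-11, D_cond=8.9e-13, nu_cond=0.753, R_drop=1.21e-6, p=0.405e-6
)
scheme = rd.default_scheme("protein")
dataset = rd.generate_dataset(params, scheme)
surface = rd.redifine_signal(params, scheme)

print("true nu_cond = 0.753, true D_dil = 8.0e-11 m^2/s")
print(f"{'Delta [ms]':>11} {'plateau':>9} {'D_mono [m^2/s]':>15} {'kurtosis K':>11}")
for i, Delta in enumerate(scheme.diffusion_times):
    plateau = surface.values[i, -1]
    D_mono, _ = rd.fit_monoexponential(dataset, Delta)
    _, K = rd.estimate_kurtosis(dataset, Delta)
    print(f"{Delta * 1e3:>11.0f} {plateau:>9.3f} {D_mono:>15.3e} {K:>11.2f}")
print(
    "-> the apparent plateau decays and the apparent diffusion coefficient "
    "drifts with Delta; no single-Delta analysis returns the true fractions."
)
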