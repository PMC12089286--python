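"""Binding kinetics of a soluble complex from exchange-averaged diffusion.

A tightly bound 1:1 protein-RNA complex (94.5% bound at 150 uM each,
k_off = 1.41 /s) diffuses ~2.5x slower than the free species; because the
exchange happens on the diffusion-time scale, the decay curves are
exchange-averaged and a global two-pool fit can separate population from
kinetics.  The fitted bound fraction and off-rate combine with the known
totals into K_d and k_on -- no titration series needed.
"""

import numpy as np

import redifine as rd

truth = rd.BindingParams(D_free=1.0e-10, D_complex=4.0e-11, nu_complex=0.945, k_off=1.41)
scheme = rd.AcquisitionScheme(
    gradient_fractions=tuple(np.linspace(0.02, 0.95, 16)),
    diffusion_times=(0.05, 0.1, 0.2, 0.35, 0.5, 0.7),  # folded domains: <= 700 ms
    gradient_duration=9e-3,
)
dataset = rd.generate_dataset(truth, scheme)

totals = rd.MixtureTotals(150e-6, 150e-6)  # equimolar, 1:1 stoichiometry
result = rd.fit_binding(dataset, totals, rd.FitSpec(n_starts=20, random_seed=1))

print(f"chi = {result.chi:.3g}")
print(f"D_free     = {result.params.D_free:.3e} m^2/s")
print(f"D_complex  = {result.params.D_complex:.3e} m^2/s")
print(f"nu_complex = {result.params.nu_complex:.3f}")
print(f"k_off      = {result.params.k_off:.3f} /s")
bd = result.binding_derived
print(f"free concentrations: {bd['c1_free'] * 1e6:.2f} uM each")
print(f"K_d  = {bd['K_d'] * 1e9:.0f} nM")
print(f"k_on = {bd['k_on']:.3g} /(M s)")
print(
    "-> sub-micromolar affinity with a ~1.4 /s off-rate, i.e. complexes "
    "live for about 700 ms."
)
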