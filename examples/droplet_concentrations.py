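"""Per-phase concentrations from fitted fractions and known sample amounts.

Once the condensed fractions of both the solute (from its own decay
curves) and the solvent (from the water signal) are known, the absolute
concentration of the solute in each phase follows from the total amounts
loaded into the sample -- here a strongly partitioning protein where 90% of
the protein but only ~3% of the water sits inside the droplets.
"""

import redifine as rd

total_protein_moles = 200e-6 * 130e-6  # 200 uM in 130 ul
total_water_volume = 130e-6            # L
nu_cond_protein = 0.90                 # fitted from the protein signal
nu_cond_water = 0.0265                 # fitted from the water signal

c_cond, c_dil, fold = rd.phase_concentrations(
    total_protein_moles, nu_cond_protein, total_water_volume, nu_cond_water
)
print(f"condensed phase: {c_cond * 1e3:.1f} mM")
print(f"dilute phase:    {c_dil * 1e6:.1f} uM")
print(f"fold enrichment: {fold:.0f}x")
print(
    "-> millimolar protein inside the droplets against tens of micromolar "
    "outside, from one NMR measurement and the loaded amounts."
)
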