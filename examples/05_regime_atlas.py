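"""Regime atlas: how extracellular potassium reshapes network stability.

Prints the analytic boundary currents (firing onset FO, bistability BS,
runaway excitation RAE, depolarization block DB) over a range of Nernst
shifts, and the effect of halving the inhibitory coupling.  All
boundaries move to lower injected currents as extracellular potassium
rises — elevated potassium makes the network easier to destabilize —
and weakened inhibition lowers the effective DB threshold further.
"""

import numpy as np

import mnm

i_mass = mnm.build_mass(mnm.wb_spec(), np.linspace(0.0, 20.0, 5),
                        duration=1600.0, transient_ms=400.0)
e_mass = mnm.build_mass(mnm.sean_spec(), np.linspace(0.0, 20.0, 5),
                        duration=1600.0, transient_ms=400.0)

df = mnm.atlas(e_mass, i_mass, mode="dnuk", grid=np.linspace(0.0, 15.0, 4))
print(df[["dnu_k", "fo", "bs", "rae", "db_bare", "db_effective"]]
      .to_string(index=False, float_format=lambda v: f"{v:8.2f}"))

print("\neffect of halving the I→E coupling on the effective DB onset:")
for dnu in (0.0, 15.0):
    full = mnm.boundary_set(e_mass, i_mass, g_ie=0.04, dnu_k=dnu).db_effective
    half = mnm.boundary_set(e_mass, i_mass, g_ie=0.02, dnu_k=dnu).db_effective
    print(f"  dnu_K={dnu:4.1f} mV: {full:6.2f} -> {half:6.2f} uA/cm^2 "
          f"({100*(1-half/full):.1f}% lower)")
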