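"""Build the inhibitory mechanistic neural mass and check its fidelity.

Runs the full parametrization pipeline for the WB model on a coarse
nu_K grid (boundaries, maxima along the shifted DB line, polynomial
fits), then compares the mass functionals FR(Q) and V_m(Q) against ODE
time averages across the firing window.  The printed medians are the
relative errors of the mean-field reduction; a few percent means the
mass reproduces the neuron's averaged input-output map.
"""

import numpy as np

import mnm
from mnm.mass_builder import fidelity_report

wb = mnm.wb_spec()
i_mass = mnm.build_mass(wb, np.linspace(0.0, 20.0, 5),
                        duration=1600.0, transient_ms=400.0)
print("I-mass thresholds: i_th1 =", np.round(i_mass.th1_coeffs, 4),
      " i_th2 =", np.round(i_mass.th2_coeffs, 3))
th1, th2, m1, m2, m3 = i_mass.thresholds_and_maxima(0.0)
print(f"at dnu_K=0: firing window [{th1:.3f}, {th2:.3f}] uA/cm^2, "
      f"max FR {m1:.0f} Hz")

df, summary = fidelity_report(i_mass, wb, [0.0, 15.0], n_currents=8,
                              duration=1500.0, transient_ms=400.0)
print("median relative errors vs ODE means:",
      {k: f"{100*v:.1f}%" for k, v in summary.median.items()})
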