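"""Firing-onset and depolarization-block boundaries of the WB model.

Traces the two bifurcation boundaries ISS_F(nu_K) and ISS_DB(nu_K) by
locating where the largest eigenvalue of the fixed-point Jacobian crosses
zero, then fits a line to the onset boundary.  The fitted slope and
intercept re-derive the published parametrization of the inhibitory-mass
firing threshold (a ~ 0.014, b ~ 1.746).
"""

import numpy as np

import mnm

wb = mnm.wb_spec()
grid = wb.nu_k_hat + np.linspace(0.0, 20.0, 9)
curves = mnm.trace_boundaries(wb, grid)
print(f"{'nu_K':>7} {'ISS_F':>8} {'ISS_DB':>8}")
for nu, f, db in zip(curves.nu_k, curves.iss_f, curves.iss_db):
    print(f"{nu:7.1f} {f:8.4f} {db:8.3f}")
a, b = np.polyfit(curves.nu_k, curves.iss_f, 1)
print(f"\nlinear fit of the onset boundary: i_th1 = {a:.4f}*nu_K + {b:.3f}")
print("(currents in uA/cm^2; the window between the two boundaries is the "
      "firing regime)")
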