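"""Three dynamical regimes of the Wang-Buzsáki interneuron.

Simulates the membrane model at a subthreshold, a moderate and a very
strong injected current and prints the time-averaged outputs.  The three
regimes are distinguished by the mean potassium flux: negative at rest
(NF), positive while spiking (F), and strongly positive on the
depolarized plateau of depolarization block (DB), where the cell pumps
potassium into the extracellular space without firing.
"""

import mnm

wb = mnm.wb_spec()
print(f"{'I_inj':>7} {'<FR> Hz':>9} {'<Vm> mV':>9} {'<Kflux>':>9}  regime")
for i_inj in (0.2, 8.0, 30.0):
    trace = mnm.simulate(wb, i_inj, dnu_k=0.0, duration=1500.0)
    s = mnm.summarize(trace, transient_ms=500.0)
    print(f"{i_inj:7.1f} {s.mean_fr:9.1f} {s.mean_vm:9.2f} "
          f"{s.mean_kflux:9.2f}  {s.regime}")
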