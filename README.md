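# mnm — mechanistic neural masses

Classic neural-mass models convert synaptic input to a population firing
rate through an assumed sigmoid, which disconnects them from the membrane
physiology they are meant to summarize.  `mnm` builds *mechanistic* neural
masses instead: mean-field elements whose thresholds, firing-rate curve and
slow-variable couplings are parametrized directly from Hodgkin-Huxley-type
single-neuron models, so that depolarization block (DB) and sensitivity to
extracellular potassium are part of the mass itself.  It is written for
computational neuroscientists studying seizure-like transitions, runaway
excitation and spreading-depolarization-type instabilities at the network
scale.

Two canonical cell classes are built in:

- **I mass** — from the Wang-Buzsáki (WB) fast-spiking interneuron,
- **E mass** — from the SEAN model (the somatic compartment of the
  Pinsky-Rinzel pyramidal cell, with a frozen-gate accommodation current),

both extended with a Na/K-pump current
`I_pump = ρ / [(1 + e^{([N̂a]_i−[Na]_i)/3})(1 + e^{[K̂]_o−[K]_o})]` and a
potassium Nernst potential ν_K = ν̂_K + Δν_K that tracks the extracellular
bath, Δν_K = (RT/F)·ln([K]_o/[K̂]_o).

## Method

1. **Regimes.** Simulating a neuron over a grid of injected current I_inj
   and Δν_K splits the plane into not-firing (NF), firing (F) and
   depolarization block (DB), distinguished by the mean firing rate ⟨FR⟩,
   mean potential ⟨V_m⟩ and mean potassium flux ⟨K_flux⟩ (negative in NF,
   positive in DB).
2. **Boundaries.** With m instantaneous, fixed points are parametrized by
   V_m; the steady-state current ISS(V_m) and the eigenvalues of the
   reduced (V, n, h) Jacobian give the firing-onset and DB boundaries
   ISS_F(ν_K), ISS_DB(ν_K) as zero crossings of the largest eigenvalue.
3. **Maxima.** ⟨FR⟩, ⟨V_m⟩, ⟨K_flux⟩ are measured on a line shifted just
   inside the DB boundary (ISS_DB − Δ), avoiding the incomplete-spike
   layer, and fitted as low-order polynomials M1, M2, M3 of ν_K; the
   boundaries are fitted as lines i_th1(ν_K), i_th2(ν_K).
4. **Functionals.** For total input X and normalized current
   Q = (X − i_th1)/(i_th2 − i_th1), the mass outputs are
   FR = M1·Q^½, V_m = C1 − M2·Q^{p}, K_flux = M3·Q^{r} + C2
   (p, r = ½ for the I mass; 0.62, 0.28 for the E mass), with FR = 0 and
   stable-fixed-point closures outside 0 ≤ Q ≤ 1.
5. **Network.** Two masses couple through unit-DC-gain alpha synapses
   (ḧ = (F−h)/τ² − 2ḣ/τ) in Wilson-Cowan-type rate equations
   ḞR = (Φ(I_tot) − FR)/λ.  The couplet shows NF, balanced firing,
   runaway excitation (the I mass in DB), network DB and hysteresis, and
   all transition currents can be written down analytically from the mass
   coefficients (the regime atlas).

## Worked example

`examples/02_boundaries_and_threshold_fit.py` traces the WB model's
bifurcation boundaries and fits the onset line:

```
   nu_K    ISS_F   ISS_DB
  -90.0   0.4726   25.442
  -87.5   0.5400   23.330
  -85.0   0.6059   21.223
  -82.5   0.6620   19.112
  -80.0   0.7029   16.993
  -77.5   0.7283   14.864
  -75.0   0.7414   12.731
  -72.5   0.7462   10.597
  -70.0   0.7463    8.466

linear fit of the onset boundary: i_th1 = 0.0137*nu_K + 1.754
```

At the nominal Nernst potential (ν_K = −90 mV) the interneuron fires for
injected currents between ≈0.47 and ≈25.4 μA/cm²; raising extracellular
potassium (ν_K toward −70 mV) narrows that window — DB arrives at ever
lower currents.  The fitted line is the I-mass firing threshold used by
the network layer.  The other examples build the masses
(`03`, printing fidelity medians of a few percent against the ODE
models), run the hysteretic ramp of the coupled network (`04`), and print
the regime atlas and its potassium/coupling sensitivity (`05`).

The `mnm` command exposes the same pipeline from the shell
(`mnm sweep`, `mnm boundaries`, `mnm parametrize`, `mnm fidelity`,
`mnm simulate-net`, `mnm hysteresis`, `mnm atlas`, `mnm fixtures`).

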