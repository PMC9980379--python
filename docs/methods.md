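# Methods

This note documents the models, parameter provenance, numerical choices
and limitations of the `mnm` package.  Units throughout: mV, ms, μA/cm²,
mS/cm², μF/cm², mM; RT/F = 26.64 mV.

## Membrane models

Both neuron models have the form

    C_m dV/dt = I_inj − G_K(V − ν_K) − G_Na(V − ν_Na) − G_L(V − ν_l)
                − I_pump [− I_K-AHP],

with m instantaneous (m = m_∞(V)) and first-order kinetics for n and h.
The pump current is a product of logistic saturations in [Na]_i and
[K]_o with strength ρ = 1.25 μA/cm²; intracellular concentrations are
held constant, so a potassium Nernst shift Δν_K is carried entirely by
[K]_o = [K̂]_o·e^{Δν_K/26.64}.

**WB (I-mass source).**  Canonical Wang-Buzsáki interneuron: C_m = 1,
g_Na = 35, g_K = 9, g_L = 0.1, ν̂_K = −90, ν_Na = 55, ν_l = −65, gating
rate scale ψ = 5, I_K = g_K n⁴(V−ν_K), I_Na = g_Na m_∞³h(V−ν_Na).
Nominal [K̂]_o = 140·e^{−90/26.64} ≈ 4.77 mM.

**SEAN (E-mass source).**  Somatic compartment of the Pinsky-Rinzel
pyramidal model, shifted by −60 mV to absolute potential: C_m = 3,
g_Na = 30, g_K = 15, g_L = 0.1, ν̂_K = −75, ν_Na = 60, ν_l = −60,
I_Na = g_Na m_∞²h(V−ν_Na), I_K-DR = g_K n(V−ν_K) (the canonical
Pinsky-Rinzel current forms), plus an accommodation current
I_K-AHP = g_K-AHP·q̂·(V−ν_K) with g_K-AHP = 0.8 and the calcium-gated
gate frozen at q̂ = q_∞(Ca = 0.2) ≈ 0.004 (fast/slow split: the slow,
calcium-tracking part of the accommodation current is exposed as an
additive input-current hook `i_extra` rather than simulated).  Nominal
[K̂]_o ≈ 8.38 mM.  With q̂ this small the fast dynamics carry essentially
no accommodation; see Limitations.

**Potassium flux.**  K_flux = G_K(V−ν_K) + I_K-AHP − 2·I_pump.  The
factor 2 reflects the 3Na/2K pump stoichiometry with the pump current
normalized per net transferred charge; it makes the resting (NF) flux
negative and the DB plateau flux positive, which is the signature used to
label regimes.

## Fixed points and boundaries

Fixed points are parametrized by V: the gates sit at their steady values
and ISS(V) is the current balancing the membrane there.  Stability comes
from the analytic 3×3 Jacobian of (V, n, h) (checked against central
finite differences to 1e-6 relative).  Scanning V ∈ [−100, 20] mV at
0.25 mV and bisecting sign changes of the largest eigenvalue real part to
|ΔV| < 1e-4 mV yields the onset (lower-current) and DB (higher-current)
crossings; mapping through ISS gives ISS_F(ν_K) and ISS_DB(ν_K).  Rows
with fewer than two crossings (closed firing window, the bistable
upper-triangle regime) are reported absent.

## Parametrization window and the shift Δ

The masses are fitted over Δν_K ∈ [0, 20] mV (9-point grid in the
shipped pipeline).  This window was chosen because the linear fit to the
WB onset boundary over it reproduces the published threshold
coefficients (slope 0.0137 vs 0.014, intercept 1.75 vs 1.746); fitting
over a wider window degrades the linearity of ISS_F and the agreement.

Mean outputs are measured at ISS_DB − Δ.  Both models stop producing
full (0 mV-crossing) action potentials in a thin layer below ISS_DB
(8–19% of the firing window at the grid points probed), so a fixed small
Δ can land on a silent point.  Δ is therefore chosen adaptively per ν_K
row: probe simulations step inward from the DB boundary in 4%-of-window
increments until at least five full spikes appear, and the measurement
point is placed one further step inside.  An explicit float Δ is also
accepted.

**Amplitude convention.**  The measured means sit at
Q_meas = 1 − Δ/window < 1 while the functionals treat M1..M3 as Q = 1
amplitudes, so measurements are divided by Q_meas^p before the ν_K fits.
The functional then interpolates every measured anchor exactly,
independent of Δ.  Fit orders: thresholds linear for both masses; M1
cubic / M2 quadratic / M3 linear (I mass); M1 quadratic / M2 quadratic /
M3 cubic (E mass).  Offsets C1 = −60 (I) / −65 (E) mV and
C2 = 0.1 μA/cm² (E only); exponents (½, ½, ½) for I and (½, 0.62, 0.28)
for E.

Outside the firing window the mass is silent and V_m / K_flux are taken
from the stable fixed point of the source neuron at the same total
current (hyperpolarized branch for NF, depolarized for DB), located by
exact root-finding with an LRU cache.

**Input convention.**  For an isolated mass the total current is the
injected current itself (the thresholds are ISS values, which already
contain the pump).  In the network equations the pump term appears
explicitly in the total current, as the coupled formulation is usually
written; at network current scales (tens of μA/cm²) the ≈0.3 μA/cm²
difference between the conventions is negligible.

## Synapses and the network

Alpha-function synapses are integrated as the critically damped system
ḧ = (F−h)/τ² − 2ḣ/τ (unit DC gain: steady h equals the presynaptic
rate), with τ_E = 10 ms (pyramidal) and τ_I = 20 ms (slow GABA_B, the
default inhibition; fast 2 ms GABA_A is available in `SynapseSpec` but
unused by default).  The couplet uses zero delays; delayed reads
(ring-buffer interpolation) are supported for larger networks.

The rate equations relax toward the mass FR functional with
λ_E = λ_I = 1 ms; nominal couplings ĝ_EI = 0.2 and ĝ_IE = 0.04 μA/cm²
per Hz; no external drive to the I mass.  Firing rates are in Hz.
Integration is fixed-step RK4 at dt = 0.05 ms, deterministic and
seedless; the mass functionals are algebraic so the system is only
mildly stiff.  Regime labels: NF (E silent, Q_E < 0), F (both firing),
RAE (E firing, I in DB: Q_I > 1), DB (E silent, Q_E > 1); "silent" means
FR < 0.5 Hz sustained for 50 ms.

## Regime atlas

The boundary chain works in absolute currents: the I mass enters DB when
its total current reaches i_th2^I, which requires
FR_E* = (i_th2^I − I_pump^I − I_I,inj)/g_EI; inverting the E functional
gives Q_E* = (FR_E*/M1^E)² and
I_RAE = i_th1^E + Q_E*(i_th2^E − i_th1^E) − I_pump^E + g_IE·M1^I.
(The alternative normalized-current reading of this chain is retained
behind `literal_q=True` for comparison; the absolute-current chain is the
one that matches the slow-ramp simulations, to within 2% at the spot
checks tested.)  I_BS = I_RAE − g_IE·M1^I; the bare E-mass DB onset is
i_th2^E − I_pump^E.  The *effective* DB onset applies the crossing rule
min(bare, I_RAE): past I_RAE the network leaves normal or bistable
operation for the pathological branch, so where the RAE boundary
undercuts the bare DB line the DB boundary is shifted onto it.  Both
values are reported; note that on a rising ramp the excitatory mass's
own collapse is observed at max(bare, I_RAE), since in the RAE regime
inhibition is already gone.

## Problem sizes

The shipped pipeline uses: 50-point ν_K grids for boundary fits, 9-point
Δν_K grids for mass construction, 2.5 s membrane simulations (0.5 s
transient discarded; adaptive-Δ probes use 0.8 s), 20 currents × 3
potassium levels per mass for fidelity, and 16 s network ramps.  The
test suite uses 5-point grids and 1.6 s simulations.

## Numerics

- Membrane integration: compiled fixed-step RK4 at dt = 0.01 ms with
  gate clamping to [0, 1].  Mean outputs are unchanged (FR to the spike,
  ⟨V_m⟩ to <0.01 mV) under dt halving to 0.0025 ms and against LSODA at
  rtol 1e-8 / atol 1e-10 / max step 0.1 ms, which remains available as
  `method="lsoda"`.
- Spike detection: upward crossing of 0 mV with a 2 ms lockout — full
  action potentials only; the incomplete spikes near DB are deliberately
  not counted (they are unlikely to drive synaptic release).
- Averages over the post-transient window use trapezoidal quadrature.
- Removable singularities of the x/(1−e^{−x/b}) rate forms are evaluated
  by series expansion for |x/b| < 1e-6.
- Polynomial fits refuse Vandermonde condition numbers above 1e10.
- Boundary tracing, fits and the network are fully deterministic; the
  only stochastic hook is an optional seeded ±0.5 mV jitter of the
  initial membrane potential.

## What the pipeline does and does not show

All quantitative checks run against the package's own ODE neuron models
under the stated canonical parameters — there is no recorded data in the
loop.  Passing tests therefore show that the mean-field reduction is
faithful to those membrane models (fidelity medians of a few percent for
FR and V_m) and that the coupled network's simulated transitions agree
with the algebraic boundary theory (≈2%); they do not show that the WB
or SEAN models themselves capture any particular biological tissue.
Published anchor values are re-derived, not imported: the onset-fit
coefficients land within a few percent of the printed ones, while
absolute DB-transition currents of the excitatory mass come out ≈13%
higher than the published figure-level values, consistent with the
parameter sets differing in details we re-derived from the canonical
literature (see Limitations).

## Limitations

- The exact coefficient tables of the original parametrization are not
  public; canonical WB and Pinsky-Rinzel values are used with the stated
  overrides.  Absolute E-mass DB currents inherit a ≈10–15% offset.
- With q̂ = q_∞(Ca = 0.2) the fast accommodation conductance is ≈0.003
  mS/cm², i.e. the parametrized E mass barely accommodates; the slow
  accommodation pathway exists only as the additive-current hook.  A
  larger frozen calcium level would lower the SEAN DB threshold
  noticeably (≈10 μA/cm² at q̂ ≈ 0.29).
- Type-2 onset, burst firing, sodium dynamics, potassium diffusion,
  glial buffering and cell swelling are out of scope; only the two-mass
  couplet is validated, though the synapse list supports N masses.
- The E-mass firing rates far exceed real pyramidal rates, a known
  property of the soma-only reduction.
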