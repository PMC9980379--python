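"""Membrane-model integration and reduction to time-averaged outputs.

This module turns a :class:`~mnm.specs.NeuronModelSpec` into voltage traces
and reduces them to the three quantities that characterize a mechanistic
neural mass: mean firing rate ⟨FR⟩, mean membrane potential ⟨V_m⟩ and mean
transmembrane potassium flux ⟨K_flux⟩, over grids of injected current and
potassium Nernst-potential shift Δν_K.

The potassium flux bookkeeping is

    K_flux(t) = G_K(V)·(V − ν_K) + I_K-AHP − 2·I_pump,

i.e. the delayed-rectifier and accommodation currents carry K⁺ outward
while the pump imports two K⁺ per cycle (3Na/2K stoichiometry, pump
current normalized per net charge).  With this convention the not-firing
(NF) regime has negative mean flux, the depolarization-block (DB) regime a
strictly positive one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .specs import NeuronModelSpec

__all__ = [
    "MembraneState",
    "Trace",
    "TraceSummary",
    "rate_functions",
    "rate_derivatives",
    "gate_steady_states",
    "pump_current",
    "k_o_at_shift",
    "derivatives",
    "k_flux",
    "simulate",
    "summarize",
    "count_spikes",
    "sweep",
]


@dataclass
class MembraneState:
    """Instantaneous membrane state (m is instantaneous: m = m_inf(V))."""

    v_m: float
    n: float
    h: float

    def as_array(self) -> np.ndarray:
        return np.array([self.v_m, self.n, self.h], dtype=float)


# ---------------------------------------------------------------------------
# rate functions and algebraic currents
# ---------------------------------------------------------------------------

def _eval_rate(coeff, v):
    x = coeff.sign * (np.asarray(v, dtype=float) + coeff.v_half)
    b = coeff.b
    if coeff.form == "linexp":
        u = x / b
        small = np.abs(u) < 1e-6
        with np.errstate(over="ignore"):
            safe = np.where(small, 1.0, u)
            val = coeff.a * x / (1.0 - np.exp(-np.where(small, 1.0, u)))
            lim = coeff.a * b * (1.0 + 0.5 * u + u * u / 12.0)
        del safe
        return np.where(small, lim, val)
    if coeff.form == "exp":
        with np.errstate(over="ignore"):
            return coeff.a * np.exp(x / b)
    # logistic
    with np.errstate(over="ignore"):
        return coeff.a / (1.0 + np.exp(-x / b))


def _eval_rate_derivative(coeff, v):
    """d(rate)/dV, analytic."""
    x = coeff.sign * (np.asarray(v, dtype=float) + coeff.v_half)
    b = coeff.b
    if coeff.form == "linexp":
        u = x / b
        small = np.abs(u) < 1e-6
        with np.errstate(over="ignore"):
            e = np.exp(-np.where(small, 1.0, u))
            g = (1.0 - e - np.where(small, 1.0, u) * e) / (1.0 - e) ** 2
        lim = 0.5 + u / 6.0 - u ** 3 / 180.0
        return coeff.sign * coeff.a * np.where(small, lim, g)
    if coeff.form == "exp":
        return coeff.sign * _eval_rate(coeff, v) / b
    p = _eval_rate(coeff, v) / coeff.a
    return coeff.sign * coeff.a * p * (1.0 - p) / b


def rate_functions(spec: NeuronModelSpec, v_m: float):
    """The six gating rates (α_m, β_m, α_n, β_n, α_h, β_h) in 1/ms.

    Removable singularities of the linexp form are evaluated by their
    analytic limit.  Raises a model-parameter error naming the offending
    coefficient if a rate comes out non-finite.
    """
    if not np.all(np.isfinite(v_m)):
        raise ValueError("V_m must be finite")
    vals = tuple(_eval_rate(c, v_m) for c in spec.rates)
    for name, v in zip(spec.rate_names, vals):
        if not np.all(np.isfinite(v)):
            raise ValueError(f"rate function {name} evaluated non-finite at V_m={v_m}")
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"rate function {name} evaluated negative at V_m={v_m}")
    return vals


def rate_derivatives(spec: NeuronModelSpec, v_m: float):
    """Analytic d/dV of the six gating rates (used by the Jacobian)."""
    return tuple(_eval_rate_derivative(c, v_m) for c in spec.rates)


def gate_steady_states(spec: NeuronModelSpec, v_m: float):
    """(n_inf, m_inf, h_inf) at membrane potential ``v_m``."""
    am, bm, an, bn, ah, bh = rate_functions(spec, v_m)
    return an / (an + bn), am / (am + bm), ah / (ah + bh)


def pump_current(spec: NeuronModelSpec, na_i: float, k_o: float) -> float:
    """Na/K-pump current (μA/cm²), a product of logistic saturations.

    Strictly positive and monotonically increasing in both [Na]_i and
    [K]_o; equals ρ/4 at the nominal concentrations.
    """
    na_i = np.asarray(na_i, dtype=float)
    k_o = np.asarray(k_o, dtype=float)
    if np.any(na_i <= 0) or np.any(k_o <= 0):
        raise ValueError("ion concentrations must be positive")
    with np.errstate(over="ignore"):
        out = spec.rho / ((1.0 + np.exp((spec.na_i_hat - na_i) / 3.0))
                          * (1.0 + np.exp(spec.k_o_hat - k_o)))
    return float(out) if out.ndim == 0 else out


def k_o_at_shift(spec: NeuronModelSpec, dnu_k: float) -> float:
    """[K]_o implied by a Nernst shift Δν_K at constant [K]_i."""
    return spec.k_o_hat * math.exp(dnu_k / spec.rt_over_f)


def pump_at_shift(spec: NeuronModelSpec, dnu_k: float) -> float:
    """Pump current with [Na]_i nominal and [K]_o set by Δν_K."""
    return pump_current(spec, spec.na_i_hat, k_o_at_shift(spec, dnu_k))


def derivatives(spec: NeuronModelSpec, state: MembraneState,
                i_inj: float, dnu_k: float, i_extra: float = 0.0) -> np.ndarray:
    """Time derivatives (dV/dt, dn/dt, dh/dt) of the membrane model.

    ``i_extra`` is the additive slow-current hook (e.g. the slow
    accommodation correction I_K-AHP,slow for the SEAN model, which is not
    part of the fast parametrized dynamics).
    """
    nu_k = spec.nu_k_hat + dnu_k
    i_pump = pump_at_shift(spec, dnu_k)
    args = _kernels.model_params(spec, i_inj, nu_k, i_pump, i_extra)
    d = _kernels._membrane_deriv(state.as_array(), _kernels.rate_table(spec), *args)
    if not np.all(np.isfinite(d)):
        raise FloatingPointError(
            f"non-finite derivative at V_m={state.v_m} (I_inj={i_inj}, dnu_k={dnu_k})")
    return d


def k_flux(spec: NeuronModelSpec, v_m, n, dnu_k: float):
    """Instantaneous net transmembrane potassium current (μA/cm²)."""
    nu_k = spec.nu_k_hat + dnu_k
    i_pump = pump_at_shift(spec, dnu_k)
    return (spec.g_k * np.asarray(n) ** spec.k_power * (np.asarray(v_m) - nu_k)
            + spec.g_k_ahp * spec.q_hat * (np.asarray(v_m) - nu_k)
            - 2.0 * i_pump)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """Dense output of one membrane simulation."""

    t: np.ndarray          # ms
    v_m: np.ndarray
    n: np.ndarray
    h: np.ndarray
    k_flux: np.ndarray
    i_inj: float
    dnu_k: float
    spec: NeuronModelSpec = field(repr=False)


def _initial_state(spec: NeuronModelSpec, v0: float | None, seed) -> np.ndarray:
    if v0 is None:
        v0 = -65.0
    if seed is not None:
        v0 = v0 + np.random.default_rng(seed).uniform(-0.5, 0.5)
    n0, _, h0 = gate_steady_states(spec, v0)
    return np.array([v0, float(n0), float(h0)])


def simulate(spec: NeuronModelSpec, i_inj: float, dnu_k: float,
             duration: float = 2500.0, dt_out: float = 0.05,
             seed=None, v0: float | None = None, i_extra: float = 0.0,
             method: str = "rk4", dt: float = 0.01) -> Trace:
    """Integrate the membrane ODEs and return dense traces.

    The production path is a compiled fixed-step RK4 at ``dt`` = 0.01 ms
    (mean outputs are converged at this step; see the methods note);
    ``method="lsoda"`` switches to the adaptive stiff solver at
    rtol 1e-8 / atol 1e-10 / max step 0.1 ms for cross-checking.
    """
    nu_k = spec.nu_k_hat + dnu_k
    i_pump = pump_at_shift(spec, dnu_k)
    args = _kernels.model_params(spec, i_inj, nu_k, i_pump, i_extra)
    tab = _kernels.rate_table(spec)
    y0 = _initial_state(spec, v0, seed)

    if method == "rk4":
        stride = max(1, round(dt_out / dt))
        n_steps = int(round(duration / dt))
        n_steps -= n_steps % stride
        out = _kernels._rk4_membrane(y0, tab, *args, dt, n_steps, stride)
        t = np.arange(out.shape[0]) * (stride * dt)
        v, n, h = out[:, 0], out[:, 1], out[:, 2]
    elif method == "lsoda":
        def fun(t, y):
            return _kernels._membrane_deriv(np.asarray(y), tab, *args)
        t = np.arange(0.0, duration + 0.5 * dt_out, dt_out)
        sol = solve_ivp(fun, (0.0, t[-1]), y0, method="LSODA",
                        rtol=1e-8, atol=1e-10, max_step=0.1, t_eval=t)
        if sol.status != 0:
            sol = solve_ivp(fun, (0.0, t[-1]), y0, method="LSODA",
                            rtol=1e-8, atol=1e-10, max_step=0.02, t_eval=t)
        if sol.status != 0:
            raise RuntimeError(
                f"stiff solver failed at (I_inj={i_inj}, dnu_k={dnu_k}): {sol.message}")
        v, n, h = sol.y
    else:
        raise ValueError(f"unknown method {method!r}")

    if not np.all(np.isfinite(v)):
        raise RuntimeError(
            f"integration produced non-finite V_m at (I_inj={i_inj}, dnu_k={dnu_k})")
    return Trace(t=t, v_m=v, n=n, h=h,
                 k_flux=np.asarray(k_flux(spec, v, n, dnu_k)),
                 i_inj=i_inj, dnu_k=dnu_k, spec=spec)


# ---------------------------------------------------------------------------
# reduction
# ---------------------------------------------------------------------------

@dataclass
class TraceSummary:
    """Time-averaged outputs of one simulation at one (I_inj, Δν_K)."""

    i_inj: float
    dnu_k: float
    mean_fr: float         # Hz
    mean_vm: float         # mV
    mean_kflux: float      # μA/cm²
    regime: str            # 'NF' | 'F' | 'DB'
    n_spikes: int
    window_ms: float
    fr_warning: bool = False


def count_spikes(t: np.ndarray, v: np.ndarray, threshold: float = 0.0,
                 lockout_ms: float = 2.0) -> np.ndarray:
    """Spike times: upward threshold crossings with a refractory lockout."""
    idx = np.where((v[:-1] < threshold) & (v[1:] >= threshold))[0]
    times = t[idx + 1]
    if len(times) == 0:
        return times
    keep = [times[0]]
    for ti in times[1:]:
        if ti - keep[-1] >= lockout_ms:
            keep.append(ti)
    return np.array(keep)


# DB/NF separators for the regime label (μA/cm² and mV).
_FLUX_TOL = 0.5
_VM_SEPARATOR = -50.0


def summarize(trace: Trace, transient_ms: float = 500.0,
              spike_threshold: float = 0.0, lockout_ms: float = 2.0) -> TraceSummary:
    """Reduce a trace to ⟨FR⟩, ⟨V_m⟩, ⟨K_flux⟩ over the post-transient window.

    Regime label: F if any full spikes occur; otherwise DB when the mean
    potassium flux is clearly positive and the membrane sits depolarized
    (plateau), else NF.
    """
    mask = trace.t >= transient_ms
    if mask.sum() < 2:
        raise ValueError("trace shorter than the transient")
    t, v = trace.t[mask], trace.v_m[mask]
    window = t[-1] - t[0]
    spikes = count_spikes(t, v, spike_threshold, lockout_ms)
    mean_vm = float(np.trapezoid(v, t) / window)
    mean_kflux = float(np.trapezoid(trace.k_flux[mask], t) / window)
    fr = len(spikes) / (window / 1000.0)
    warn = False
    if len(spikes) in (1, 2, 3):
        warn = True   # averaging window shorter than ~2 inter-spike intervals
    if len(spikes) > 0:
        regime = "F"
    elif mean_kflux > _FLUX_TOL and mean_vm > _VM_SEPARATOR:
        regime = "DB"
    else:
        regime = "NF"
    return TraceSummary(i_inj=trace.i_inj, dnu_k=trace.dnu_k,
                        mean_fr=fr if regime == "F" else 0.0,
                        mean_vm=mean_vm, mean_kflux=mean_kflux,
                        regime=regime, n_spikes=len(spikes),
                        window_ms=window, fr_warning=warn)


def sweep(spec: NeuronModelSpec, i_inj_grid, dnu_k_grid,
          duration: float = 2500.0, transient_ms: float = 500.0,
          dt_out: float = 0.05, seed=None, progress: bool = False):
    """Grid of TraceSummary over (I_inj, Δν_K); returns a tidy DataFrame.

    Columns: i_inj, dnu_k, mean_fr, mean_vm, mean_kflux, regime, n_spikes.
    Individual point failures are recorded with regime='error', not fatal.
    """
    import pandas as pd

    rows = []
    for dnu in np.asarray(dnu_k_grid, dtype=float):
        for i in np.asarray(i_inj_grid, dtype=float):
            try:
                tr = simulate(spec, i, dnu, duration=duration,
                              dt_out=dt_out, seed=seed)
                s = summarize(tr, transient_ms=transient_ms)
                rows.append(dict(i_inj=i, dnu_k=dnu, mean_fr=s.mean_fr,
                                 mean_vm=s.mean_vm, mean_kflux=s.mean_kflux,
                                 regime=s.regime, n_spikes=s.n_spikes))
            except (RuntimeError, FloatingPointError) as exc:  # pragma: no cover
                warnings.warn(f"sweep point (I={i}, dnu={dnu}) failed: {exc}")
                rows.append(dict(i_inj=i, dnu_k=dnu, mean_fr=np.nan,
                                 mean_vm=np.nan, mean_kflux=np.nan,
                                 regime="error", n_spikes=0))
    return pd.DataFrame(rows)
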