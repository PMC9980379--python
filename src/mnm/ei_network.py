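"""The coupled excitatory-inhibitory mass network (firing-rate ODEs).

Two mechanistic masses sharing one extracellular potassium bath are
coupled through alpha-function synapses:

    dFR_E/dt = (Φ_E(I_E(t)) − FR_E)/λ_E,
    dFR_I/dt = (Φ_I(I_I(t)) − FR_I)/λ_I,
    I_E(t) = I_E,inj(t) + I_E,pump − g_IE·h_I(t − D_IE),
    I_I(t) = I_I,inj    + I_I,pump + g_EI·h_E(t − D_EI),

where Φ is the mass firing-rate functional (M1·√Q inside the firing
window, 0 in NF and DB — the discontinuous DB target smoothed by λ) and
each h obeys the critically damped alpha-synapse ODE driven by the
instantaneous firing rate of its source mass.  Fixed-step RK4, compiled;
deterministic and seedless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import _integrate_couplet
from .mass_core import MassParametrization
from .synapse import SynapseSpec

__all__ = [
    "NetworkConfig",
    "StimulusProtocol",
    "NetworkState",
    "integrate_network",
    "classify_regime",
    "hysteresis_scan",
    "HysteresisResult",
]

#: Nominal coupling constants (μA/cm² per Hz).
G_EI_NOMINAL = 0.2
G_IE_NOMINAL = 0.04


@dataclass
class NetworkConfig:
    """Couplet configuration: two masses, two synapses, one bath."""

    e_param: MassParametrization
    i_param: MassParametrization
    lam_e: float = 1.0                 # FR relaxation time constants, ms
    lam_i: float = 1.0
    syn_ei: SynapseSpec = field(default_factory=lambda: SynapseSpec(
        tau=10.0, g=G_EI_NOMINAL, sign=+1))   # E→I, pyramidal kernel
    syn_ie: SynapseSpec = field(default_factory=lambda: SynapseSpec(
        tau=20.0, g=G_IE_NOMINAL, sign=-1))   # I→E, slow (GABA_B) kernel
    dnu_k: float = 0.0                 # shared bath shift, mV
    i_i_inj: float = 0.0               # external drive to the I mass

    def __post_init__(self):
        if self.lam_e <= 0 or self.lam_i <= 0:
            raise ValueError("relaxation time constants must be positive")
        if self.e_param.mass_kind != "E" or self.i_param.mass_kind != "I":
            raise ValueError("e_param must be an E mass and i_param an I mass")
        if self.syn_ei.sign != +1 or self.syn_ie.sign != -1:
            raise ValueError("E→I synapse must be excitatory (+1), I→E inhibitory (-1)")


@dataclass
class NetworkState:
    """Instantaneous network state."""

    t: float
    fr_e: float
    fr_i: float
    h_e: float
    h_i: float
    q_e: float
    q_i: float


@dataclass
class StimulusProtocol:
    """Piecewise-linear injected-current waveform for the E mass.

    kinds:
      ``constant``       — amplitude ``peak`` throughout,
      ``symmetric_ramp`` — 0 → peak → 0 triangle over ``duration``,
      ``pulse_train``    — pulses with linear ramp fronts of
                           ``ramp_ms``, duty cycle ``duty`` and period
                           ``period_ms``, amplitudes increasing linearly to
                           ``peak`` over the train.
    """

    kind: str
    peak: float
    duration: float
    ramp_ms: float = 250.0
    duty: float = 0.75
    period_ms: float = 2000.0

    def waveform(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            return np.full_like(t, self.peak)
        if self.kind == "symmetric_ramp":
            half = self.duration / 2.0
            up = self.peak * t / half
            down = self.peak * (self.duration - t) / half
            return np.clip(np.minimum(up, down), 0.0, None)
        if self.kind == "pulse_train":
            n_pulses = max(1, int(np.floor(self.duration / self.period_ms)))
            phase = np.mod(t, self.period_ms)
            k = np.floor(t / self.period_ms)
            amp = self.peak * (k + 1) / n_pulses
            on = self.duty * self.period_ms
            env = np.where(phase < self.ramp_ms, phase / self.ramp_ms,
                           np.where(phase < on, 1.0, 0.0))
            return amp * env
        raise ValueError(f"unknown stimulus kind {self.kind!r}")


def integrate_network(config: NetworkConfig, protocol: StimulusProtocol,
                      duration: float | None = None, dt: float = 0.05,
                      dt_out: float = 0.25, y0=None) -> pd.DataFrame:
    """Integrate the couplet; returns a trajectory DataFrame.

    Columns: t, i_e_inj, fr_e, fr_i, h_e, h_i, q_e, q_i.
    """
    if duration is None:
        duration = protocol.duration
    if dt > min(config.lam_e, config.lam_i, config.syn_ei.tau,
                config.syn_ie.tau) / 10.0:
        raise ValueError("dt must be at most a tenth of the fastest time constant")
    dnu = config.dnu_k
    th1_e, th2_e, m1_e, *_ = config.e_param.thresholds_and_maxima(
        dnu, warn_extrapolation=False)
    th1_i, th2_i, m1_i, *_ = config.i_param.thresholds_and_maxima(
        dnu, warn_extrapolation=False)
    pump_e = config.e_param.pump_current(dnu)
    pump_i = config.i_param.pump_current(dnu)

    out_stride = max(1, round(dt_out / dt))
    n_steps = int(round(duration / dt))
    n_steps -= n_steps % out_stride
    t_half = np.arange(2 * n_steps + 1) * (dt / 2.0)
    stim_half = np.ascontiguousarray(protocol.waveform(t_half))

    y0 = np.zeros(6) if y0 is None else np.asarray(y0, dtype=float)
    d_ie = round(config.syn_ie.delay / dt)
    d_ei = round(config.syn_ei.delay / dt)

    fr_e, fr_i, h_e, h_i, q_e, q_i, stim = _integrate_couplet(
        stim_half, config.i_i_inj, dt, n_steps,
        th1_e, th2_e, m1_e, th1_i, th2_i, m1_i,
        pump_e, pump_i, config.syn_ei.g, config.syn_ie.g,
        config.lam_e, config.lam_i, config.syn_ei.tau, config.syn_ie.tau,
        d_ie, d_ei, y0, out_stride)
    if not np.all(np.isfinite(fr_e)):
        raise RuntimeError("network integration produced non-finite state")
    t = np.arange(len(fr_e)) * (out_stride * dt)
    return pd.DataFrame(dict(t=t, i_e_inj=stim, fr_e=fr_e, fr_i=fr_i,
                             h_e=h_e, h_i=h_i, q_e=q_e, q_i=q_i))


# ---------------------------------------------------------------------------
# regime classification
# ---------------------------------------------------------------------------

_FR_ZERO = 0.5          # Hz: "silent" threshold
_SUSTAIN_MS = 50.0      # silence must persist this long


def classify_regime(window: pd.DataFrame) -> str:
    """Label a (steady-state) trajectory window as NF / F / RAE / DB.

    NF: E silent with subthreshold drive (Q_E < 0).  F: both masses fire.
    RAE: E fires while the I mass sits in DB (Q_I > 1).  DB: E silent with
    suprathreshold drive (Q_E > 1).  An oscillatory window is labelled by
    its cycle-averaged quantities (with a warning).
    """
    fr_e = window.fr_e.to_numpy()
    fr_i = window.fr_i.to_numpy()
    q_e = window.q_e.to_numpy()
    q_i = window.q_i.to_numpy()
    t = window.t.to_numpy()
    if len(t) > 2:
        tail = window[t > t[-1] - (t[-1] - t[0]) / 3]
        if tail.fr_e.std() > 0.05 * max(tail.fr_e.mean(), 1.0):
            warnings.warn("window not at steady state; labelling by averages")
    e_silent = fr_e.mean() < _FR_ZERO
    if e_silent and q_e.mean() < 0:
        return "NF"
    if e_silent and q_e.mean() > 1:
        return "DB"
    if q_i.mean() > 1 and fr_i.mean() < _FR_ZERO:
        return "RAE"
    return "F"


# ---------------------------------------------------------------------------
# hysteresis
# ---------------------------------------------------------------------------

@dataclass
class HysteresisResult:
    """Transition currents detected on the two phases of a symmetric ramp."""

    i_rae_up: float       # I-mass DB entry, rising phase (RAE onset)
    i_rae_down: float     # I-mass DB exit, falling phase
    i_db_up: float        # E-mass DB entry, rising phase
    i_db_down: float      # E-mass DB exit, falling phase
    bistable: tuple       # (down-transition, up-transition) of the I mass
    trajectory: pd.DataFrame = field(repr=False, default=None)

    @property
    def bistable_width(self) -> float:
        lo, hi = self.bistable
        return hi - lo if np.isfinite(hi) and np.isfinite(lo) else np.nan


def _sustained_first(t, mask, sustain_ms):
    """First index where ``mask`` holds continuously for ``sustain_ms``."""
    if not mask.any():
        return None
    idx = np.where(mask)[0]
    runs = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
    for run in runs:
        if t[run[-1]] - t[run[0]] >= sustain_ms or run[-1] == len(t) - 1:
            return run[0]
    return None


def hysteresis_scan(config: NetworkConfig, peak: float,
                    ramp_duration: float = 16000.0, dt: float = 0.05,
                    dt_out: float = 0.25) -> HysteresisResult:
    """Slow symmetric ramp 0 → peak → 0; detect DB entries and exits.

    The ramp must be quasi-static (slow against λ and τ); transition
    currents converge as the ramp rate → 0.  The bistable interval is
    [I-mass DB exit (down), I-mass DB entry (up)].
    """
    protocol = StimulusProtocol("symmetric_ramp", peak=peak, duration=ramp_duration)
    df = integrate_network(config, protocol, dt=dt, dt_out=dt_out)
    t = df.t.to_numpy()
    i_inj = df.i_e_inj.to_numpy()
    rising = t <= ramp_duration / 2.0
    falling = ~rising

    def first_current(phase, mask, sustain=2.0):
        tt = t[phase]
        ii = i_inj[phase]
        k = _sustained_first(tt, mask[phase], sustain)
        return float(ii[k]) if k is not None else np.nan

    i_db_mask = df.q_i.to_numpy() > 1.0
    e_db_mask = (df.q_e.to_numpy() > 1.0) & (df.fr_e.to_numpy() < _FR_ZERO)

    i_rae_up = first_current(rising, i_db_mask)
    i_db_up = first_current(rising, e_db_mask, sustain=10.0)
    # falling phase: exits = first sustained absence after having been in DB
    fall_i = i_db_mask[falling]
    fall_e = e_db_mask[falling]
    t_f, i_f = t[falling], i_inj[falling]

    def exit_current(in_db):
        if not in_db.any():
            return np.nan
        last = np.where(in_db)[0][-1]
        return float(i_f[last]) if last < len(i_f) else np.nan

    i_rae_down = exit_current(fall_i)
    i_db_down = exit_current(fall_e)
    return HysteresisResult(i_rae_up=i_rae_up, i_rae_down=i_rae_down,
                            i_db_up=i_db_up, i_db_down=i_db_down,
                            bistable=(i_rae_down, i_rae_up), trajectory=df)
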