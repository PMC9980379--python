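"""Alpha-function synaptic dynamics as a second-order linear ODE.

The synaptic impulse response is the alpha kernel α(t) = t·e^{-t/τ}.  The
population conductance proxy h(t) is the firing rate convolved with the
kernel, computed here without an explicit convolution by integrating

    ḧ = (F − h)/τ² − 2ḣ/τ,

which is the critically damped second-order system whose impulse response
has the alpha shape and whose DC gain is one: a constant presynaptic rate
F gives h → F.  Delays are handled by reading the (single) synaptic state
of each presynaptic mass at t − D per connection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SynapseSpec", "AlphaSynapse", "alpha_kernel", "delayed_read"]


@dataclass(frozen=True)
class SynapseSpec:
    """Per-connection synaptic parameters.

    ``g`` converts presynaptic firing rate to postsynaptic current
    (μA/cm² per Hz); ``sign`` is +1 (excitatory) or −1 (inhibitory).
    """

    tau: float            # ms
    g: float              # μA/cm² per Hz
    delay: float = 0.0    # ms
    sign: int = +1

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("synaptic time constant must be positive")
        if self.delay < 0:
            raise ValueError("delay must be nonnegative")
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")


def alpha_kernel(t, tau: float):
    """Unit-DC-gain alpha kernel: (t/τ²)·e^{-t/τ} for t ≥ 0."""
    t = np.asarray(t, dtype=float)
    return np.where(t >= 0, t / tau ** 2 * np.exp(-np.clip(t, 0, None) / tau), 0.0)


@dataclass
class AlphaSynapse:
    """State (h, ḣ) of one synaptic filter, stepped with RK4.

    Requires dt ≤ τ/10 for the stated accuracy; history is kept in a ring
    buffer for delayed reads.
    """

    tau: float
    h: float = 0.0
    hdot: float = 0.0
    history_ms: float = 0.0
    _hist_t: list = field(default_factory=list, repr=False)
    _hist_h: list = field(default_factory=list, repr=False)
    _t: float = 0.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        self._record()

    def _record(self):
        if self.history_ms > 0:
            self._hist_t.append(self._t)
            self._hist_h.append(self.h)
            while len(self._hist_t) > 1 and self._hist_t[0] < self._t - self.history_ms - 1e-9:
                self._hist_t.pop(0)
                self._hist_h.pop(0)

    def _deriv(self, h, hdot, f):
        return hdot, (f - h) / self.tau ** 2 - 2.0 * hdot / self.tau

    def step(self, f: float, dt: float) -> float:
        """Advance one step with presynaptic rate ``f`` held over [t, t+dt]."""
        if dt > self.tau / 10.0 + 1e-12:
            raise ValueError(f"dt={dt} too large for tau={self.tau} (need dt <= tau/10)")
        h, hd = self.h, self.hdot
        k1 = self._deriv(h, hd, f)
        k2 = self._deriv(h + 0.5 * dt * k1[0], hd + 0.5 * dt * k1[1], f)
        k3 = self._deriv(h + 0.5 * dt * k2[0], hd + 0.5 * dt * k2[1], f)
        k4 = self._deriv(h + dt * k3[0], hd + dt * k3[1], f)
        self.h = h + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        self.hdot = hd + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        self._t += dt
        self._record()
        return self.h

    def read(self, delay: float = 0.0) -> float:
        """h(t − delay); delay 0 returns the current state."""
        if delay == 0.0:
            return self.h
        return delayed_read(np.asarray(self._hist_t), np.asarray(self._hist_h),
                            self._t, delay)


def delayed_read(t_hist: np.ndarray, h_hist: np.ndarray,
                 t_now: float, delay: float) -> float:
    """Linear interpolation of a state history at t_now − delay.

    During warm-up (history shorter than the delay) the earliest recorded
    value is returned.
    """
    if delay < 0:
        raise ValueError("delay must be nonnegative")
    if len(t_hist) == 0:
        raise ValueError("empty history")
    t_query = t_now - delay
    if t_query <= t_hist[0]:
        return float(h_hist[0])
    return float(np.interp(t_query, t_hist, h_hist))
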