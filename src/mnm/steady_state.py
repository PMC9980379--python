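"""Fixed points, stability, and the firing / depolarization-block boundaries.

For a Hodgkin-Huxley-type model with instantaneous m, the fixed points are
parametrized by membrane potential: at V the gates sit at their steady
values and the injected current that holds the system there is the
steady-state current

    ISS(V) = G_K(V−ν_K) + G_Na(V−ν_Na) + G_L(V−ν_l) [+ I_K-AHP] + I_pump.

Stability follows from the eigenvalues of the reduced (V, n, h) Jacobian.
Scanning V at fixed ν_K, the largest eigenvalue's real part crosses zero
twice around an unstable (spiking) window: the lower crossing maps through
ISS to the firing-onset boundary ISS_F(ν_K), the upper to the
depolarization-block boundary ISS_DB(ν_K).

The mean outputs used to parametrize a mass are sampled on a line shifted
into the firing region, ISS_DB − Δ, because spikes become incomplete
(sub-threshold) in a thin layer below ISS_DB.  Δ is chosen adaptively per
ν_K row: the smallest probed fraction of the firing window that still
produces full spikes, plus one probe step of margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .neuron_models import (
    gate_steady_states, pump_at_shift, rate_functions, rate_derivatives,
    simulate, summarize,
)
from .specs import NeuronModelSpec

__all__ = [
    "FixedPointRecord",
    "BoundaryCurves",
    "iss_of_vm",
    "jacobian",
    "jacobian_fd",
    "jacobian_spectrum",
    "fixed_point_record",
    "trace_boundaries",
    "maxima_along_shifted_db",
]


def iss_of_vm(spec: NeuronModelSpec, v_m, nu_k: float):
    """Steady-state current at the fixed point parametrized by V_m (exact)."""
    v = np.asarray(v_m, dtype=float)
    n, m, h = gate_steady_states(spec, v)
    dnu = nu_k - spec.nu_k_hat
    return (spec.g_k * n ** spec.k_power * (v - nu_k)
            + spec.g_na * m ** spec.na_power * h * (v - spec.nu_na)
            + spec.g_l * (v - spec.nu_l)
            + spec.g_k_ahp * spec.q_hat * (v - nu_k)
            + pump_at_shift(spec, dnu))


def jacobian(spec: NeuronModelSpec, v_m: float, nu_k: float) -> np.ndarray:
    """Analytic 3x3 Jacobian of (V, n, h) at the fixed point at ``v_m``.

    m is eliminated as instantaneous (m = m_inf(V)); the pump does not
    depend on state, so it drops out of the derivatives.
    """
    am, bm, an, bn, ah, bh = rate_functions(spec, v_m)
    dam, dbm, dan, dbn, dah, dbh = rate_derivatives(spec, v_m)
    n, m, h = gate_steady_states(spec, v_m)
    dm = (dam * bm - am * dbm) / (am + bm) ** 2
    c = spec.c_m
    gk_eff = spec.g_k * n ** spec.k_power + spec.g_k_ahp * spec.q_hat
    j = np.empty((3, 3))
    j[0, 0] = -(gk_eff
                + spec.g_na * h * (spec.na_power * m ** (spec.na_power - 1) * dm
                                   * (v_m - spec.nu_na) + m ** spec.na_power)
                + spec.g_l) / c
    j[0, 1] = -spec.g_k * spec.k_power * n ** (spec.k_power - 1) * (v_m - nu_k) / c
    j[0, 2] = -spec.g_na * m ** spec.na_power * (v_m - spec.nu_na) / c
    j[1, 0] = spec.psi * (dan * (1 - n) - dbn * n)
    j[1, 1] = -spec.psi * (an + bn)
    j[1, 2] = 0.0
    j[2, 0] = spec.psi * (dah * (1 - h) - dbh * h)
    j[2, 1] = 0.0
    j[2, 2] = -spec.psi * (ah + bh)
    return j


def jacobian_fd(spec: NeuronModelSpec, v_m: float, nu_k: float,
                eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian (cross-check of the analytic one)."""
    from .neuron_models import MembraneState, derivatives

    n, _, h = gate_steady_states(spec, v_m)
    y0 = np.array([v_m, n, h])
    dnu = nu_k - spec.nu_k_hat
    i_ss = float(iss_of_vm(spec, v_m, nu_k))
    j = np.empty((3, 3))
    for col in range(3):
        yp, ym = y0.copy(), y0.copy()
        yp[col] += eps
        ym[col] -= eps
        fp = derivatives(spec, MembraneState(*yp), i_ss, dnu)
        fm = derivatives(spec, MembraneState(*ym), i_ss, dnu)
        j[:, col] = (fp - fm) / (2 * eps)
    return j


def jacobian_spectrum(spec: NeuronModelSpec, v_m: float, nu_k: float) -> np.ndarray:
    """Real parts of the Jacobian eigenvalues at the fixed point (sorted desc)."""
    eig = np.linalg.eigvals(jacobian(spec, v_m, nu_k))
    return np.sort(eig.real)[::-1]


@dataclass
class FixedPointRecord:
    v_m: float
    gates: tuple            # (n_inf, m_inf, h_inf)
    iss: float              # μA/cm²
    max_re_eig: float       # 1/ms
    stable: bool
    nu_k: float


def fixed_point_record(spec: NeuronModelSpec, v_m: float, nu_k: float) -> FixedPointRecord:
    n, m, h = gate_steady_states(spec, v_m)
    lam = float(jacobian_spectrum(spec, v_m, nu_k)[0])
    return FixedPointRecord(v_m=float(v_m), gates=(float(n), float(m), float(h)),
                            iss=float(iss_of_vm(spec, v_m, nu_k)),
                            max_re_eig=lam, stable=lam < 0, nu_k=float(nu_k))


# ---------------------------------------------------------------------------
# boundary tracing
# ---------------------------------------------------------------------------

@dataclass
class BoundaryCurves:
    """ISS_F and ISS_DB samples over ν_K, plus the maxima line data.

    ``m1/m2/m3`` hold the raw measured means (⟨FR⟩, ⟨V_m⟩, ⟨K_flux⟩) at
    ISS_DB − Δ; ``q_meas`` the normalized current of each measurement point,
    (ISS_DB − Δ − ISS_F)/(ISS_DB − ISS_F).  Rows where a boundary or
    measurement is absent hold NaN.
    """

    nu_k: np.ndarray
    iss_f: np.ndarray
    iss_db: np.ndarray
    v_f: np.ndarray = None          # V_m at the onset crossing
    v_db: np.ndarray = None
    delta: np.ndarray = None        # per-row shift, μA/cm²
    m1: np.ndarray = None           # Hz
    m2: np.ndarray = None           # mV
    m3: np.ndarray = None           # μA/cm²
    q_meas: np.ndarray = None
    spec_kind: str = ""

    def to_frame(self) -> pd.DataFrame:
        cols = dict(nu_k=self.nu_k, iss_f=self.iss_f, iss_db=self.iss_db)
        for name in ("delta", "m1", "m2", "m3", "q_meas"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BoundaryCurves":
        df = pd.read_csv(path)
        kw = {c: df[c].to_numpy() for c in df.columns}
        return cls(**kw)


def _bisect_crossing(f, a: float, b: float, tol: float = 1e-4) -> float:
    fa = f(a)
    for _ in range(200):
        if b - a < tol:
            break
        m = 0.5 * (a + b)
        if np.sign(f(m)) == np.sign(fa):
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def _row_crossings(spec, nu_k, v_range, coarse):
    vs = np.arange(v_range[0], v_range[1] + 0.5 * coarse, coarse)
    lam = np.array([jacobian_spectrum(spec, v, nu_k)[0] for v in vs])
    sign = np.sign(lam)
    idx = np.where(sign[:-1] * sign[1:] < 0)[0]
    out = []
    for i in idx:
        f = lambda v: jacobian_spectrum(spec, v, nu_k)[0]
        out.append(_bisect_crossing(f, vs[i], vs[i + 1]))
    return out


def trace_boundaries(spec: NeuronModelSpec, nu_k_grid,
                     v_range=(-100.0, 20.0), coarse: float = 0.25) -> BoundaryCurves:
    """Locate ISS_F(ν_K) and ISS_DB(ν_K) by eigenvalue zero crossings.

    For each ν_K the largest-eigenvalue sign changes over V_m are bisected
    to |ΔV| < 1e-4 mV and mapped through :func:`iss_of_vm`.  Rows with
    fewer than two crossings (closed firing window) are marked absent (NaN).
    Deterministic: bit-reproducible for a given spec and grid.
    """
    nu_k_grid = np.asarray(nu_k_grid, dtype=float)
    n = len(nu_k_grid)
    iss_f = np.full(n, np.nan)
    iss_db = np.full(n, np.nan)
    v_f = np.full(n, np.nan)
    v_db = np.full(n, np.nan)
    for i, nu in enumerate(nu_k_grid):
        crossings = _row_crossings(spec, nu, v_range, coarse)
        if len(crossings) < 2:
            continue
        lo, hi = crossings[0], crossings[-1]
        a, b = float(iss_of_vm(spec, lo, nu)), float(iss_of_vm(spec, hi, nu))
        # onset is the lower current by construction; keep the ordering explicit
        if a <= b:
            iss_f[i], iss_db[i], v_f[i], v_db[i] = a, b, lo, hi
        else:  # pragma: no cover - not observed for these models
            iss_f[i], iss_db[i], v_f[i], v_db[i] = b, a, hi, lo
    return BoundaryCurves(nu_k=nu_k_grid, iss_f=iss_f, iss_db=iss_db,
                          v_f=v_f, v_db=v_db, spec_kind=spec.model_kind)


_PROBE_FRACTIONS = np.arange(0.04, 0.41, 0.04)


def maxima_along_shifted_db(spec: NeuronModelSpec, curves: BoundaryCurves,
                            delta: float | str = "auto",
                            duration: float = 2500.0, transient_ms: float = 500.0,
                            probe_duration: float = 800.0,
                            probe_transient: float = 300.0,
                            min_spikes: int = 5) -> BoundaryCurves:
    """Populate M1/M2/M3 by simulating at I_inj = ISS_DB − Δ per ν_K row.

    ``delta="auto"`` probes inward from the DB boundary in steps of 4% of
    the firing window with short simulations, stopping at the first
    fraction that yields at least ``min_spikes`` full spikes, then adds one
    step of margin.  A float ``delta`` is used as-is (μA/cm²); a row where
    the shifted point does not fire is reported absent with a warning.
    """
    n = len(curves.nu_k)
    d_arr = np.full(n, np.nan)
    m1 = np.full(n, np.nan)
    m2 = np.full(n, np.nan)
    m3 = np.full(n, np.nan)
    qm = np.full(n, np.nan)
    for i, nu in enumerate(curves.nu_k):
        f, db = curves.iss_f[i], curves.iss_db[i]
        if not (np.isfinite(f) and np.isfinite(db)):
            continue
        w = db - f
        dnu = nu - spec.nu_k_hat
        if delta == "auto":
            d_row = None
            for frac in _PROBE_FRACTIONS:
                tr = simulate(spec, db - frac * w, dnu, duration=probe_duration)
                s = summarize(tr, transient_ms=probe_transient)
                if s.n_spikes >= min_spikes:
                    d_row = min((frac + 0.04), 0.5) * w
                    break
            if d_row is None:
                warnings.warn(f"no firing found near ISS_DB at nu_k={nu}; row absent")
                continue
        else:
            d_row = float(delta)
        tr = simulate(spec, db - d_row, dnu, duration=duration)
        s = summarize(tr, transient_ms=transient_ms)
        if s.mean_fr <= 0:
            warnings.warn(f"shifted point not firing at nu_k={nu} (delta={d_row:.3g}); "
                          "row absent — delta too small or too large")
            continue
        d_arr[i], m1[i], m2[i], m3[i] = d_row, s.mean_fr, s.mean_vm, s.mean_kflux
        qm[i] = (db - d_row - f) / w
    return replace(curves, delta=d_arr, m1=m1, m2=m2, m3=m3, q_meas=qm)
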