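"""Build a MassParametrization from boundary curves and check its fidelity.

The pipeline is: trace the ISS_F / ISS_DB boundaries over a ν_K grid,
measure the mean outputs on the shifted line ISS_DB − Δ, fit low-order
polynomials in ν_K (linear thresholds; M1 cubic / M2 quadratic / M3 linear
for the I mass, M1 quadratic / M2 quadratic / M3 cubic for the E mass),
and assemble the mass functionals.

Amplitude convention: the measured means sit at normalized current
Q_meas = 1 − Δ/(ISS_DB − ISS_F) < 1, while the functionals use M1..M3 as
their Q = 1 amplitudes.  By default the measurements are therefore
divided by Q_meas^p before fitting, so the functional exactly
interpolates each measured anchor point whatever Δ was used
(``amplitude_correction=False`` restores the raw-amplitude behaviour).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mass_core import MassInput, MassParametrization, evaluate_mass
from .neuron_models import simulate, summarize
from .specs import NeuronModelSpec
from .steady_state import BoundaryCurves, maxima_along_shifted_db, trace_boundaries

__all__ = [
    "DEFAULT_ORDERS",
    "fit_parametrization",
    "build_mass",
    "fidelity_report",
    "FidelitySummary",
]

#: Polynomial fit orders (th1, th2, M1, M2, M3) per mass kind.
DEFAULT_ORDERS = {"I": (1, 1, 3, 2, 1), "E": (1, 1, 2, 2, 3)}

#: Default parametrization window in Δν_K (mV).
DEFAULT_WINDOW = (0.0, 20.0)

_COND_LIMIT = 1e10


def _fit_poly(x, y, order):
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < order + 2:
        raise ValueError(f"need at least {order + 2} samples for an order-{order} fit, "
                         f"got {int(mask.sum())}")
    cond = np.linalg.cond(np.vander(x[mask], order + 1))
    if cond > _COND_LIMIT:
        raise ValueError(f"Vandermonde condition number {cond:.2e} exceeds 1e10; "
                         "rescale the nu_K grid")
    coeffs = np.polyfit(x[mask], y[mask], order)
    resid = y[mask] - np.polyval(coeffs, x[mask])
    return tuple(coeffs), float(np.sqrt(np.mean(resid ** 2)))


def fit_parametrization(curves: BoundaryCurves, mass_kind: str,
                        spec: NeuronModelSpec | None = None,
                        orders=None,
                        amplitude_correction: bool = True) -> MassParametrization:
    """Least-squares fits of thresholds and maxima as functions of ν_K."""
    if curves.m1 is None:
        raise ValueError("curves carry no maxima; run maxima_along_shifted_db first")
    orders = tuple(orders) if orders is not None else DEFAULT_ORDERS[mass_kind]
    from .mass_core import _C1, _C2, _EXPONENTS
    c1, c2 = _C1[mass_kind], _C2[mass_kind]
    p_fr, p_vm, p_kf = _EXPONENTS[mass_kind]

    nu = np.asarray(curves.nu_k, dtype=float)
    qm = np.asarray(curves.q_meas, dtype=float)
    if amplitude_correction:
        a1 = curves.m1 / qm ** p_fr
        a2 = (c1 - curves.m2) / qm ** p_vm
        a3 = (curves.m3 - c2) / qm ** p_kf
    else:
        a1 = np.asarray(curves.m1, dtype=float)
        a2 = c1 - np.asarray(curves.m2, dtype=float)
        a3 = np.asarray(curves.m3, dtype=float) - c2

    th1, r1 = _fit_poly(nu, curves.iss_f, orders[0])
    th2, r2 = _fit_poly(nu, curves.iss_db, orders[1])
    m1, r3 = _fit_poly(nu, a1, orders[2])
    m2, r4 = _fit_poly(nu, a2, orders[3])
    m3, r5 = _fit_poly(nu, a3, orders[4])

    nu_hat = spec.nu_k_hat if spec is not None else float(np.min(nu))
    window = (float(np.min(nu) - nu_hat), float(np.max(nu) - nu_hat))
    prov = dict(
        nu_k_grid=[float(v) for v in nu],
        delta=[float(v) for v in np.asarray(curves.delta, dtype=float)],
        amplitude_correction=bool(amplitude_correction),
        orders=list(orders),
        residual_rms=dict(th1=r1, th2=r2, m1=r3, m2=r4, m3=r5),
    )
    return MassParametrization(
        mass_kind=mass_kind, nu_k_hat=nu_hat,
        th1_coeffs=th1, th2_coeffs=th2,
        m1_coeffs=m1, m2_coeffs=m2, m3_coeffs=m3,
        fit_window=window,
        rho=spec.rho if spec is not None else 1.25,
        k_o_hat=spec.k_o_hat if spec is not None else None,
        na_i_hat=spec.na_i_hat if spec is not None else 25.0,
        rt_over_f=spec.rt_over_f if spec is not None else 26.64,
        neuron=spec, provenance=prov)


def build_mass(spec: NeuronModelSpec, dnu_k_grid=None, delta="auto",
               duration: float = 2500.0, transient_ms: float = 500.0,
               **fit_kw) -> MassParametrization:
    """End-to-end mass construction: boundaries → maxima → fits."""
    if dnu_k_grid is None:
        dnu_k_grid = np.linspace(*DEFAULT_WINDOW, 9)
    nu_grid = spec.nu_k_hat + np.asarray(dnu_k_grid, dtype=float)
    curves = trace_boundaries(spec, nu_grid)
    curves = maxima_along_shifted_db(spec, curves, delta=delta,
                                     duration=duration, transient_ms=transient_ms)
    kind = "I" if spec.model_kind == "WB" else "E"
    return fit_parametrization(curves, kind, spec=spec, **fit_kw)


# ---------------------------------------------------------------------------
# fidelity
# ---------------------------------------------------------------------------

@dataclass
class FidelitySummary:
    median: dict      # per-quantity median relative error
    p90: dict         # per-quantity 90th-percentile relative error
    n_points: int


_FLOORS = dict(fr=1.0, vm=1.0, kflux=0.05)


def fidelity_report(param: MassParametrization, spec: NeuronModelSpec,
                    dnu_k_values, n_currents: int = 20,
                    central_frac: float = 0.8,
                    duration: float = 2500.0, transient_ms: float = 500.0):
    """Mass functionals vs ODE time averages across the firing range.

    For each Δν_K, ``n_currents`` injected currents span the central
    ``central_frac`` of the fitted window [i_th1, i_th2]; the isolated
    mass is driven with X_tot = I_inj (the injected current plays the role
    of the steady-state current at the fixed point).  Points where the ODE
    model does not fire (the incomplete-spike layer below DB) are outside
    the firing range and are excluded from the error summary.

    Returns ``(DataFrame, FidelitySummary)``.
    """
    rows = []
    edge = (1.0 - central_frac) / 2.0
    for dnu in dnu_k_values:
        th1, th2, *_ = param.thresholds_and_maxima(dnu, warn_extrapolation=False)
        if th2 <= th1:
            warnings.warn(f"empty firing range at dnu_k={dnu}; row skipped")
            continue
        w = th2 - th1
        currents = th1 + np.linspace(edge, 1.0 - edge, n_currents) * w
        for i_inj in currents:
            tr = simulate(spec, float(i_inj), float(dnu), duration=duration)
            s = summarize(tr, transient_ms=transient_ms)
            out = evaluate_mass(param, MassInput(x_tot=float(i_inj), dnu_k=float(dnu)))
            rows.append(dict(
                dnu_k=dnu, i_inj=i_inj, q=out.q,
                fr_ode=s.mean_fr, fr_mass=out.fr,
                vm_ode=s.mean_vm, vm_mass=out.v_m,
                kflux_ode=s.mean_kflux, kflux_mass=out.k_flux,
                ode_firing=s.regime == "F",
            ))
    df = pd.DataFrame(rows)
    for q in ("fr", "vm", "kflux"):
        df[f"relerr_{q}"] = (np.abs(df[f"{q}_mass"] - df[f"{q}_ode"])
                             / np.maximum(np.abs(df[f"{q}_ode"]), _FLOORS[q]))
    firing = df[df.ode_firing]
    med = {q: float(firing[f"relerr_{q}"].median()) for q in ("fr", "vm", "kflux")}
    p90 = {q: float(firing[f"relerr_{q}"].quantile(0.9)) for q in ("fr", "vm", "kflux")}
    return df, FidelitySummary(median=med, p90=p90, n_points=len(firing))
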