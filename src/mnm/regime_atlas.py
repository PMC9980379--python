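"""Analytic regime boundaries of the coupled E-I network.

In the (I_E,inj, Δν_K) — or (g_IE/ĝ_IE, I_E,inj) — plane the couplet
shows five regimes: not-firing (NF), firing (F), bistable (BS), runaway
excitation (RAE) and depolarization block (DB).  Their boundaries follow
algebraically from the mass parametrizations:

FO  (firing onset):  I = i_th1^E(ν_K) − I_pump^E  (no synaptic input at
    onset, since neither mass fires below it).

RAE (I-mass DB entry): the E-mass firing rate needed to push the I mass's
    total current to its DB threshold is
    FR_E* = (i_th2^I − I_pump^I − I_I,inj)/g_EI; inverting the E firing
    functional gives Q_E* = (FR_E*/M1^E)^2 and
    I_RAE = i_th1^E + Q_E*·(i_th2^E − i_th1^E) − I_pump^E + g_IE·M1^I
    (the I mass fires at its maximum just before failing).  If
    FR_E* > M1^E the E mass cannot silence the I mass and the boundary is
    absent.

BS  (bistability): I_BS = I_RAE − g_IE·M1^I (the inhibitory current lost
    when the I mass fails).  The bistable band is [I_BS, I_RAE].

DB:  the bare E-mass DB onset is i_th2^E − I_pump^E (no inhibition in
    RAE).  The *effective* DB onset applies the crossing rule,
    min(bare, I_RAE): past I_RAE the network leaves normal/bistable
    operation for the pathological branch that terminates in DB, so where
    the RAE boundary undercuts the bare DB line the DB boundary is shifted
    onto it.  Both values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ei_network import G_EI_NOMINAL, G_IE_NOMINAL
from .mass_core import MassParametrization

__all__ = [
    "RegimeBoundarySet",
    "firing_onset_boundary",
    "rae_boundary",
    "bistability_boundary",
    "db_boundary",
    "boundary_set",
    "atlas",
]


def firing_onset_boundary(e_param: MassParametrization, dnu_k: float) -> float:
    """Injected current at the E-mass firing onset (μA/cm²)."""
    th1, *_ = e_param.thresholds_and_maxima(dnu_k, warn_extrapolation=False)
    return th1 - e_param.pump_current(dnu_k)


def rae_boundary(e_param: MassParametrization, i_param: MassParametrization,
                 g_ei: float = G_EI_NOMINAL, g_ie: float = G_IE_NOMINAL,
                 dnu_k: float = 0.0, i_i_inj: float = 0.0,
                 literal_q: bool = False) -> float:
    """Injected current at which the I mass is driven into DB (RAE onset).

    ``literal_q=True`` evaluates the alternative normalized-current
    reading of the boundary chain (kept for comparison only).
    """
    if g_ei <= 0 or g_ie < 0:
        raise ValueError("couplings must be positive (g_ei) / nonnegative (g_ie)")
    th1_e, th2_e, m1_e, *_ = e_param.thresholds_and_maxima(dnu_k, warn_extrapolation=False)
    th1_i, th2_i, m1_i, *_ = i_param.thresholds_and_maxima(dnu_k, warn_extrapolation=False)
    pump_e = e_param.pump_current(dnu_k)
    pump_i = i_param.pump_current(dnu_k)
    p_fr_e = e_param.exponents[0]
    if literal_q:
        fr_e_req = (1.0 - i_i_inj + pump_i) / g_ei
        if fr_e_req > m1_e or fr_e_req < 0:
            return np.nan
        q_e = (fr_e_req / m1_e) ** (1.0 / p_fr_e)
        return q_e + pump_e + g_ie * m1_i
    fr_e_req = (th2_i - pump_i - i_i_inj) / g_ei
    if fr_e_req > m1_e or fr_e_req < 0:
        return np.nan
    q_e = (fr_e_req / m1_e) ** (1.0 / p_fr_e)
    x_e = th1_e + q_e * (th2_e - th1_e)
    return x_e - pump_e + g_ie * m1_i


def bistability_boundary(i_rae: float, i_param: MassParametrization,
                         g_ie: float = G_IE_NOMINAL, dnu_k: float = 0.0) -> float:
    """Lower edge of the bistable band: I_BS = I_RAE − g_IE·M1^I."""
    _, _, m1_i, *_ = i_param.thresholds_and_maxima(dnu_k, warn_extrapolation=False)
    return i_rae - g_ie * m1_i


def db_boundary(e_param: MassParametrization, dnu_k: float,
                i_rae: float = np.nan) -> tuple[float, float]:
    """(bare, effective) E-mass DB onset currents.

    bare = i_th2^E − I_pump^E; effective applies the crossing rule
    min(bare, I_RAE) (= bare where the RAE boundary is absent).
    """
    _, th2, *_ = e_param.thresholds_and_maxima(dnu_k, warn_extrapolation=False)
    bare = th2 - e_param.pump_current(dnu_k)
    effective = min(bare, i_rae) if np.isfinite(i_rae) else bare
    return bare, effective


@dataclass
class RegimeBoundarySet:
    """All boundary currents at one (Δν_K, coupling) point."""

    dnu_k: float
    g_ei: float
    g_ie: float
    fo: float
    bs: float
    rae: float
    db_bare: float
    db_effective: float


def boundary_set(e_param, i_param, g_ei=G_EI_NOMINAL, g_ie=G_IE_NOMINAL,
                 dnu_k: float = 0.0, i_i_inj: float = 0.0) -> RegimeBoundarySet:
    fo = firing_onset_boundary(e_param, dnu_k)
    rae = rae_boundary(e_param, i_param, g_ei, g_ie, dnu_k, i_i_inj)
    bs = bistability_boundary(rae, i_param, g_ie, dnu_k) if np.isfinite(rae) else np.nan
    bare, eff = db_boundary(e_param, dnu_k, rae)
    return RegimeBoundarySet(dnu_k=dnu_k, g_ei=g_ei, g_ie=g_ie,
                             fo=fo, bs=bs, rae=rae,
                             db_bare=bare, db_effective=eff)


def atlas(e_param, i_param, mode: str = "dnuk", grid=None,
          g_ei: float = G_EI_NOMINAL, g_ie: float = G_IE_NOMINAL,
          dnu_k: float = 0.0, i_i_inj: float = 0.0) -> pd.DataFrame:
    """Boundary curves over a Δν_K grid (``mode='dnuk'``) or a coupling
    ratio grid g_IE/ĝ_IE (``mode='ratio'``, at fixed ``dnu_k``).

    The returned frame also carries the uncoupled E-mass onset/DB lines
    (``fo_uncoupled`` = FO, ``db_uncoupled`` = bare DB) for reference.
    """
    rows = []
    if mode == "dnuk":
        grid = np.linspace(0.0, 20.0, 21) if grid is None else np.asarray(grid, float)
        for d in grid:
            b = boundary_set(e_param, i_param, g_ei, g_ie, float(d), i_i_inj)
            rows.append(dict(dnu_k=d, ratio=g_ie / G_IE_NOMINAL, **_row(b)))
    elif mode == "ratio":
        grid = np.geomspace(0.1, 10.0, 25) if grid is None else np.asarray(grid, float)
        for r in grid:
            b = boundary_set(e_param, i_param, g_ei, r * G_IE_NOMINAL,
                             dnu_k, i_i_inj)
            rows.append(dict(dnu_k=dnu_k, ratio=r, **_row(b)))
    else:
        raise ValueError("mode must be 'dnuk' or 'ratio'")
    return pd.DataFrame(rows)


def _row(b: RegimeBoundarySet) -> dict:
    return dict(fo=b.fo, bs=b.bs, rae=b.rae, db_bare=b.db_bare,
                db_effective=b.db_effective,
                fo_uncoupled=b.fo, db_uncoupled=b.db_bare)
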