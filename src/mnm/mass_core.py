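"""The mechanistic neural-mass element: thresholds, maxima and functionals.

A :class:`MassParametrization` encodes one mass (inhibitory "I" derived
from the WB model, excitatory "E" from the SEAN model) as a small set of
polynomial fits in the potassium Nernst potential ν_K:

- linear firing threshold ``i_th1(ν_K)`` and DB threshold ``i_th2(ν_K)``
  (the ISS_F / ISS_DB boundary fits),
- polynomial amplitudes M1, M2, M3 for the maximal mean firing rate,
  membrane potential and potassium flux,
- fixed exponents and offsets of the output functionals.

Given a total input current X and the normalized current
``Q = (X − i_th1)/(i_th2 − i_th1)`` the outputs inside the firing window
(0 ≤ Q ≤ 1) are

    FR    = M1 · Q^p_FR,
    V_m   = C1 − M2 · Q^p_Vm,
    K_flux = M3 · Q^p_KF + C2,

with (p_FR, p_Vm, p_KF) = (1/2, 1/2, 1/2) for the I mass and
(1/2, 0.62, 0.28) for the E mass; C1 = −60 (I) or −65 (E) mV, C2 = 0.1
μA/cm² (E only).  Outside the window the mass is silent (FR = 0): NF for
Q < 0, DB for Q > 1, where V_m and K_flux follow the stable fixed points
of the underlying neuron model (see :class:`FixedPointClosure`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np

from .specs import NeuronModelSpec, RT_OVER_F

__all__ = [
    "nernst_shift",
    "k_o_from_shift",
    "nominal_k_o",
    "MassInput",
    "MassOutput",
    "MassParametrization",
    "FixedPointClosure",
    "evaluate_mass",
    "total_current",
]


# ---------------------------------------------------------------------------
# Nernst-potential utilities
# ---------------------------------------------------------------------------

def nernst_shift(k_o: float, k_o_hat: float, rt_over_f: float = RT_OVER_F) -> float:
    """Δν_K = (RT/F)·ln([K]_o/[K̂]_o), the shift of the K Nernst potential.

    Intracellular potassium is treated as constant, so the shift is carried
    entirely by the extracellular concentration.
    """
    if k_o <= 0 or k_o_hat <= 0:
        raise ValueError("potassium concentrations must be positive")
    return rt_over_f * math.log(k_o / k_o_hat)


def k_o_from_shift(dnu_k: float, k_o_hat: float, rt_over_f: float = RT_OVER_F) -> float:
    """Inverse of :func:`nernst_shift` (exact round trip)."""
    if k_o_hat <= 0:
        raise ValueError("nominal concentration must be positive")
    return k_o_hat * math.exp(dnu_k / rt_over_f)


def nominal_k_o(nu_k_hat: float, k_i: float, rt_over_f: float = RT_OVER_F) -> float:
    """Nominal [K]_o implied by a nominal Nernst potential and [K]_i."""
    if k_i <= 0:
        raise ValueError("intracellular concentration must be positive")
    return k_i * math.exp(nu_k_hat / rt_over_f)


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass
class MassInput:
    x_tot: float          # total input current, μA/cm²
    dnu_k: float = 0.0    # Nernst shift, mV


@dataclass
class MassOutput:
    fr: float             # Hz
    v_m: float            # mV
    k_flux: float         # μA/cm²
    q: float              # normalized current
    regime: str           # 'NF' | 'F' | 'DB'


_EXPONENTS = {"I": (0.5, 0.5, 0.5), "E": (0.5, 0.62, 0.28)}
_C1 = {"I": -60.0, "E": -65.0}
_C2 = {"I": 0.0, "E": 0.1}


@dataclass
class MassParametrization:
    """Fitted coefficient sets of one mechanistic neural mass.

    Polynomial coefficients are stored highest power first (``np.polyval``
    convention) in the absolute Nernst potential ν_K (mV).
    """

    mass_kind: str                      # 'I' | 'E'
    nu_k_hat: float                     # mV
    th1_coeffs: tuple                   # linear (a, b): i_th1 = a·ν_K + b
    th2_coeffs: tuple
    m1_coeffs: tuple                    # Hz vs ν_K
    m2_coeffs: tuple                    # mV (magnitude entering C1 − M2·Q^p)
    m3_coeffs: tuple                    # μA/cm²
    fit_window: tuple                   # (Δν_K lo, Δν_K hi) of the fit
    exponents: tuple = None             # (p_FR, p_Vm, p_KF)
    c1: float = None                    # mV
    c2: float = None                    # μA/cm²
    rho: float = 1.25
    k_o_hat: float = None               # mM
    na_i_hat: float = 25.0
    rt_over_f: float = RT_OVER_F
    neuron: NeuronModelSpec | None = field(default=None, repr=False)
    provenance: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.mass_kind not in ("I", "E"):
            raise ValueError("mass_kind must be 'I' or 'E'")
        if self.exponents is None:
            self.exponents = _EXPONENTS[self.mass_kind]
        if self.c1 is None:
            self.c1 = _C1[self.mass_kind]
        if self.c2 is None:
            self.c2 = _C2[self.mass_kind]
        if self.k_o_hat is None:
            self.k_o_hat = nominal_k_o(self.nu_k_hat, 140.0, self.rt_over_f)
        self.exponents = tuple(float(e) for e in self.exponents)
        for name in ("th1_coeffs", "th2_coeffs", "m1_coeffs", "m2_coeffs", "m3_coeffs"):
            setattr(self, name, tuple(float(c) for c in getattr(self, name)))

    # -- evaluation --------------------------------------------------------

    def pump_current(self, dnu_k: float) -> float:
        """Pump current at nominal [Na]_i and [K]_o set by Δν_K."""
        k_o = k_o_from_shift(dnu_k, self.k_o_hat, self.rt_over_f)
        return self.rho / ((1.0 + math.exp(0.0))
                           * (1.0 + math.exp(self.k_o_hat - k_o)))

    def thresholds_and_maxima(self, dnu_k: float, warn_extrapolation: bool = True):
        """(i_th1, i_th2, M1, M2, M3) at Δν_K — pure polynomial evaluation."""
        lo, hi = self.fit_window
        if warn_extrapolation and not (lo <= dnu_k <= hi):
            warnings.warn(
                f"dnu_k={dnu_k} outside the fitted window [{lo}, {hi}]; "
                "polynomials extrapolated", stacklevel=2)
        nu = self.nu_k_hat + dnu_k
        return tuple(float(np.polyval(c, nu)) for c in
                     (self.th1_coeffs, self.th2_coeffs,
                      self.m1_coeffs, self.m2_coeffs, self.m3_coeffs))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "neuron"}
        for name in ("th1_coeffs", "th2_coeffs", "m1_coeffs", "m2_coeffs",
                     "m3_coeffs", "exponents", "fit_window"):
            d[name] = list(d[name])
        d["neuron"] = self.neuron.to_dict() if self.neuron is not None else None
        d["schema_version"] = 1
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MassParametrization":
        d = dict(d)
        version = d.pop("schema_version", 1)
        if version != 1:
            raise ValueError(f"unsupported MassParametrization schema version {version}")
        neuron = d.pop("neuron", None)
        for name in ("th1_coeffs", "th2_coeffs", "m1_coeffs", "m2_coeffs",
                     "m3_coeffs", "exponents", "fit_window"):
            if name in d and d[name] is not None:
                d[name] = tuple(d[name])
        return cls(neuron=NeuronModelSpec.from_dict(neuron) if neuron else None, **d)


# ---------------------------------------------------------------------------
# NF/DB closures from the neuron's stable fixed points
# ---------------------------------------------------------------------------

class FixedPointClosure:
    """V_m and K_flux of the stable fixed point at a given total current.

    Outside the firing window the mass's mean potential and potassium flux
    are those of the underlying neuron's stable fixed point: the
    hyperpolarized branch in NF, the depolarized branch in DB.  Roots of
    ISS(V) = X are located by scan + bisection and screened for stability.
    """

    def __init__(self, spec: NeuronModelSpec, v_range=(-100.0, 20.0),
                 coarse: float = 0.5):
        self.spec = spec
        self.v_range = v_range
        self.coarse = coarse
        self._eval = lru_cache(maxsize=4096)(self._eval_uncached)

    def __call__(self, x_tot: float, dnu_k: float, branch: str):
        return self._eval(round(float(x_tot), 6), round(float(dnu_k), 6), branch)

    def _eval_uncached(self, x_tot: float, dnu_k: float, branch: str):
        from .neuron_models import k_flux
        from .steady_state import iss_of_vm, jacobian_spectrum

        spec = self.spec
        nu_k = spec.nu_k_hat + dnu_k
        vs = np.arange(self.v_range[0], self.v_range[1], self.coarse)
        res = np.asarray(iss_of_vm(spec, vs, nu_k)) - x_tot
        idx = np.where(np.sign(res[:-1]) * np.sign(res[1:]) < 0)[0]
        roots = []
        for i in idx:
            a, b = vs[i], vs[i + 1]
            fa = res[i]
            for _ in range(80):
                m = 0.5 * (a + b)
                fm = float(iss_of_vm(spec, m, nu_k)) - x_tot
                if np.sign(fm) == np.sign(fa):
                    a, fa = m, fm
                else:
                    b = m
                if b - a < 1e-8:
                    break
            roots.append(0.5 * (a + b))
        stable = [v for v in roots if jacobian_spectrum(spec, v, nu_k)[0] < 0]
        if not stable:
            return (math.nan, math.nan)
        v = min(stable) if branch == "NF" else max(stable)
        from .neuron_models import gate_steady_states
        n, _, _ = gate_steady_states(spec, v)
        return (float(v), float(k_flux(spec, v, n, dnu_k)))


# ---------------------------------------------------------------------------
# functional evaluation
# ---------------------------------------------------------------------------

def evaluate_mass(param: MassParametrization, inp: MassInput,
                  closures: FixedPointClosure | None = None,
                  warn_extrapolation: bool = False) -> MassOutput:
    """Evaluate the mass functionals at a total input current.

    Inside the firing window FR rises continuously from 0 at ``i_th1`` to
    M1 at ``i_th2`` (the drop to 0 beyond ``i_th2`` — DB entry — is the
    model's intentional discontinuity).  Outside the window FR = 0 and, if
    the parametrization carries its neuron spec (or ``closures`` is
    given), V_m and K_flux come from the stable fixed-point branch.
    """
    th1, th2, m1, m2, m3 = param.thresholds_and_maxima(
        inp.dnu_k, warn_extrapolation=warn_extrapolation)
    p_fr, p_vm, p_kf = param.exponents
    w = th2 - th1
    if w <= 0:
        warnings.warn(f"degenerate firing window at dnu_k={inp.dnu_k} "
                      f"(i_th2 <= i_th1); regime by sign of X - i_th1")
        q = math.inf if inp.x_tot > th1 else -math.inf
    else:
        q = (inp.x_tot - th1) / w

    if 0.0 <= q <= 1.0:
        return MassOutput(fr=m1 * q ** p_fr,
                          v_m=param.c1 - m2 * q ** p_vm,
                          k_flux=m3 * q ** p_kf + param.c2,
                          q=q, regime="F")
    regime = "NF" if q < 0 else "DB"
    if closures is None and param.neuron is not None:
        closures = _default_closure(param)
    if closures is not None:
        v_m, kf = closures(inp.x_tot, inp.dnu_k, regime)
    else:
        v_m, kf = math.nan, math.nan
    return MassOutput(fr=0.0, v_m=v_m, k_flux=kf, q=q, regime=regime)


_CLOSURE_CACHE: dict[int, FixedPointClosure] = {}


def _default_closure(param: MassParametrization) -> FixedPointClosure:
    key = id(param)
    if key not in _CLOSURE_CACHE:
        _CLOSURE_CACHE[key] = FixedPointClosure(param.neuron)
    return _CLOSURE_CACHE[key]


def total_current(param: MassParametrization, i_inj: float, dnu_k: float,
                  synapses=()) -> float:
    """Total input current X_tot = I_inj + I_pump(Δν_K) + Σ sign·g·h.

    ``synapses`` is an iterable of (g, h, sign) with sign +1 for an
    excitatory and −1 for an inhibitory afferent (signs are explicit).
    """
    x = i_inj + param.pump_current(dnu_k)
    for g, h, sign in synapses:
        if sign not in (+1, -1):
            raise ValueError("synaptic sign must be +1 or -1")
        x += sign * g * h
    return x
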