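"""Neuron-model parameter sets for the Wang-Buzsáki and SEAN membrane models.

A :class:`NeuronModelSpec` holds the full parameter set of one
Hodgkin-Huxley-type membrane model: maximal conductances, reversal (Nernst)
potentials, the Na/K-pump parameters, and a table of voltage-dependent
rate-function coefficients.  Two canonical builders are provided:

``wb_spec()``
    The Wang-Buzsáki fast-spiking interneuron (the inhibitory cell class),
    with the sodium-potassium pump current added.

``sean_spec()``
    The Single-compartment Excitatory Accommodating Neuron: the somatic
    compartment of the Pinsky-Rinzel pyramidal-cell model, shifted to
    absolute membrane potential (rest near -60 mV), with the pump and a
    calcium-gated K-AHP (accommodation) current whose gate is frozen at a
    nominal calcium level (the fast/slow split of the accommodation
    current; only the fast part enters the parametrization).

Units package-wide: mV, ms, μA/cm², mS/cm², μF/cm², mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

__all__ = [
    "RT_OVER_F",
    "RateCoeff",
    "NeuronModelSpec",
    "wb_spec",
    "sean_spec",
    "q_infinity",
]

#: Thermal voltage k_B T / e at body temperature (mV).
RT_OVER_F = 26.64

_FORMS = ("linexp", "exp", "logistic")
_RATE_NAMES = ("alpha_m", "beta_m", "alpha_n", "beta_n", "alpha_h", "beta_h")


@dataclass(frozen=True)
class RateCoeff:
    """One alpha/beta rate function ``r(V)`` of the gating kinetics.

    With ``x = sign * (V + v_half)`` the three functional forms are

    - ``linexp``:   ``a * x / (1 - exp(-x/b))``  (removable singularity at
      x = 0, evaluated by its analytic limit ``a*b``),
    - ``exp``:      ``a * exp(x/b)`` (use ``sign=-1`` for a decaying tail),
    - ``logistic``: ``a / (1 + exp(-x/b))``.
    """

    form: str
    a: float
    v_half: float
    b: float
    sign: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown rate form {self.form!r}; expected one of {_FORMS}")
        if self.b == 0:
            raise ValueError("rate slope parameter b must be nonzero")
        if self.sign not in (1.0, -1.0):
            raise ValueError("sign must be +1 or -1")


def q_infinity(ca: float) -> float:
    """Steady-state K-AHP (accommodation) gate at calcium level ``ca``."""
    alpha_q = min(0.00002 * ca, 0.01)
    return alpha_q / (alpha_q + 0.001)


@dataclass(frozen=True)
class NeuronModelSpec:
    """Full parameter set + equation form of one membrane ODE model."""

    model_kind: str                       # "WB" or "SEAN"
    c_m: float                            # μF/cm²
    g_k: float                            # mS/cm²
    g_na: float                           # mS/cm²
    g_l: float                            # mS/cm²
    nu_k_hat: float                       # nominal K Nernst potential, mV
    nu_na: float                          # Na Nernst potential (held fixed), mV
    nu_l: float                           # leak reversal, mV
    rho: float                            # pump strength, μA/cm²
    na_i_hat: float                       # nominal [Na]_i, mM
    k_i: float                            # [K]_i (held constant), mM
    rates: tuple[RateCoeff, ...]          # (α_m, β_m, α_n, β_n, α_h, β_h)
    psi: float = 1.0                      # gating rate scale (WB only)
    g_k_ahp: float = 0.0                  # accommodation conductance (SEAN only)
    q_hat: float = 0.0                    # frozen accommodation gate (SEAN only)
    k_power: float = 4.0                  # n exponent in I_K
    na_power: float = 3.0                 # m exponent in I_Na
    rt_over_f: float = RT_OVER_F          # mV
    k_o_hat: float = field(default=0.0)   # nominal [K]_o, mM (0 -> derived)

    def __post_init__(self) -> None:
        if self.model_kind not in ("WB", "SEAN"):
            raise ValueError(f"model_kind must be 'WB' or 'SEAN', got {self.model_kind!r}")
        for name in ("c_m", "g_k", "g_na"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.g_l < 0 or self.g_k_ahp < 0:
            raise ValueError("conductances must be nonnegative")
        if len(self.rates) != 6:
            raise ValueError("rates must hold exactly six entries "
                             "(alpha/beta for m, n, h)")
        if self.model_kind == "WB" and self.g_k_ahp != 0.0:
            raise ValueError("WB spec has no accommodation (g_k_ahp) term")
        if self.model_kind == "SEAN" and self.psi != 1.0:
            raise ValueError("SEAN spec has no gating rate scale psi")
        if self.k_o_hat == 0.0:
            # Nominal extracellular K from the nominal Nernst potential.
            object.__setattr__(
                self, "k_o_hat",
                self.k_i * math.exp(self.nu_k_hat / self.rt_over_f))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rates"] = [asdict(r) for r in self.rates]
        d["schema_version"] = 1
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronModelSpec":
        d = dict(d)
        version = d.pop("schema_version", 1)
        if version != 1:
            raise ValueError(f"unsupported NeuronModelSpec schema version {version}")
        try:
            rates = tuple(RateCoeff(**r) for r in d.pop("rates"))
        except KeyError as exc:
            raise ValueError(f"rate table entry missing field {exc}") from exc
        return cls(rates=rates, **d)

    @property
    def rate_names(self) -> tuple[str, ...]:
        return _RATE_NAMES


def wb_spec(**overrides) -> NeuronModelSpec:
    """Canonical Wang-Buzsáki interneuron with the Na/K pump current.

    Keyword overrides replace individual fields (e.g. ``g_k_ahp`` is
    rejected: the WB model carries no accommodation current).
    """
    kw = dict(
        model_kind="WB",
        c_m=1.0, g_k=9.0, g_na=35.0, g_l=0.1,
        nu_k_hat=-90.0, nu_na=55.0, nu_l=-65.0,
        psi=5.0, rho=1.25, na_i_hat=25.0, k_i=140.0,
        k_power=4.0, na_power=3.0,
        rates=(
            RateCoeff("linexp", 0.1, 35.0, 10.0),        # alpha_m
            RateCoeff("exp", 4.0, 60.0, 18.0, -1.0),     # beta_m
            RateCoeff("linexp", 0.01, 34.0, 10.0),       # alpha_n
            RateCoeff("exp", 0.125, 44.0, 80.0, -1.0),   # beta_n
            RateCoeff("exp", 0.07, 58.0, 20.0, -1.0),    # alpha_h
            RateCoeff("logistic", 1.0, 28.0, 10.0),      # beta_h
        ),
    )
    kw.update(overrides)
    return NeuronModelSpec(**kw)


def sean_spec(**overrides) -> NeuronModelSpec:
    """Canonical SEAN (somatic Pinsky-Rinzel) excitatory neuron.

    The Pinsky-Rinzel somatic currents are I_Na = g_Na m_inf^2 h (V - nu_Na)
    and I_K-DR = g_K n (V - nu_K); membrane potential is shifted by -60 mV
    relative to the original Pinsky-Rinzel voltage convention so that the
    reversal potentials take their absolute values (nu_Na = 60, nu_l = -60).
    The accommodation gate is frozen at q_hat = q_inf(Ca = 0.2).
    """
    kw = dict(
        model_kind="SEAN",
        c_m=3.0, g_k=15.0, g_na=30.0, g_l=0.1,
        nu_k_hat=-75.0, nu_na=60.0, nu_l=-60.0,
        rho=1.25, na_i_hat=25.0, k_i=140.0,
        g_k_ahp=0.8, q_hat=q_infinity(0.2),
        k_power=1.0, na_power=2.0,
        rates=(
            RateCoeff("linexp", 0.32, 46.9, 4.0),        # alpha_m
            RateCoeff("linexp", 0.28, 19.9, 5.0, -1.0),  # beta_m
            RateCoeff("linexp", 0.016, 24.9, 5.0),       # alpha_n
            RateCoeff("exp", 0.25, 40.0, 40.0, -1.0),    # beta_n
            RateCoeff("exp", 0.128, 43.0, 18.0, -1.0),   # alpha_h
            RateCoeff("logistic", 4.0, 20.0, 5.0),       # beta_h
        ),
    )
    kw.update(overrides)
    return NeuronModelSpec(**kw)
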