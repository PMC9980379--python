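"""Serialization, run manifests and test fixtures.

Model specs and mass parametrizations are stored as YAML with an explicit
schema version; every CLI output is accompanied by a RunManifest recording
the input hashes, grids and solver settings so deterministic stages are
rerunnable bit-identically.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .mass_core import MassParametrization
from .specs import NeuronModelSpec, wb_spec, sean_spec

__all__ = [
    "load_spec", "dump_spec", "load_mass", "dump_mass",
    "RunManifest", "make_fixture_parametrization", "spec_hash",
]

_BUILTIN = {"wb": wb_spec, "sean": sean_spec}


def spec_hash(obj: dict) -> str:
    """Stable short hash of a configuration dictionary."""
    payload = json.dumps(obj, sort_keys=True, default=float).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def load_spec(source) -> NeuronModelSpec:
    """Load a NeuronModelSpec from YAML (path), a dict, or a builtin name.

    A YAML config may give only ``model: wb`` (or ``sean``) plus field
    overrides; canonical defaults fill the rest.  Schema violations raise
    an error naming the field.
    """
    if isinstance(source, str) and source.lower() in _BUILTIN:
        return _BUILTIN[source.lower()]()
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(source)
    if "model" in data:
        builder = _BUILTIN.get(str(data.pop("model")).lower())
        if builder is None:
            raise ValueError("model must be 'wb' or 'sean'")
        data.pop("schema_version", None)
        return builder(**data)
    return NeuronModelSpec.from_dict(data)


def dump_spec(spec: NeuronModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def load_mass(path) -> MassParametrization:
    with open(path) as fh:
        return MassParametrization.from_dict(yaml.safe_load(fh))


def dump_mass(param: MassParametrization, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(param.to_dict(), fh, sort_keys=False)


@dataclass
class RunManifest:
    """Provenance record written next to every CLI artifact."""

    command: str
    inputs: dict
    settings: dict
    schema_version: int = 1
    software: str = "mnm 0.1.0"
    timestamp: str = field(default_factory=lambda: datetime.datetime.now(
        datetime.timezone.utc).isoformat(timespec="seconds"))

    @property
    def input_hash(self) -> str:
        return spec_hash({"inputs": self.inputs, "settings": self.settings})

    def write(self, out_path) -> Path:
        path = Path(str(out_path) + ".manifest.yaml")
        d = asdict(self)
        d["input_hash"] = self.input_hash
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
        return path


def make_fixture_parametrization(mass_kind: str, seed: int = 0) -> MassParametrization:
    """Synthetic but structurally valid MassParametrization for fast tests.

    Coefficients are anchored at realistic magnitudes with small seeded
    jitter; thresholds satisfy i_th1 < i_th2 over the stated Δν_K window
    and the exponent/offset schema of the requested mass kind.  Same seed,
    same coefficients.
    """
    rng = np.random.default_rng(seed)
    jit = lambda s: 1.0 + s * rng.uniform(-1.0, 1.0)
    if mass_kind == "I":
        nu_hat = -90.0
        th1 = (0.014 * jit(0.05), 1.75 * jit(0.05))
        th2 = (-0.85 * jit(0.05), -51.0 * jit(0.05))
        m1 = (0.0, 0.0, -6.0 * jit(0.1), -100.0 * jit(0.1))     # Hz, gentle cubic
        m2 = (0.0, 0.3 * jit(0.1), 0.0)
        m3 = (-0.5 * jit(0.1), -25.0 * jit(0.1))
    elif mass_kind == "E":
        nu_hat = -75.0
        th1 = (0.002 * jit(0.05), 0.75 * jit(0.05))
        th2 = (-1.4 * jit(0.05), -14.0 * jit(0.05))
        m1 = (0.0, -2.0 * jit(0.1), 130.0 * jit(0.1))
        m2 = (0.0, 0.4 * jit(0.1), 0.0)
        m3 = (0.0, 0.0, 1.1 * jit(0.1), 110.0 * jit(0.1))
    else:
        raise ValueError("mass_kind must be 'I' or 'E'")
    param = MassParametrization(
        mass_kind=mass_kind, nu_k_hat=nu_hat,
        th1_coeffs=th1, th2_coeffs=th2,
        m1_coeffs=m1, m2_coeffs=m2, m3_coeffs=m3,
        fit_window=(0.0, 20.0),
        provenance=dict(fixture=True, seed=int(seed)))
    for d in (0.0, 10.0, 20.0):
        t1, t2, M1, *_ = param.thresholds_and_maxima(d, warn_extrapolation=False)
        assert t1 < t2 and M1 > 0, "fixture invariant violated"
    return param
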