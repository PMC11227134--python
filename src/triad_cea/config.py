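"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

_REQUIRED = ("n", "seed")

_DEFAULTS = {
    "out_dir": "triad_cea_run",
    "discount_rate": 0.03,
    "wtp": 23_000.0,
    "horizon_years": 70.0,
    "max_age": 110.0,
    "psa_samples": 1000,
    "psa_subsample": 2000,
    "n_knots": 4,
    "tau_months": 52.0,
    "sim_subsample": None,
    "no_discount": False,
    "all_outpatient_costs": False,
    "generator": None,
}

_TYPES = {
    "n": int, "seed": int, "out_dir": str, "discount_rate": (int, float),
    "wtp": (int, float), "horizon_years": (int, float), "max_age": (int, float),
    "psa_samples": int, "psa_subsample": (int, type(None)),
    "n_knots": int, "tau_months": (int, float),
    "sim_subsample": (int, type(None)),
    "no_discount": bool, "all_outpatient_costs": bool,
    "generator": (dict, type(None)),
}


@dataclass
class RunConfig:
    """Validated pipeline configuration with defaults filled in.

    ``no_discount`` re-runs the decision stage at a 0% rate;
    ``all_outpatient_costs`` is the cost reparametrization scenario in
    which the out-of-hospital daily cost reflects all outpatient care
    (implemented as a configurable scale-up of the generator's outpatient
    cost truth before fitting).
    """

    n: int
    seed: int
    out_dir: str = _DEFAULTS["out_dir"]
    discount_rate: float = _DEFAULTS["discount_rate"]
    wtp: float = _DEFAULTS["wtp"]
    horizon_years: float = _DEFAULTS["horizon_years"]
    max_age: float = _DEFAULTS["max_age"]
    psa_samples: int = _DEFAULTS["psa_samples"]
    psa_subsample: int | None = _DEFAULTS["psa_subsample"]
    n_knots: int = _DEFAULTS["n_knots"]
    tau_months: float = _DEFAULTS["tau_months"]
    sim_subsample: int | None = _DEFAULTS["sim_subsample"]
    no_discount: bool = False
    all_outpatient_costs: bool = False
    generator: dict | None = None

    def validate(self) -> None:
        for key, typ in _TYPES.items():
            v = getattr(self, key)
            if isinstance(typ, tuple):
                ok = isinstance(v, typ)
            else:
                ok = isinstance(v, typ) and not isinstance(v, bool) if typ is int \
                    else isinstance(v, typ)
            if not ok:
                raise TypeError(f"config key {key!r}: expected {typ}, got {type(v).__name__}")
        if self.n < 0:
            raise ValueError("config key 'n' must be >= 0")
        if self.discount_rate < 0:
            raise ValueError("config key 'discount_rate' must be >= 0")
        if self.psa_samples < 1:
            raise ValueError("config key 'psa_samples' must be >= 1")
        if self.n_knots < 2:
            raise ValueError("config key 'n_knots' must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected (naming the key) and missing required keys
    raise; everything else falls back to documented defaults.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise TypeError("config file must contain a mapping")
    known = set(_TYPES)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    for key in _REQUIRED:
        if key not in raw:
            raise ValueError(f"missing required config key: {key!r}")
    merged = {**_DEFAULTS, **raw}
    cfg = RunConfig(**merged)
    cfg.validate()
    return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
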