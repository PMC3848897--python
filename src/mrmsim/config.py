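"""Run configuration: YAML/JSON loading with validation and study defaults.

A config file is a flat mapping. Omitted fields take the standard study
defaults (L = 300, p_d = 0.2, C_e = 2.0, init_occupancy = 0.8,
t_max = 1000). Neighbourhoods use the figure-axis labels: ``"N"`` (von
Neumann), odd integers for Moore windows, ``"MF"`` (mean field; ``h`` only).
The community is given either as ``n`` (that many metabolic types with
k_i = 3 + 2i) or as an explicit ``types`` list of ``{k, metabolic}``
mappings; ``parasite_k`` appends parasite types.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .core import (
    ConfigurationError,
    Neighborhood,
    ReplicatorType,
    SimulationParams,
    default_types,
)

__all__ = ["RunConfig", "load_config", "config_to_dict"]

_PARAM_KEYS = {
    "L", "p_d", "C_e", "D", "init_occupancy", "t_max", "seed",
    "schedule", "metabolic_function", "update_sampling", "early_stop",
}
_EXTRA_KEYS = {
    "r", "h", "n", "types", "parasite_k",
    "output_dir", "snapshot_times", "census_every", "log_level",
}


@dataclass
class RunConfig:
    """SimulationParams plus artifact plumbing (output paths, snapshot and
    census schedules, logging)."""

    params: SimulationParams
    output_dir: Path = Path("mrm_out")
    snapshot_times: tuple[int, ...] = ()
    census_every: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.census_every < 1:
            raise ConfigurationError(
                f"census_every must be >= 1, got {self.census_every}"
            )
        for s in self.snapshot_times:
            if not 0 <= s <= self.params.t_max:
                raise ConfigurationError(
                    f"snapshot time {s} outside [0, t_max={self.params.t_max}]"
                )


def _build_types(raw: dict):
    if "types" in raw and "n" in raw:
        raise ConfigurationError("give either 'n' or 'types', not both")
    parasite_ks = raw.pop("parasite_k", [])
    if isinstance(parasite_ks, (int, float)):
        parasite_ks = [parasite_ks]
    if "types" in raw:
        spec = raw.pop("types")
        types = []
        for i, t in enumerate(spec):
            if not isinstance(t, dict) or "k" not in t:
                raise ConfigurationError(f"types[{i}] must be a mapping with 'k'")
            unknown = set(t) - {"k", "metabolic"}
            if unknown:
                raise ConfigurationError(f"types[{i}]: unknown keys {sorted(unknown)}")
            types.append(
                ReplicatorType(i + 1, float(t["k"]), bool(t.get("metabolic", True)))
            )
        base = len(types)
        types += [
            ReplicatorType(base + 1 + j, float(kp), False)
            for j, kp in enumerate(parasite_ks)
        ]
        return tuple(types)
    n = int(raw.pop("n", 4))
    return default_types(n, parasite_ks)


def dict_to_config(raw: dict) -> RunConfig:
    """Build a validated RunConfig from a plain mapping (see module docs)."""
    raw = dict(raw or {})
    unknown = set(raw) - _PARAM_KEYS - _EXTRA_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    try:
        if "r" in raw:
            kwargs["r_spec"] = Neighborhood.from_label(raw.pop("r"))
            if kwargs["r_spec"].is_mean_field:
                raise ConfigurationError("key 'r': replication neighborhood "
                                         "cannot be mean-field")
        if "h" in raw:
            kwargs["h_spec"] = Neighborhood.from_label(raw.pop("h"))
    except ConfigurationError as e:
        raise ConfigurationError(f"invalid neighborhood label: {e}") from None
    kwargs["types"] = _build_types(raw)
    out_dir = Path(raw.pop("output_dir", "mrm_out"))
    snaps = tuple(int(s) for s in raw.pop("snapshot_times", ()) or ())
    census_every = int(raw.pop("census_every", 1))
    log_level = str(raw.pop("log_level", "INFO"))
    for key in _PARAM_KEYS:
        if key in raw:
            kwargs[key] = raw.pop(key)
    try:
        params = SimulationParams(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigurationError(str(e)) from None
    return RunConfig(
        params=params, output_dir=out_dir, snapshot_times=snaps,
        census_every=census_every, log_level=log_level,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON, a YAML subset) config file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return dict_to_config(raw)


def config_to_dict(cfg: RunConfig) -> dict:
    """Inverse of dict_to_config for the documented keys (round-trips)."""
    p = cfg.params
    return {
        "L": p.L,
        "p_d": p.p_d,
        "C_e": p.C_e,
        "D": p.D,
        "r": p.r_spec.label,
        "h": p.h_spec.label,
        "types": [
            {"k": t.k, "metabolic": t.is_metabolic} for t in p.types
        ],
        "init_occupancy": p.init_occupancy,
        "t_max": p.t_max,
        "seed": p.seed,
        "schedule": p.schedule,
        "metabolic_function": p.metabolic_function,
        "update_sampling": p.update_sampling,
        "early_stop": p.early_stop,
        "output_dir": str(cfg.output_dir),
        "snapshot_times": list(cfg.snapshot_times),
        "census_every": cfg.census_every,
        "log_level": cfg.log_level,
    }
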