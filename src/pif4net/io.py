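"""Round-trip serialization of parameters, genotypes and protocols.

Everything is plain YAML (a JSON-compatible dialect): a scalar inhibition
strength is a number, a time-varying one is a mapping with the schedule
fields.  Loading validates through the dataclass constructors, so malformed
configurations fail with a :class:`~pif4net.errors.ConfigurationError`
naming the offending field.
"""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .model import GenotypeSpec, ParameterSet, Schedule
from .protocols import EnvironmentProtocol, GenotypeRegistry, Segment

__all__ = [
    "strength_to_obj", "strength_from_obj",
    "params_to_dict", "params_from_dict",
    "genotype_to_dict", "genotype_from_dict",
    "registry_to_dict", "registry_from_dict",
    "protocol_to_dict", "protocol_from_dict",
    "load_yaml", "save_yaml",
]

_SCHEDULE_KEYS = {"max_day", "min_val", "max_night", "D1", "D2"}


def strength_to_obj(value) -> Any:
    if isinstance(value, Schedule):
        return {f.name: getattr(value, f.name) for f in fields(Schedule)}
    return float(value)


def strength_from_obj(obj) -> Any:
    if isinstance(obj, Mapping):
        unknown = set(obj) - _SCHEDULE_KEYS
        if unknown:
            raise ConfigurationError(f"unknown schedule fields: {sorted(unknown)}")
        return Schedule(**obj)
    return float(obj)


def params_to_dict(params: ParameterSet) -> dict:
    d = asdict(params)
    d["pself"] = strength_to_obj(params.pself)
    d["pFP"] = strength_to_obj(params.pFP)
    d["temperature_variants"] = {
        label: {
            k: (strength_to_obj(v) if k in ("pself", "pFP") else v)
            for k, v in overrides.items()
        }
        for label, overrides in params.temperature_variants.items()
    }
    return d


def params_from_dict(d: Mapping) -> ParameterSet:
    d = dict(d)
    known = {f.name for f in fields(ParameterSet)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown parameter fields: {sorted(unknown)}")
    if "pself" in d:
        d["pself"] = strength_from_obj(d["pself"])
    if "pFP" in d:
        d["pFP"] = strength_from_obj(d["pFP"])
    variants = {}
    for label, overrides in dict(d.get("temperature_variants", {})).items():
        variants[str(label)] = {
            k: (strength_from_obj(v) if k in ("pself", "pFP") else v)
            for k, v in dict(overrides).items()
        }
    d["temperature_variants"] = variants
    try:
        return ParameterSet(**d)
    except TypeError as exc:  # missing required field
        raise ConfigurationError(str(exc)) from exc


def genotype_to_dict(g: GenotypeSpec) -> dict:
    d = {
        "name": g.name, "mutB": g.mutB, "mutE": g.mutE,
        "mutC": g.mutC, "mutP": g.mutP,
    }
    if g.overrides:
        d["overrides"] = {
            k: (strength_to_obj(v) if k in ("pself", "pFP") else v)
            for k, v in g.overrides.items()
        }
    return d


def genotype_from_dict(d: Mapping) -> GenotypeSpec:
    d = dict(d)
    overrides = {
        k: (strength_from_obj(v) if k in ("pself", "pFP") else v)
        for k, v in dict(d.pop("overrides", {})).items()
    }
    return GenotypeSpec(overrides=overrides, **d)


def registry_to_dict(registry: GenotypeRegistry) -> dict:
    return {name: genotype_to_dict(g) for name, g in registry.items()}


def registry_from_dict(d: Mapping) -> GenotypeRegistry:
    registry = {}
    for name, sub in d.items():
        sub = dict(sub)
        sub.setdefault("name", name)
        registry[name] = genotype_from_dict(sub)
    return registry


def protocol_to_dict(protocol: EnvironmentProtocol) -> dict:
    segs = []
    for s in protocol.segments:
        seg = {"duration": s.duration, "temperature": s.temperature}
        if s.day_length is not None:
            seg["day_length"] = s.day_length
        else:
            seg["light"] = s.light
        segs.append(seg)
    return {"segments": segs}


def protocol_from_dict(d: Mapping) -> EnvironmentProtocol:
    try:
        return EnvironmentProtocol([Segment(**seg) for seg in d["segments"]])
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"invalid protocol definition: {exc}") from exc


def load_yaml(path: str | Path) -> Any:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_yaml(obj: Any, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
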