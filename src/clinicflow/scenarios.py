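"""The what-if scenarios, encoded as data: field-path deltas on a config.

Scenario definitions ship in ``configs/scenarios.yaml``; user files in the
same schema can be loaded with :func:`load_scenarios`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import yaml

from .clinic_model import ClassId, ClinicConfig, ConfigError, StationId, packaged_config_path

__all__ = ["Scenario", "get_scenario", "apply_scenario", "load_scenarios", "all_scenario_ids"]


@dataclass(frozen=True)
class Scenario:
    """A named set of (field-path, new-value) deltas on a ClinicConfig."""

    id: int
    label: str
    deltas: tuple[tuple[str, object], ...] = field(default_factory=tuple)


def load_scenarios(path: str | Path) -> dict[int, Scenario]:
    data = yaml.safe_load(Path(path).read_text())
    out: dict[int, Scenario] = {}
    for entry in data["scenarios"]:
        sc = Scenario(
            id=int(entry["id"]),
            label=str(entry.get("label", f"scenario {entry['id']}")),
            deltas=tuple((d["path"], d["value"]) for d in entry.get("deltas", [])),
        )
        out[sc.id] = sc
    return out


@lru_cache(maxsize=1)
def _bundled() -> dict[int, Scenario]:
    return load_scenarios(packaged_config_path("scenarios.yaml"))


def all_scenario_ids() -> list[int]:
    return sorted(_bundled())


def get_scenario(scenario_id: int) -> Scenario:
    """Scenario by id; 0 is the base case (empty delta list)."""
    try:
        return _bundled()[int(scenario_id)]
    except KeyError:
        raise KeyError(f"unknown scenario id {scenario_id}") from None


def _resolve(config: ClinicConfig, path: str):
    """Resolve all but the last component of a dotted field path."""
    parts = path.split(".")
    obj: object = config
    i = 0
    while i < len(parts) - 1:
        part = parts[i]
        if isinstance(obj, ClinicConfig) and part in ("stations", "classes") and i + 2 < len(parts) + 1:
            key_raw = parts[i + 1]
            try:
                if part == "stations":
                    mapping, key = obj.stations, StationId(key_raw)
                else:
                    mapping, key = obj.classes, ClassId(key_raw)
            except ValueError:
                raise ConfigError(f"delta path {path!r}: unknown id {key_raw!r}") from None
            if key not in mapping:
                raise ConfigError(f"delta path {path!r}: {key} not in config")
            obj = mapping[key]
            i += 2
            continue
        if not hasattr(obj, part):
            raise ConfigError(f"delta path {path!r}: no field {part!r}")
        obj = getattr(obj, part)
        i += 1
    leaf = parts[-1]
    if i != len(parts) - 1 or not hasattr(obj, leaf):
        raise ConfigError(f"delta path {path!r}: no field {leaf!r}")
    return obj, leaf


def apply_scenario(config: ClinicConfig, scenario: Scenario) -> ClinicConfig:
    """Return a new config with the scenario's deltas applied.

    The input config is untouched; applying the base case (empty deltas)
    returns an equal config.  Deltas name fields by dotted path, e.g.
    ``stations.novice_resident.schedule.n_servers``.
    """
    new = config.copy()
    for path, value in scenario.deltas:
        obj, leaf = _resolve(new, path)
        current = getattr(obj, leaf)
        if isinstance(current, bool):
            value = bool(value)
        elif isinstance(current, int) and not isinstance(value, bool):
            value = int(value)
        elif isinstance(current, float):
            value = float(value)
        setattr(obj, leaf, value)
    new.validate()
    return new
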