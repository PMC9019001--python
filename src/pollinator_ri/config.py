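"""Scenario configuration: a flat YAML schema for communities and simulations.

Schema::

    f: 0.5                    # focal-plant frequency in (0, 1)
    pollinators:              # one entry per guild member
      - id: bee               # optional label
        rho: 0.8              # number in [-1, 1], or a named hook:
        # rho: {hook: linear, strength: 0.5}
        kappa: 0.0            # number in [-1, 1]
        phi: 0.5              # visit share; shares must sum to 1
    simulation:               # optional, only for `simulate`
      n_bouts: 200
      bout_length: 20
      seed: 1                 # may instead be given on the command line

Validation failures raise :class:`ConfigError` with a message naming the
offending key.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .behavior import DomainError
from .community import GuildMember, linear_preference

__all__ = ["ConfigError", "ScenarioConfig", "load_scenario", "parse_scenario"]

_HOOKS = {"linear": linear_preference}


class ConfigError(ValueError):
    """A scenario document is malformed; the message names the key."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Parsed scenario: frequency, guild and optional simulation settings."""

    f: float | None
    guild: tuple[GuildMember, ...]
    simulation: dict | None = None


def _parse_rho(raw, label: str):
    if isinstance(raw, dict):
        name = raw.get("hook")
        if name not in _HOOKS:
            raise ConfigError(
                f"pollinator {label!r}: unknown preference hook {name!r}; "
                f"available: {sorted(_HOOKS)}"
            )
        params = {k: v for k, v in raw.items() if k != "hook"}
        try:
            return _HOOKS[name](**params)
        except (TypeError, DomainError) as exc:
            raise ConfigError(f"pollinator {label!r}: bad hook parameters: {exc}") from exc
    if isinstance(raw, (int, float)):
        return float(raw)
    raise ConfigError(
        f"pollinator {label!r}: rho must be a number or a hook mapping, got {raw!r}"
    )


def parse_scenario(doc: dict) -> ScenarioConfig:
    """Validate a loaded scenario mapping into a :class:`ScenarioConfig`."""
    if not isinstance(doc, dict):
        raise ConfigError(f"scenario document must be a mapping, got {type(doc).__name__}")
    unknown = set(doc) - {"f", "pollinators", "simulation"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    f = doc.get("f")
    if f is not None:
        if not isinstance(f, (int, float)):
            raise ConfigError(f"f must be a number in (0, 1), got {f!r}")
        f = float(f)

    raw_pollinators = doc.get("pollinators")
    if not isinstance(raw_pollinators, list) or not raw_pollinators:
        raise ConfigError("'pollinators' must be a non-empty list")
    members = []
    for k, entry in enumerate(raw_pollinators):
        if not isinstance(entry, dict):
            raise ConfigError(f"pollinators[{k}] must be a mapping, got {entry!r}")
        label = str(entry.get("id", f"pollinator{k + 1}"))
        extra = set(entry) - {"id", "rho", "kappa", "phi"}
        if extra:
            raise ConfigError(f"pollinator {label!r}: unknown keys {sorted(extra)}")
        for key in ("rho", "kappa", "phi"):
            if key not in entry:
                raise ConfigError(f"pollinator {label!r}: missing required key {key!r}")
        try:
            members.append(
                GuildMember(
                    rho=_parse_rho(entry["rho"], label),
                    kappa=float(entry["kappa"]),
                    phi=float(entry["phi"]),
                    id=label,
                )
            )
        except (TypeError, ValueError) as exc:  # DomainError is a ValueError
            raise ConfigError(f"pollinator {label!r}: {exc}") from exc

    sim = doc.get("simulation")
    if sim is not None:
        if not isinstance(sim, dict):
            raise ConfigError("'simulation' must be a mapping")
        extra = set(sim) - {"n_bouts", "bout_length", "seed"}
        if extra:
            raise ConfigError(f"simulation: unknown keys {sorted(extra)}")
        sim = dict(sim)

    return ScenarioConfig(f=f, guild=tuple(members), simulation=sim)


def load_scenario(path) -> ScenarioConfig:
    """Load and validate a YAML scenario file."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read scenario file {path}: {exc}") from exc
    return parse_scenario(doc)
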