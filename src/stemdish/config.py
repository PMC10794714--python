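"""Run configuration: one validated object covering every parameter block.

``SimConfig`` groups the rate table defaults and the experiment knobs
(geometry, leading-signal scenario, death controller, phase schedule, stop
rule, output cadence).  It round-trips losslessly through YAML; unknown keys
are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import pathlib

import numpy as np
import yaml

from .adhesion import AdhesionConfig
from .death import DeathConfig
from .signals import LeadingSignalConfig, TerritorySignalParams
from .switches import PSwitchParams, SSwitchParams


@dataclasses.dataclass(frozen=True)
class EngineParams:
    """Constant per-cell reaction rates of the lattice engine."""

    r_s: float = 56.4      # stem-cell division
    w_p: float = 0.329     # S -> P transition
    m_s: float = 2.82      # stem-cell movement
    r_p: float = 32.9      # progenitor division
    w_s: float = 0.1645    # P -> S transition
    m_p: float = 0.94      # progenitor movement

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"engine rate {f.name} must be >= 0")


@dataclasses.dataclass
class SimConfig:
    radius: int = 100
    n_stem: int | None = None        # default: stem_fraction of the dish
    stem_fraction: float = 0.05
    seed: int = 0

    engine: EngineParams = dataclasses.field(default_factory=EngineParams)
    sswitch: SSwitchParams = dataclasses.field(default_factory=SSwitchParams)
    pswitch: PSwitchParams = dataclasses.field(default_factory=PSwitchParams)
    territory: TerritorySignalParams = dataclasses.field(
        default_factory=TerritorySignalParams)
    leading: LeadingSignalConfig = dataclasses.field(
        default_factory=LeadingSignalConfig)
    death: DeathConfig = dataclasses.field(default_factory=DeathConfig)
    adhesion: AdhesionConfig = dataclasses.field(default_factory=AdhesionConfig)

    #: reference density anchoring iota_xs(n); default 0.85 * in-dish meshes
    #: — the homeostatic occupancy, so stem self-renewal reactivates exactly
    #: when the tissue dips below its target density
    n_ref: float | None = None
    #: "table" = constant-rate diffusion propensity D/h^2 per mesh per
    #: direction as the rate table prints it; "mass_action" = (D/h^2)*count
    diffusion_kinetics: str = "table"
    #: phase-1 length: event count, or a time horizon if phase1_time is set
    phase1_iterations: int = 200_000
    phase1_time: float | None = None
    #: phase 2 -> 3 when both specialized counts reach this
    ab_threshold: int = 10
    #: stop when cumulative P divisions / time-averaged P count reaches this
    division_target: float = 50.0
    snapshot_events: int = 250_000
    max_events: int = 400_000_000
    max_time: float = float("inf")
    #: optional explicit leading-signal field (overrides leading.pattern)
    sl_field: np.ndarray | None = dataclasses.field(default=None, repr=False)

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if not 0 <= self.stem_fraction <= 1:
            raise ValueError("stem_fraction must be in [0, 1]")
        if self.division_target < 0 or self.snapshot_events <= 0:
            raise ValueError("division_target >= 0 and snapshot_events > 0 required")
        if self.diffusion_kinetics not in ("table", "mass_action"):
            raise ValueError("diffusion_kinetics must be 'table' or 'mass_action'")


_BLOCKS = {
    "engine": EngineParams,
    "sswitch": SSwitchParams,
    "pswitch": PSwitchParams,
    "territory": TerritorySignalParams,
    "leading": LeadingSignalConfig,
    "death": DeathConfig,
    "adhesion": AdhesionConfig,
}


def config_to_dict(cfg: SimConfig) -> dict:
    out = {}
    for f in dataclasses.fields(cfg):
        if f.name == "sl_field":
            continue  # numeric grids travel as CSV, not YAML
        v = getattr(cfg, f.name)
        out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
    return out


def config_from_dict(data: dict | None) -> SimConfig:
    data = dict(data or {})
    top_fields = {f.name for f in dataclasses.fields(SimConfig)}
    kwargs = {}
    for key, val in data.items():
        if key not in top_fields:
            raise ValueError(f"unknown configuration key: {key!r}")
        if key in _BLOCKS:
            cls = _BLOCKS[key]
            sub_fields = {f.name for f in dataclasses.fields(cls)}
            bad = set(val) - sub_fields
            if bad:
                raise ValueError(f"unknown keys in {key!r} block: {sorted(bad)}")
            kwargs[key] = cls(**val)
        else:
            kwargs[key] = val
    return SimConfig(**kwargs)


def load_config(path: str | pathlib.Path) -> SimConfig:
    """Read a YAML config; omitted blocks fall back to the rate-table defaults."""
    text = pathlib.Path(path).read_text()
    return config_from_dict(yaml.safe_load(text))


def save_config(cfg: SimConfig, path: str | pathlib.Path) -> None:
    pathlib.Path(path).write_text(
        yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
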