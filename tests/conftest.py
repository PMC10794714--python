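"""Shared fixtures: cached basin maps and reusable simulation runs.

Engine runs are the expensive resource, so every run that more than one test
consumes lives in a session-scoped fixture.
"""

from __future__ import annotations

import numpy as np
import pytest

from stemdish import SimConfig, run_simulation, switches
from stemdish.death import DeathConfig
from stemdish.fixtures import patterned_dish
from stemdish.signals import LeadingSignalConfig


@pytest.fixture(scope="session")
def base_maps():
    """Fate-labelled basin maps of both switches at reference parameters."""
    return switches.fate_maps()


@pytest.fixture(scope="session")
def map_families():
    return switches.fate_map_families()


def _half_run(seed: int):
    cfg = SimConfig(radius=25, seed=seed,
                    leading=LeadingSignalConfig(scenario="fixed", pattern="half"),
                    death=DeathConfig(mode="cube_root"),
                    phase1_time=0.0, division_target=10.0,
                    snapshot_events=500_000, max_events=100_000_000)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def half_pattern_runs():
    """Radius-25 half/half formation runs to 10 mean progenitor divisions."""
    return [_half_run(seed) for seed in (1, 2, 3, 4, 5)]


def maintenance_run(pattern: str, mode: str, seed: int, t_max: float,
                    radius: int = 15):
    """Homeostasis run started from an established pattern (phase 3)."""
    state, _ = patterned_dish(pattern, radius, seed=seed)
    cfg = SimConfig(radius=radius, seed=seed,
                    leading=LeadingSignalConfig(scenario="fixed", pattern=pattern),
                    death=DeathConfig(mode=mode),
                    division_target=0.0, snapshot_events=2_000_000,
                    max_events=500_000_000, max_time=t_max)
    return run_simulation(cfg, initial_state=state)


@pytest.fixture(scope="session")
def maintenance_shape_runs():
    """Long gaussian/stripe maintenance runs for the score-trace contrast."""
    return {(pat, seed): maintenance_run(pat, "cube_root", seed, 100.0)
            for pat in ("gaussian", "stripes") for seed in (1, 2)}


@pytest.fixture(scope="session")
def controller_runs():
    """Cube-root vs linear death control on the gaussian pattern, 5 seeds."""
    return {(mode, seed): maintenance_run("gaussian", mode, seed, 30.0)
            for mode in ("cube_root", "linear") for seed in (1, 2, 3, 4, 5)}


@pytest.fixture(scope="session")
def no_signal_run():
    """Radius-25 control run without any leading signal."""
    cfg = SimConfig(radius=25, seed=7,
                    leading=LeadingSignalConfig(scenario="none"),
                    death=DeathConfig(mode="fixed"),
                    phase1_time=0.0, division_target=10.0,
                    snapshot_events=500_000, max_events=100_000_000)
    return run_simulation(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
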