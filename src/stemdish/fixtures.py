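"""Programmatic fixtures: every experiment's initial condition at any scale.

All fixtures are generated from code and a seed — no external data.  They
reproduce the study's setups: a dish of randomly scattered stem cells, the
static leading-signal patterns, and a tiny hand-checkable dish for
brute-force verification of the scoring algorithm.
"""

from __future__ import annotations

import numpy as np

from . import lattice, signals, switches
from .lattice import A, B, DishState, S

FIXTURE_NAMES = ("random_stem_dish", "half_signal", "stripe_signal",
                 "spot_signal", "reversed_spot_signal", "gaussian_signal",
                 "checker_signal", "toy_6x6_score")


def make_fixture(name: str, size: int = 25, seed: int = 0,
                 stem_fraction: float = 0.05):
    """Deterministic-under-seed fixture by name.

    ``size`` is the dish radius (ignored by the toy scoring fixture).
    Returns a :class:`DishState` for cell fixtures, a signal field array for
    signal fixtures, and an ``(occupancy, field)`` pair for the toy scoring
    dish.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")
    if name == "random_stem_dish":
        s_map, _ = switches.fate_maps()
        pts = s_map.points(S)
        mask = lattice.dish_mask(size)
        n_stem = int(round(stem_fraction * mask.sum()))
        return lattice.init_dish(size, n_stem, pts, seed=seed)
    if name == "toy_6x6_score":
        return toy_score_dish()
    pattern = {"half_signal": "half", "stripe_signal": "stripes",
               "spot_signal": "spots", "reversed_spot_signal": "reversed_spots",
               "gaussian_signal": "gaussian", "checker_signal": "checker"}[name]
    return signals.fixed_pattern(pattern, size)


def patterned_dish(pattern: str, radius: int, seed: int = 0,
                   occupancy: float = 0.85, stem_frac: float = 0.04,
                   prog_frac: float = 0.06,
                   territory: "signals.TerritorySignalParams | None" = None
                   ) -> tuple[DishState, np.ndarray]:
    """Dish already organised in a leading-signal pattern, at homeostasis.

    Maintenance experiments start from an established pattern: A cells on
    the high-signal territory and B cells on the low one at the homeostatic
    ``occupancy``, a sprinkling of stem and progenitor cells, warm
    territorial signal fields at their local steady level (production/decay
    balance), and the leading field frozen (phase 3).  Returns the state and
    the leading-signal pattern.
    """
    from . import switches as sw

    field = signals.fixed_pattern(pattern, radius)
    state = lattice.empty_dish(radius)
    state.seed = seed
    rng = np.random.default_rng(seed)
    mask = state.mask
    occ = state.occ
    hi = (field > signals.PATTERN_MAX / 2) & mask
    lo = mask & ~hi
    u = rng.random(occ.shape)
    occ[hi & (u < occupancy)] = A
    occ[lo & (u < occupancy)] = B
    # sprinkle S and P over the remaining empties
    v = rng.random(occ.shape)
    empties = mask & (occ == lattice.EMPTY)
    rest = 1.0 - occupancy
    occ[empties & (v < stem_frac / rest)] = S
    occ[empties & (v >= stem_frac / rest)
        & (v < (stem_frac + prog_frac) / rest)] = lattice.P

    ts = territory or signals.TerritorySignalParams()
    steady = int(round(ts.alpha / ts.k))
    state.s1[hi] = steady
    state.s2[lo] = steady
    state.sl = field.copy()

    s_map, p_map = sw.fate_maps()
    for code, pts in ((S, s_map.points(S)), (lattice.P, p_map.points(lattice.P))):
        sel = occ == code
        k = int(sel.sum())
        if k:
            det = pts[rng.integers(0, len(pts), size=k)]
            state.xdet[sel] = det[:, 0]
            state.ydet[sel] = det[:, 1]
    state.phase = 3
    return state, field


def toy_score_dish() -> tuple[np.ndarray, np.ndarray]:
    """6x6 occupancy grid and leading field small enough to score by hand.

    The 'dish' is the central 4x4 block (the border ring is out-of-dish);
    the field splits it into a left high-signal half and a right low half,
    and a handful of A/B cells sit partly in and partly out of place.
    """
    occ = np.full((6, 6), lattice.OUT, dtype=np.int8)
    occ[1:5, 1:5] = lattice.EMPTY
    field = np.zeros((6, 6), dtype=np.int64)
    field[1:5, 1:3] = signals.PATTERN_MAX
    occ[1, 1] = A
    occ[2, 2] = A
    occ[3, 3] = B
    occ[4, 4] = B  # in-dish, low half: correctly placed B
    occ[2, 4] = A  # misplaced A in the low half
    return occ, field
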