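"""Pseudo-adhesion rules for the borderless (wall-free) variant.

Without a dish wall, cohesion comes from a minimal cell–matrix adhesion
model: the extracellular matrix is wherever signalling molecules are present
(total local S1 + S2 + S_l at or above a threshold) or inside the disc where
the founding stem cells were planted.  Off the matrix, division is
inhibited, apoptosis is triggered for every cell type (including S and P,
which never die in the walled model), and movement is damped.  Cells may
otherwise move and be born anywhere on the (large, open) grid.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .lattice import DishState, EMPTY, OUT


@dataclasses.dataclass(frozen=True)
class AdhesionConfig:
    enabled: bool = False
    matrix_threshold: int = 1      # molecules of S1+S2+S_l that define matrix
    movement_penalty: float = 0.1  # factor on movement propensity off-matrix
    apoptosis_rate: float = 0.1    # added death propensity off-matrix
    grid_factor: float = 3.0       # open-grid side = grid_factor * seed diameter

    def __post_init__(self):
        if self.matrix_threshold < 0:
            raise ValueError("matrix_threshold must be >= 0")
        if not 0 <= self.movement_penalty <= 1:
            raise ValueError("movement_penalty must be in [0, 1]")
        if self.apoptosis_rate < 0:
            raise ValueError("apoptosis_rate must be >= 0")


def seed_disc_mask(side: int, seed_radius: int) -> np.ndarray:
    """Disc at the grid centre where the founding population was planted."""
    c = side // 2
    rr, cc = np.mgrid[0:side, 0:side]
    return (rr - c) ** 2 + (cc - c) ** 2 <= seed_radius**2


def matrix_mask(state: DishState, config: AdhesionConfig,
                seed_disc: np.ndarray | None = None) -> np.ndarray:
    """Meshes counting as extracellular matrix under the adhesion rules."""
    if not config.enabled:
        raise ValueError("adhesion is not enabled")
    total = state.s1 + state.s2 + state.sl
    mask = total >= config.matrix_threshold
    if seed_disc is not None:
        mask = mask | seed_disc
    return mask


def adhesion_adjust(propensities: dict[str, float], on_matrix: bool,
                    occupant: int, config: AdhesionConfig) -> dict[str, float]:
    """Apply the adhesion rules to one cell's propensity contributions.

    ``propensities`` maps channel names (``division``, ``movement``, ...) to
    rates; on-matrix cells are untouched, off-matrix cells lose division,
    have movement multiplied by the penalty, and gain an ``apoptosis``
    channel regardless of type.
    """
    if not config.enabled:
        raise ValueError("adhesion is not enabled")
    out = dict(propensities)
    if on_matrix or occupant in (EMPTY, OUT):
        return out
    if "division" in out:
        out["division"] = 0.0
    if "movement" in out:
        out["movement"] = out["movement"] * config.movement_penalty
    out["apoptosis"] = config.apoptosis_rate
    return out
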