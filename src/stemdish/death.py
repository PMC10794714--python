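"""Adaptive death-rate control for the specialized cells.

Death of A/B cells is the only removal channel in the model, so their death
rates gamma_A/gamma_B set the homeostatic abundances.  Target abundances
n*_A/n*_B are read off the leading-signal pattern (its high-signal fraction
p of the dish is the intended A territory) under the constraint that stem
cells, progenitors and empty meshes together occupy at most 15% of the dish.
Three feedback controllers map the instantaneous abundance n_i onto a death
rate:

* ``step``   — low rate below target, high rate above (0.05 / 0.1);
* ``linear`` — gamma_i = (n_i / n*_i) * v_g;
* ``cube_root`` — gamma_i = (n_i / n*_i)^(1/3) * v_g, which reacts much more
  strongly to small deviations and therefore tracks the target more tightly.

A fourth, non-adaptive mode ``fixed`` applies constant rates (the model's
rate table reports the time-averaged realized values 0.003 / 0.0034); it is
used when no leading pattern defines a target, e.g. the no-signal control
experiment.
"""

from __future__ import annotations

import dataclasses

import numpy as np

DEATH_MODES = ("step", "linear", "cube_root", "fixed")


@dataclasses.dataclass(frozen=True)
class DeathConfig:
    mode: str = "cube_root"
    v_g: float = 0.0125
    step_low: float = 0.05
    step_high: float = 0.1
    occupancy_fraction: float = 0.85
    n_star_A: float | None = None   # filled from the leading pattern if None
    n_star_B: float | None = None
    gamma_A_fixed: float = 0.003
    gamma_B_fixed: float = 0.0034

    def __post_init__(self):
        if self.mode not in DEATH_MODES:
            raise ValueError(f"mode must be one of {DEATH_MODES}")
        if not self.step_low < self.step_high:
            raise ValueError("step_low must be < step_high")
        if not 0 < self.occupancy_fraction <= 1:
            raise ValueError("occupancy_fraction must be in (0, 1]")


def target_abundances(s_l_field: np.ndarray, dish_mask: np.ndarray,
                      occupancy_fraction: float = 0.85,
                      threshold: float = 125.0) -> tuple[float, float]:
    """Target A/B abundances implied by a leading-signal pattern.

    ``p`` is the fraction of in-dish meshes with signal above half the
    pattern maximum (the same threshold as the scoring template);
    ``n*_A = p * occupancy_fraction * N`` and
    ``n*_B = (1 - p) * occupancy_fraction * N`` with N the in-dish mesh
    count, so together the specialized cells fill ``occupancy_fraction`` of
    the dish.
    """
    s_l_field = np.asarray(s_l_field)
    dish_mask = np.asarray(dish_mask, dtype=bool)
    if s_l_field.shape != dish_mask.shape:
        raise ValueError("field and mask shapes differ")
    n_tot = int(dish_mask.sum())
    if n_tot == 0:
        raise ValueError("empty dish")
    p = float((s_l_field[dish_mask] > threshold).mean())
    return p * occupancy_fraction * n_tot, (1.0 - p) * occupancy_fraction * n_tot


def death_rate(n_i: int, n_star_i: float, config: DeathConfig) -> float:
    """Death rate of one specialized cell type at abundance ``n_i``."""
    if config.mode == "fixed":
        return config.gamma_A_fixed  # caller picks per-type constant; see engine
    if n_star_i is None or n_star_i <= 0:
        raise ValueError("n_star_i must be positive for adaptive death modes")
    if config.mode == "step":
        return config.step_low if n_i < n_star_i else config.step_high
    ratio = n_i / n_star_i
    if config.mode == "linear":
        return ratio * config.v_g
    return ratio ** (1.0 / 3.0) * config.v_g


def flux_balance_rate(n_p_star: float, lam: float, mu_d: float, mu_i: float,
                      n_i: float) -> float:
    """Death rate that balances the production flux of one specialized type.

    ``gamma_i = n_P* (lambda_i + mu_d + 2 mu_i) / n_i`` makes the mean-field
    time derivative of n_i vanish.
    """
    if n_i <= 0:
        raise ValueError("n_i must be positive")
    return n_p_star * (lam + mu_d + 2.0 * mu_i) / n_i
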