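"""Signal fields: territorial S1/S2, the leading signal S_l and its partner S_a.

Three signal families live on the lattice as integer molecule counts evolved
by the same Gillespie machinery as the cells:

* **Territorial signals S1/S2** — secreted by A and B cells respectively,
  with mutual Hill repression of production, first-order decay and
  diffusion.  They let specialized cells defend their territory.
* **Leading signal S_l** — the symmetry-breaking field.  Scenarios:
  ``fixed`` (a static user/fixture pattern), ``diffusive`` (secretion by
  population cells, decay, diffusion), or ``turing`` (a two-species
  activator–substrate system with linear reaction terms and hard clipping of
  S_l to ``[s_lower, s_upper]``, which produces reversed-spot / stripe /
  spot patterns depending on the diffusivities and the clip ceiling).
* **Turing partner S_a** — the fast-diffusing partner species of the Turing
  scenario.

The functions here return the per-mesh propensity contributions; they are the
reference semantics that the compiled engine kernel mirrors (a test holds the
two together).  Diffusion follows the rate table's convention by default — a
constant propensity ``D/h^2`` per occupied mesh per in-dish neighbour
direction — with the mass-action form ``(D/h^2) * count`` available as an
option; either way one event moves one molecule to a uniformly chosen
in-dish neighbour, so the dish wall reflects and diffusion-only dynamics
conserve molecules exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .lattice import A, B, OUT, dish_mask

SCENARIOS = ("none", "fixed", "diffusive", "turing")
PATTERN_NAMES = ("half", "stripes", "spots", "reversed_spots", "gaussian",
                 "checker", "none")

#: peak molecule count of the static leading-signal patterns
PATTERN_MAX = 250


@dataclasses.dataclass(frozen=True)
class TerritorySignalParams:
    alpha: float = 220.0  # production rate at zero repressor
    beta: float = 2.0     # Hill half-saturation of mutual repression
    hill_n: float = 4.0
    k: float = 0.5        # decay rate
    D: float = 110.0      # diffusion coefficient
    h: float = 1.0        # mesh size

    def __post_init__(self):
        if min(self.alpha, self.beta, self.k, self.D, self.h) <= 0:
            raise ValueError("territory-signal rates must be positive")


@dataclasses.dataclass(frozen=True)
class LeadingSignalConfig:
    scenario: str = "none"
    pattern: str = "none"        # fixture name for the fixed scenario
    alpha_sl: float = 1.0e4      # diffusive-scenario production rate
    k_sl: float = 0.0            # diffusive-scenario decay
    D_sl: float = 2.5e5          # diffusive-scenario diffusion
    d_l: float = 1.0e4           # Turing: S_l diffusion
    d_a: float = 2.0e5           # Turing: S_a diffusion
    gamma_sl: float = 1.0e4      # Turing reaction scale for S_l
    gamma_sa: float = 1.0e4      # Turing reaction scale for S_a
    A: float = 0.9               # f(s_l, s_a) = A*s_l - s_a + C
    B: float = 1.2               # g(s_l, s_a) = B*s_l - s_a - 1
    C: float = 0.2
    s_upper: int = 10
    s_lower: int = 0
    sources: str = "cells"       # diffusive production: "cells" or "all"

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.s_lower >= self.s_upper:
            raise ValueError("s_lower must be < s_upper")
        if min(self.alpha_sl, self.D_sl, self.d_l, self.d_a,
               self.gamma_sl, self.gamma_sa) < 0 or self.k_sl < 0:
            raise ValueError("leading-signal rates must be non-negative")
        if self.sources not in ("cells", "all"):
            raise ValueError("sources must be 'cells' or 'all'")


# ---------------------------------------------------------------------------
# per-mesh propensities (reference semantics)

def diffusion_propensity(rate: float, count: int, n_nbr: int,
                         kinetics: str = "table") -> float:
    """Per-mesh diffusion propensity under either kinetics convention.

    ``table``: the rate-table form, a constant rate per occupied mesh per
    neighbour direction (zero at zero count); ``mass_action``: the usual
    reaction–diffusion master-equation form, rate per molecule per
    direction.  Either way one event moves one molecule to one uniformly
    chosen in-dish neighbour.
    """
    if kinetics == "table":
        return rate * n_nbr if count > 0 else 0.0
    return rate * count * n_nbr


def territory_propensities(occupant: int, s1: int, s2: int, n_nbr: int,
                           params: TerritorySignalParams,
                           kinetics: str = "table") -> dict[str, float]:
    """Propensities of the S1/S2 reactions at one in-dish mesh."""
    if occupant == OUT:
        raise ValueError("mesh is outside the dish")
    n = params.hill_n
    bn = params.beta ** n
    D = params.D / params.h**2
    out = {
        "s1_prod": params.alpha * bn / (bn + float(s2) ** n) if occupant == A else 0.0,
        "s2_prod": params.alpha * bn / (bn + float(s1) ** n) if occupant == B else 0.0,
        "s1_deg": params.k * s1,
        "s2_deg": params.k * s2,
        "s1_diff": diffusion_propensity(D, s1, n_nbr, kinetics),
        "s2_diff": diffusion_propensity(D, s2, n_nbr, kinetics),
    }
    return out


def leading_propensities(occupant: int, sl: int, sa: int, n_nbr: int,
                         cfg: LeadingSignalConfig, phase: int,
                         kinetics: str = "table") -> dict[str, float]:
    """Propensities of the S_l reactions at one mesh for the given phase.

    In phase 3 the leading signal is switched off entirely; in the fixed (or
    absent) scenario it has no reactions in any phase.
    """
    zero = {"sl_prod": 0.0, "sl_deg": 0.0, "sl_diff": 0.0}
    if phase >= 3 or cfg.scenario in ("none", "fixed"):
        return zero
    if cfg.scenario == "diffusive":
        occupied = occupant in (1, 2, 3, 4)
        prod = cfg.alpha_sl if (occupied or cfg.sources == "all") else 0.0
        return {"sl_prod": prod, "sl_deg": cfg.k_sl * sl,
                "sl_diff": diffusion_propensity(cfg.D_sl, sl, n_nbr, kinetics)}
    # turing: birth gamma*(A*sl + C), death gamma*sa, both clipped at the bounds
    prod = cfg.gamma_sl * (cfg.A * sl + cfg.C) if sl < cfg.s_upper else 0.0
    deg = cfg.gamma_sl * sa if sl > cfg.s_lower else 0.0
    diff = diffusion_propensity(cfg.d_l, sl, n_nbr, kinetics) \
        if sl > cfg.s_lower else 0.0
    return {"sl_prod": prod, "sl_deg": deg, "sl_diff": diff}


def partner_propensities(sl: int, sa: int, n_nbr: int,
                         cfg: LeadingSignalConfig, phase: int = 1,
                         kinetics: str = "table") -> dict[str, float]:
    """Propensities of the Turing partner S_a at one mesh."""
    if cfg.scenario != "turing" or phase >= 3:
        return {"sa_prod": 0.0, "sa_deg": 0.0, "sa_diff": 0.0}
    return {
        "sa_prod": cfg.gamma_sa * cfg.B * sl,
        "sa_deg": cfg.gamma_sa * (sa + 1),
        "sa_diff": diffusion_propensity(cfg.d_a, sa, n_nbr, kinetics),
    }


# ---------------------------------------------------------------------------
# static leading-signal patterns

def fixed_pattern(name: str, radius: int) -> np.ndarray:
    """Static leading-signal field on a radius-``radius`` dish.

    Binary patterns take values {0, 250}; ``gaussian`` is graded with peak
    250 at the centre.  Out-of-dish meshes are 0.
    """
    if name not in PATTERN_NAMES:
        raise ValueError(f"unknown pattern {name!r}; valid names: {PATTERN_NAMES}")
    mask = dish_mask(radius)
    side = mask.shape[0]
    c = side // 2
    rr, cc = np.mgrid[0:side, 0:side]
    field = np.zeros((side, side), dtype=np.int64)
    if name == "half":
        field[cc < c] = PATTERN_MAX
    elif name == "stripes":
        width = max(3, int(round(side / 6)))
        field[(cc // width) % 2 == 0] = PATTERN_MAX
    elif name in ("spots", "reversed_spots"):
        rho = max(2, radius // 5)
        pitch = 4 * rho
        on = np.zeros_like(mask)
        for pr in range(0, side + pitch, pitch):
            for pc in range(0, side + pitch, pitch):
                on |= (rr - pr) ** 2 + (cc - pc) ** 2 <= rho**2
        if name == "spots":
            field[on] = PATTERN_MAX
        else:
            field[~on] = PATTERN_MAX
    elif name == "gaussian":
        sigma = radius / 2.0
        d2 = (rr - c) ** 2 + (cc - c) ** 2
        field = np.rint(PATTERN_MAX * np.exp(-d2 / (2 * sigma**2))).astype(np.int64)
        field[c, c] = PATTERN_MAX
    elif name == "checker":
        block = max(3, radius // 2)
        field[((rr // block) + (cc // block)) % 2 == 0] = PATTERN_MAX
    field[~mask] = 0
    return field


def generate_turing_field(radius: int, cfg: LeadingSignalConfig, seed: int,
                          horizon: float) -> np.ndarray:
    """Mature a stochastic Turing field on an empty dish and return S_l.

    Runs the engine with no cells and the Turing scenario for ``horizon``
    time units.  The returned integer field lies in ``[s_lower, s_upper]``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    from .config import SimConfig
    from .engine import run_simulation

    cfg = dataclasses.replace(cfg, scenario="turing")
    sim = SimConfig(radius=radius, n_stem=0, seed=seed, leading=cfg,
                    phase1_time=horizon, division_target=0.0, max_events=2**62)
    traj = run_simulation(sim, phases=(1,))
    return traj.final_state.sl.copy()


def turing_uniform_start(cfg: LeadingSignalConfig) -> tuple[int, int]:
    """Homogeneous reaction fixed point of the Turing system, clipped to bounds.

    Solves ``A s + C = s_a`` and ``B s - 1 = s_a`` and rounds to integers;
    stochasticity supplies the symmetry-breaking perturbations.
    """
    denom = cfg.B - cfg.A
    s = (1.0 + cfg.C) / denom if denom > 0 else 0.5 * (cfg.s_lower + cfg.s_upper)
    s = int(round(np.clip(s, cfg.s_lower, cfg.s_upper)))
    sa = max(int(round(cfg.B * s - 1)), 0)
    return s, sa
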