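"""Dish geometry and lattice state.

The tissue lives on a square grid of unit meshes ("pixels"). A circular dish
of a given radius is carved out of the grid; meshes outside the dish exist in
the arrays but are inert. Each mesh can hold at most one cell (stem cell S,
progenitor P, or terminally differentiated A/B), two integer determinant
counts for the occupant's internal regulatory switch, and integer molecule
counts for the four diffusing signal species (territorial signals S1/S2, the
leading signal S_l and its Turing partner S_a).

Conventions
-----------
* grid side = ``2 * radius + 1``; the dish is centred at ``(radius, radius)``;
  coordinates are 0-based, row-major.
* occupancy codes: ``-1`` out-of-dish, ``0`` empty, ``1`` S, ``2`` P, ``3`` A,
  ``4`` B.
* connectivity is 4-neighbour (von Neumann); the dish wall reflects, i.e.
  molecules never diffuse out of the dish and cells are never placed outside.
"""

from __future__ import annotations

import dataclasses
import pathlib

import numpy as np

OUT = -1
EMPTY = 0
S = 1
P = 2
A = 3
B = 4

CELL_NAMES = {OUT: "out", EMPTY: "empty", S: "S", P: "P", A: "A", B: "B"}

#: figure palette: S cyan, P green, A yellow, B red, empty blue, out-of-dish gray
CELL_COLORS = {
    OUT: (0.6, 0.6, 0.6),
    EMPTY: (0.10, 0.20, 0.80),
    S: (0.0, 0.85, 0.85),
    P: (0.05, 0.65, 0.10),
    A: (0.95, 0.85, 0.05),
    B: (0.85, 0.10, 0.10),
}

SIGNAL_FIELDS = ("s1", "s2", "sl", "sa")


class CapacityError(ValueError):
    """More cells requested than the dish can hold."""


def dish_mask(radius: int, side: int | None = None) -> np.ndarray:
    """Boolean mask of in-dish meshes: Euclidean distance to centre <= radius."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if side is None:
        side = 2 * radius + 1
    c = side // 2
    rr, cc = np.mgrid[0:side, 0:side]
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2


def neighbor_table(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Compacted von Neumann neighbour table restricted to ``mask``.

    Returns ``(nbr, nnbr)`` where ``nbr`` has shape ``(N, 4)`` over flattened
    meshes; row ``i`` lists the flat indices of the in-mask neighbours of mesh
    ``i`` in its first ``nnbr[i]`` slots and ``-1`` elsewhere.  Out-of-mask
    meshes have no neighbours.  Because a mesh adjacent to the wall simply has
    fewer neighbours, diffusion built on this table reflects at the wall and
    conserves molecules.
    """
    side_r, side_c = mask.shape
    n = mask.size
    nbr = np.full((n, 4), -1, dtype=np.int32)
    nnbr = np.zeros(n, dtype=np.int8)
    flat = mask.ravel()
    for i in range(n):
        if not flat[i]:
            continue
        r, c = divmod(i, side_c)
        k = 0
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < side_r and 0 <= c2 < side_c and mask[r2, c2]:
                nbr[i, k] = r2 * side_c + c2
                k += 1
        nnbr[i] = k
    return nbr, nnbr


def neighbors(rc: tuple[int, int], mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Von Neumann neighbours of grid location ``rc`` (clipped at the grid edge).

    Each entry is ``(row, col, in_dish)``; ``in_dish=False`` flags a
    neighbour beyond the dish wall so callers can treat the wall as
    reflecting.
    """
    r, c = rc
    side_r, side_c = mask.shape
    if not (0 <= r < side_r and 0 <= c < side_c):
        raise IndexError(f"mesh {rc} outside the grid")
    out = []
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        r2, c2 = r + dr, c + dc
        if 0 <= r2 < side_r and 0 <= c2 < side_c:
            out.append((r2, c2, bool(mask[r2, c2])))
    return out


@dataclasses.dataclass
class DishState:
    """Full lattice state: occupancy, determinants, signals and the clock."""

    radius: int
    occ: np.ndarray        # int8 (side, side)
    xdet: np.ndarray       # int64
    ydet: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    sl: np.ndarray
    sa: np.ndarray
    time: float = 0.0
    phase: int = 1
    seed: int | None = None

    @property
    def side(self) -> int:
        return self.occ.shape[0]

    @property
    def mask(self) -> np.ndarray:
        return self.occ != OUT

    def abundances(self) -> tuple[int, int, int, int]:
        return recount_abundances(self)

    def copy(self) -> "DishState":
        return DishState(
            radius=self.radius,
            occ=self.occ.copy(), xdet=self.xdet.copy(), ydet=self.ydet.copy(),
            s1=self.s1.copy(), s2=self.s2.copy(), sl=self.sl.copy(),
            sa=self.sa.copy(), time=self.time, phase=self.phase, seed=self.seed,
        )


def empty_dish(radius: int) -> DishState:
    mask = dish_mask(radius)
    side = mask.shape[0]
    occ = np.where(mask, EMPTY, OUT).astype(np.int8)
    z = lambda: np.zeros((side, side), dtype=np.int64)  # noqa: E731
    return DishState(radius=radius, occ=occ, xdet=z(), ydet=z(),
                     s1=z(), s2=z(), sl=z(), sa=z())


def init_dish(radius: int, n_stem: int, s_basin_points: np.ndarray,
              seed: int | None = None) -> DishState:
    """Seed a dish with ``n_stem`` stem cells at random in-dish meshes.

    Each stem cell's determinant pair is drawn uniformly from the integer
    points of the stem-fate basin of the stem-cell switch
    (``s_basin_points``, an ``(m, 2)`` array of (x, y) counts).
    """
    state = empty_dish(radius)
    state.seed = seed
    mask = state.mask
    in_idx = np.flatnonzero(mask.ravel())
    if n_stem > in_idx.size:
        raise CapacityError(
            f"n_stem={n_stem} exceeds dish capacity {in_idx.size}")
    if n_stem == 0:
        return state
    if s_basin_points.ndim != 2 or s_basin_points.shape[1] != 2 or not len(s_basin_points):
        raise ValueError("s_basin_points must be a non-empty (m, 2) array")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(in_idx, size=n_stem, replace=False)
    det_idx = rng.integers(0, len(s_basin_points), size=n_stem)
    occ = state.occ.ravel()
    xd = state.xdet.ravel()
    yd = state.ydet.ravel()
    occ[chosen] = S
    xd[chosen] = s_basin_points[det_idx, 0]
    yd[chosen] = s_basin_points[det_idx, 1]
    return state


def recount_abundances(state: DishState) -> tuple[int, int, int, int]:
    """Counts of (S, P, A, B) by full grid scan."""
    occ = state.occ
    return (int((occ == S).sum()), int((occ == P).sum()),
            int((occ == A).sum()), int((occ == B).sum()))


# ---------------------------------------------------------------------------
# serialization / rendering

def save_state(state: DishState, directory: str | pathlib.Path) -> None:
    """Write occupancy and all signal fields as CSV grids."""
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "occupancy.csv", state.occ, fmt="%d", delimiter=",")
    for name in SIGNAL_FIELDS:
        np.savetxt(d / f"{name}.csv", getattr(state, name), fmt="%d", delimiter=",")
    (d / "meta.csv").write_text(
        f"radius,time,phase\n{state.radius},{state.time!r},{state.phase}\n")


def load_state(directory: str | pathlib.Path) -> DishState:
    d = pathlib.Path(directory)
    occ = np.loadtxt(d / "occupancy.csv", dtype=np.int8, delimiter=",")
    fields = {name: np.loadtxt(d / f"{name}.csv", dtype=np.int64, delimiter=",")
              for name in SIGNAL_FIELDS}
    meta = (d / "meta.csv").read_text().strip().splitlines()[1].split(",")
    side = occ.shape[0]
    state = DishState(radius=int(meta[0]), occ=occ,
                      xdet=np.zeros((side, side), np.int64),
                      ydet=np.zeros((side, side), np.int64),
                      s1=fields["s1"], s2=fields["s2"],
                      sl=fields["sl"], sa=fields["sa"],
                      time=float(meta[1]), phase=int(meta[2]))
    return state


def render_state(state_or_occ, path: str | pathlib.Path | None = None):
    """Render an occupancy grid as an RGB image with the standard palette."""
    occ = state_or_occ.occ if isinstance(state_or_occ, DishState) else np.asarray(state_or_occ)
    img = np.zeros(occ.shape + (3,), dtype=float)
    for code, color in CELL_COLORS.items():
        img[occ == code] = color
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(img, interpolation="nearest")
        ax.set_axis_off()
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return img
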