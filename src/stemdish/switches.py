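"""Deterministic skeletons of the cells' internal regulatory switches.

Stem cells carry a two-determinant bistable switch (mutual Hill repression of
X_s and Y_s); its two stable states correspond to the S and P fates.
Progenitor cells carry a two-determinant tristable switch (Hill
self-activation plus mutual repression of X_p and Y_p); its three stable
states correspond to the P, A and B fates.  A newborn cell's fate is read off
the basin of attraction in which its inherited determinant counts land.

Extracellular signals act on the progenitor switch through additive
"signalling effect" coefficients eps_1/eps_2 on the self-activation rates:
the leading signal S_l biases the first territorial decision, while the
territorial signals S1/S2 lock cells into their own territory afterwards.

The stem switch's X_s synthesis rate iota_xs falls with the total cell
density n; this is the negative feedback that makes the symmetric
self-renewal rate a decreasing function of density and stabilises the
homeostatic state.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np
from scipy import ndimage, optimize

from .lattice import A, B, P, S

STABLE = "stable"
SADDLE = "saddle"
UNSTABLE = "unstable"
UNRESOLVED = 0


@dataclasses.dataclass(frozen=True)
class SSwitchParams:
    """Stem-cell bistable switch (defaults from the model's rate table)."""

    iota_x: float = 85.0    # base X_s synthesis rate, modulated by density
    iota_y: float = 100.0   # Y_s synthesis rate
    beta: float = 45.0      # Hill half-saturation of the mutual repression
    hill_n: float = 4.0
    gamma: float = 1.0      # determinant degradation rate
    n_ref_exp: float = 4.0  # exponent of the density feedback on iota_x

    def __post_init__(self):
        if min(self.iota_x, self.iota_y, self.beta, self.gamma) <= 0:
            raise ValueError("all S-switch rates must be strictly positive")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")


@dataclasses.dataclass(frozen=True)
class PSwitchParams:
    """Progenitor tristable switch plus the signalling-effect coefficients."""

    alpha_x: float = 30.0
    alpha_y: float = 30.0
    iota_x: float = 30.0
    iota_y: float = 30.0
    beta: float = 47.5
    hill_n: float = 4.0
    gamma: float = 0.38
    eps_a: float = 30.0    # scale of the signalling effect (saturation value)
    eps_b: float = 100.0   # molecule count at which g(S_i) saturates
    sl_max: float = 250.0  # leading-signal scale used for the complementary response

    def __post_init__(self):
        if min(self.alpha_x, self.alpha_y, self.iota_x, self.iota_y,
               self.beta, self.gamma, self.eps_a, self.eps_b) <= 0:
            raise ValueError("all P-switch rates must be strictly positive")


@dataclasses.dataclass
class FixedPoint:
    x: float
    y: float
    stability: str
    eigenvalues: tuple[complex, complex] | None = None
    fate_label: int | None = None


@dataclasses.dataclass
class BasinMap:
    """Fate labels over the integer lattice of the (x, y) determinant plane.

    ``labels[xi, yi]`` is the fate code of the stable fixed point reached by
    forward integration started from ``(xi * resolution, yi * resolution)``;
    0 marks unresolved points (only possible before hole-filling).
    """

    labels: np.ndarray
    resolution: float
    fixed_points: list[FixedPoint]

    def points(self, label: int) -> np.ndarray:
        """Integer (x, y) determinant pairs belonging to basin ``label``."""
        xi, yi = np.nonzero(self.labels == label)
        pts = np.stack([xi, yi], axis=1).astype(np.int32)
        return (pts * self.resolution).astype(np.int32) if self.resolution != 1 else pts

    def to_csv(self, path) -> None:
        np.savetxt(path, self.labels, fmt="%d", delimiter=",")


# ---------------------------------------------------------------------------
# right-hand sides

def _check_nonneg(*vals):
    for v in vals:
        if np.any(np.asarray(v) < 0):
            raise ValueError("determinant/signal values must be non-negative")


def s_switch_rhs(x, y, params: SSwitchParams, iota_x_eff: float | None = None):
    """Time derivatives (dx, dy) of the stem-cell switch.

    ``iota_x_eff`` is the density-modulated X_s synthesis rate; the base
    ``params.iota_x`` is used when it is omitted.
    """
    _check_nonneg(x, y)
    if iota_x_eff is None:
        iota_x_eff = params.iota_x
    bn = params.beta ** params.hill_n
    dx = iota_x_eff * bn / (bn + np.asarray(y, float) ** params.hill_n) - params.gamma * x
    dy = params.iota_y * bn / (bn + np.asarray(x, float) ** params.hill_n) - params.gamma * y
    return dx, dy


def iota_x_of_n(n_total, params: SSwitchParams, n_ref: float):
    """Density-dependent X_s synthesis rate, anchored to the base value at n_ref.

    A decreasing Hill form ``2 * iota_x * n_ref^k / (n_ref^k + n^k)`` (k =
    ``params.n_ref_exp``): it equals ``2 * iota_x`` at zero density,
    ``iota_x`` at the reference density, and falls monotonically to 0.
    """
    if n_ref <= 0:
        raise ValueError("n_ref must be positive")
    n = np.asarray(n_total, dtype=float)
    k = params.n_ref_exp
    return 2.0 * params.iota_x * n_ref**k / (n_ref**k + n**k)


def p_switch_rhs(x, y, params: PSwitchParams, eps1: float = 0.0, eps2: float = 0.0):
    """Time derivatives (dx, dy) of the progenitor switch."""
    _check_nonneg(x, y, eps1, eps2)
    n = params.hill_n
    bn = params.beta ** n
    xf = np.asarray(x, float) ** n
    yf = np.asarray(y, float) ** n
    dx = (params.alpha_x + eps1) * xf / (bn + xf) + params.iota_x * bn / (bn + yf) \
        - params.gamma * x
    dy = (params.alpha_y + eps2) * yf / (bn + yf) + params.iota_y * bn / (bn + xf) \
        - params.gamma * y
    return dx, dy


def epsilon_coefficients(s_l: float, s1: float, s2: float, params: PSwitchParams,
                         leading_active: bool = True) -> tuple[float, float]:
    """Signalling-effect coefficients (eps1, eps2) at one mesh.

    ``eps_i = f_i(S_l) + g(S_i)``.  The leading-signal response ``f`` is a
    steep Hill switch (exponent 12) normalized to half-max at half the
    leading-signal scale ``sl_max / 2`` — the same threshold that separates
    the intended A and B territories in the scoring template — and gated
    off as soon as the cell sits in established territory (local S_i > 0).
    The territorial response ``g`` grows linearly and saturates at ``eps_a``
    once ``S_i >= eps_b``.  High S_l favours the X (A-fate) side; the Y
    (B-fate) side responds to the complement ``sl_max - S_l`` so that low
    S_l regions are biased toward B.  With no leading-signal field at all
    (``leading_active=False``) both f terms vanish.
    """
    _check_nonneg(s_l, s1, s2)
    a, b = params.eps_a, params.eps_b
    s_half = params.sl_max / 2.0

    def g(s):
        return a * s / b if s <= b else a

    def f(u):
        u12 = (float(u) / s_half) ** 12
        return a * u12 / (1.0 + u12)

    f1 = f(s_l) if (leading_active and s1 == 0) else 0.0
    f2 = f(max(params.sl_max - s_l, 0.0)) if (leading_active and s2 == 0) else 0.0
    return f1 + g(s1), f2 + g(s2)


# ---------------------------------------------------------------------------
# fixed points and basins

def _numeric_jacobian(rhs, x, y, h=1e-5):
    fx0, fy0 = rhs(max(x - h, 0.0), y)
    fx1, fy1 = rhs(x + h, y)
    gx0, gy0 = rhs(x, max(y - h, 0.0))
    gx1, gy1 = rhs(x, y + h)
    dxl = (x + h) - max(x - h, 0.0)
    dyl = (y + h) - max(y - h, 0.0)
    return np.array([[(fx1 - fx0) / dxl, (gx1 - gx0) / dyl],
                     [(fy1 - fy0) / dxl, (gy1 - gy0) / dyl]])


def find_fixed_points(rhs, search_box: float, resolution: float = 2.0,
                      tol: float = 1e-8) -> list[FixedPoint]:
    """All roots of the planar system in ``[0, search_box]^2``.

    Seeds a root search from every local minimum of the residual norm on a
    coarse grid, polishes with a hybrid Newton method, deduplicates, and
    classifies each root by the eigenvalues of a central-difference Jacobian.
    """
    g = np.arange(0.0, search_box + resolution, resolution)
    X, Y = np.meshgrid(g, g, indexing="ij")
    dx, dy = rhs(X, Y)
    res = np.hypot(dx, dy)
    # local minima of the residual (8-neighbourhood), generous threshold
    mins = (res == ndimage.minimum_filter(res, size=3))
    seeds = list(zip(X[mins].ravel(), Y[mins].ravel()))
    roots: list[FixedPoint] = []
    for sx, sy in seeds:
        sol = optimize.root(lambda v: np.array(rhs(max(v[0], 0.0), max(v[1], 0.0))),
                            [sx, sy], method="hybr", tol=1e-12)
        if not sol.success:
            continue
        x, y = float(max(sol.x[0], 0.0)), float(max(sol.x[1], 0.0))
        fx, fy = rhs(x, y)
        if np.hypot(fx, fy) > tol:
            continue
        if x > search_box or y > search_box:
            continue
        if any(np.hypot(x - r.x, y - r.y) < 1e-3 * max(1.0, search_box / 100) for r in roots):
            continue
        jac = _numeric_jacobian(rhs, x, y)
        ev = np.linalg.eigvals(jac)
        re = np.real(ev)
        if np.all(re < -tol):
            stab = STABLE
        elif np.all(re > tol):
            stab = UNSTABLE
        else:
            stab = SADDLE
        roots.append(FixedPoint(x, y, stab, (complex(ev[0]), complex(ev[1]))))
    roots.sort(key=lambda r: (r.x, r.y))
    return roots


def compute_basin_map(rhs, fixed_points: list[FixedPoint], box: float,
                      resolution: float = 1.0, t_max: float = 120.0,
                      dt: float = 0.05, fate_of_fp=None,
                      prefer_label: int | None = None) -> BasinMap:
    """Label every lattice point of ``[0, box]^2`` by the stable state it reaches.

    Forward RK4 integration of all grid points at once; end points are
    assigned to the nearest stable fixed point.  Points that have not come
    close to any attractor within the horizon are filled from their nearest
    resolved neighbour (ties broken toward ``prefer_label``, normally the
    progenitor/middle fate).
    """
    stable = [fp for fp in fixed_points if fp.stability == STABLE]
    if len(stable) < 1:
        raise ValueError("need at least one stable fixed point for a basin map")
    if fate_of_fp is None:
        fate_of_fp = {id(fp): i + 1 for i, fp in enumerate(stable)}
        labels_of = [i + 1 for i in range(len(stable))]
    else:
        labels_of = [fate_of_fp[id(fp)] for fp in stable]

    g = np.arange(0.0, box + resolution / 2, resolution)
    n = len(g)
    X, Y = np.meshgrid(g, g, indexing="ij")
    X = X.ravel().copy()
    Y = Y.ravel().copy()

    def step(x, y, h):
        k1x, k1y = rhs(x, y)
        x2 = np.maximum(x + 0.5 * h * k1x, 0.0)
        y2 = np.maximum(y + 0.5 * h * k1y, 0.0)
        k2x, k2y = rhs(x2, y2)
        x3 = np.maximum(x + 0.5 * h * k2x, 0.0)
        y3 = np.maximum(y + 0.5 * h * k2y, 0.0)
        k3x, k3y = rhs(x3, y3)
        x4 = np.maximum(x + h * k3x, 0.0)
        y4 = np.maximum(y + h * k3y, 0.0)
        k4x, k4y = rhs(x4, y4)
        xn = x + h / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        yn = y + h / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
        return np.maximum(xn, 0.0), np.maximum(yn, 0.0)

    nsteps = int(np.ceil(t_max / dt))
    for _ in range(nsteps):
        X, Y = step(X, Y, dt)

    # assign to nearest stable fixed point within a capture radius
    sx = np.array([fp.x for fp in stable])
    sy = np.array([fp.y for fp in stable])
    d2 = (X[:, None] - sx[None, :]) ** 2 + (Y[:, None] - sy[None, :]) ** 2
    nearest = np.argmin(d2, axis=1)
    dmin = np.sqrt(d2[np.arange(len(X)), nearest])
    capture = max(2.0, 0.02 * box)
    lab = np.zeros(len(X), dtype=np.int8)
    ok = dmin <= capture
    lab[ok] = np.array(labels_of, dtype=np.int8)[nearest[ok]]
    lab = lab.reshape(n, n)

    if (lab == UNRESOLVED).any() and (lab != UNRESOLVED).any():
        resolved = lab != UNRESOLVED
        dr, (ix, iy) = ndimage.distance_transform_edt(~resolved, return_indices=True)
        filled = lab[ix, iy]
        if prefer_label is not None and (lab == prefer_label).any():
            # a tie between basins at equal distance resolves to the middle fate
            dp = ndimage.distance_transform_edt(lab != prefer_label)
            filled = np.where(dp <= dr + 0.5, prefer_label, filled)
        lab = np.where(lab == UNRESOLVED, filled, lab)

    return BasinMap(labels=lab.astype(np.int8), resolution=resolution,
                    fixed_points=fixed_points)


def classify_fate(x_det: int, y_det: int, basin_map: BasinMap) -> int:
    """Fate code of the basin-map cell nearest to integer counts (x, y)."""
    if x_det < 0 or y_det < 0:
        raise ValueError("determinant counts must be non-negative")
    n = basin_map.labels.shape[0]
    xi = min(int(round(x_det / basin_map.resolution)), n - 1)
    yi = min(int(round(y_det / basin_map.resolution)), n - 1)
    return int(basin_map.labels[xi, yi])


# ---------------------------------------------------------------------------
# fate-labelled maps for the engine

def _label_s_fps(fps: list[FixedPoint]) -> dict[int, int]:
    """High-x stable state -> S, high-y -> P."""
    stable = [fp for fp in fps if fp.stability == STABLE]
    out = {}
    for fp in stable:
        out[id(fp)] = S if fp.x > fp.y else P
        fp.fate_label = out[id(fp)]
    return out


def _label_p_fps(fps: list[FixedPoint]) -> dict[int, int]:
    """High-x -> A, high-y -> B, middle (most symmetric) -> P."""
    stable = [fp for fp in fps if fp.stability == STABLE]
    mid = min(stable, key=lambda fp: abs(fp.x - fp.y))
    out = {}
    for fp in stable:
        if fp is mid:
            out[id(fp)] = P
        else:
            out[id(fp)] = A if fp.x > fp.y else B
        fp.fate_label = out[id(fp)]
    return out


@functools.lru_cache(maxsize=8)
def fate_maps(sparams: SSwitchParams = SSwitchParams(),
              pparams: PSwitchParams = PSwitchParams(),
              box: float = 340.0, resolution: float = 1.0
              ) -> tuple[BasinMap, BasinMap]:
    """Basin maps of both switches with fate-coded labels, cached per params.

    The stem map is computed at the base (reference-density) iota_x and the
    progenitor map at eps = 0: the density and signalling feedbacks act on
    the stochastic determinant dynamics, while newborn classification uses
    the reference phase planes.
    """
    s_rhs = lambda x, y: s_switch_rhs(x, y, sparams)            # noqa: E731
    p_rhs = lambda x, y: p_switch_rhs(x, y, pparams, 0.0, 0.0)  # noqa: E731

    s_fps = find_fixed_points(s_rhs, box)
    s_fate = _label_s_fps(s_fps)
    s_map = compute_basin_map(s_rhs, s_fps, box, resolution,
                              t_max=20.0 / sparams.gamma, dt=0.1 / sparams.gamma,
                              fate_of_fp=s_fate, prefer_label=P)

    p_fps = find_fixed_points(p_rhs, box)
    p_fate = _label_p_fps(p_fps)
    p_map = compute_basin_map(p_rhs, p_fps, box, resolution,
                              t_max=20.0 / pparams.gamma, dt=0.1 / pparams.gamma,
                              fate_of_fp=p_fate, prefer_label=P)
    return s_map, p_map


# ---------------------------------------------------------------------------
# shifted-basin families
#
# The decision boundaries a newborn cell faces are the basins of its switch
# *with the feedbacks applied*: the progenitor switch includes the local
# signalling coefficients (eps1, eps2) and the stem switch the
# density-modulated iota_xs(n).  The engine therefore classifies against a
# family of basin maps precomputed on a quantized grid of those inputs.
# Each shifted map's stable states are fate-labelled by looking their
# coordinates up in the unshifted reference map, which tracks attractor
# identity continuously as the basins deform (a state that has merged into
# the A attractor's reference basin *is* an A-committed state).

def _family_map(rhs, base_map: BasinMap, box: float, resolution: float,
                gamma: float) -> np.ndarray:
    fps = find_fixed_points(rhs, box)
    stable = [fp for fp in fps if fp.stability == STABLE]
    if not stable:  # pathological parameters: fall back to the reference map
        step = max(int(round(resolution / base_map.resolution)), 1)
        return base_map.labels[::step, ::step].copy()
    fate = {id(fp): classify_fate(fp.x, fp.y, base_map) for fp in stable}
    bm = compute_basin_map(rhs, fps, box, resolution,
                           t_max=20.0 / gamma, dt=0.1 / gamma,
                           fate_of_fp=fate, prefer_label=P)
    return bm.labels


@functools.lru_cache(maxsize=4)
def fate_map_families(sparams: SSwitchParams = SSwitchParams(),
                      pparams: PSwitchParams = PSwitchParams(),
                      n_eps: int = 7, n_iota: int = 9,
                      box: float = 340.0, resolution: float = 2.0) -> dict:
    """Quantized families of fate-labelled basin maps for the engine.

    Returns ``iota_levels`` with ``s_maps[l]`` (stem switch at
    ``iota_x = iota_levels[l]``) and ``eps_levels`` with ``p_maps[i, j]``
    (progenitor switch at ``eps1 = eps_levels[i], eps2 = eps_levels[j]``).
    """
    base_s, base_p = fate_maps(sparams, pparams, box=box)
    eps_levels = np.linspace(0.0, 2.0 * pparams.eps_a, n_eps)
    iota_levels = np.linspace(0.2 * sparams.iota_x, 2.0 * sparams.iota_x, n_iota)
    nb = int(np.floor(box / resolution)) + 1

    s_maps = np.zeros((n_iota, nb, nb), dtype=np.int8)
    for l, iota in enumerate(iota_levels):
        rhs = lambda x, y: s_switch_rhs(x, y, sparams, iota_x_eff=iota)  # noqa: E731
        s_maps[l] = _family_map(rhs, base_s, box, resolution, sparams.gamma)

    symmetric = (pparams.alpha_x == pparams.alpha_y
                 and pparams.iota_x == pparams.iota_y)
    p_maps = np.zeros((n_eps, n_eps, nb, nb), dtype=np.int8)
    swap = {A: B, B: A, P: P, UNRESOLVED: UNRESOLVED}
    for i, e1 in enumerate(eps_levels):
        for j, e2 in enumerate(eps_levels):
            if symmetric and j < i:
                src = p_maps[j, i]
                p_maps[i, j] = np.vectorize(swap.get, otypes=[np.int8])(src).T
                continue
            rhs = lambda x, y: p_switch_rhs(x, y, pparams, e1, e2)  # noqa: E731
            p_maps[i, j] = _family_map(rhs, base_p, box, resolution,
                                       pparams.gamma)
    return {
        "iota_levels": iota_levels, "s_maps": s_maps,
        "eps_levels": eps_levels, "p_maps": p_maps,
        "resolution": resolution, "box": box,
    }
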