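"""Template-matching score of pattern maintenance.

A leading-signal pattern defines two filters over the d x d dish window: the
*template* is +1 where the signal exceeds half its maximum (the intended A
territory), -1 at every other in-dish mesh (the intended B territory) and 0
outside the dish; the *penalty* is 1 exactly at out-of-dish meshes.  A
snapshot of the dish maps to a matrix with +1 at A cells and -1 at B cells,
embedded centrally in a 2d x 2d zero matrix.  The snapshot's raw score is
the maximum over all filter placements of (template correlation - penalty
correlation); dividing by the score of the perfectly matching snapshot
normalizes a perfect match to 1.  Scores are reported unclamped, so badly
anti-matching snapshots can be negative.  The max-over-offsets makes the
score insensitive to rigid translations of the whole pattern.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as _sig

from .lattice import A, B

TEMPLATE_THRESHOLD = 125.0  # half the 250-molecule pattern maximum


@dataclasses.dataclass
class ScoreFilters:
    template: np.ndarray   # int8 (d, d), entries {+1, -1, 0}
    penalty: np.ndarray    # uint8 (d, d), entries {0, 1}
    max_score: float
    d: int


def build_filters(s_l_field: np.ndarray, dish_mask: np.ndarray,
                  threshold: float = TEMPLATE_THRESHOLD) -> ScoreFilters:
    """Template and penalty filters for a leading-signal pattern."""
    s_l_field = np.asarray(s_l_field)
    dish_mask = np.asarray(dish_mask, dtype=bool)
    if s_l_field.shape != dish_mask.shape:
        raise ValueError("field and mask shapes differ")
    template = np.zeros(s_l_field.shape, dtype=np.int8)
    template[dish_mask] = np.where(s_l_field[dish_mask] > threshold, 1, -1)
    penalty = (~dish_mask).astype(np.uint8)
    d = s_l_field.shape[0]
    filters = ScoreFilters(template=template, penalty=penalty, max_score=1.0, d=d)
    ideal = np.zeros_like(template)
    ideal[template == 1] = A
    ideal[template == -1] = B
    filters.max_score = _raw_score(snapshot_matrix(ideal), filters)
    if filters.max_score <= 0:
        raise ValueError("degenerate template: ideal snapshot has no positive score")
    return filters


def snapshot_matrix(occ: np.ndarray) -> np.ndarray:
    """±1 cell matrix of a d x d occupancy grid, zero-padded to 2d x 2d."""
    occ = np.asarray(occ)
    d = occ.shape[0]
    small = np.zeros((d, d), dtype=np.int8)
    small[occ == A] = 1
    small[occ == B] = -1
    big = np.zeros((2 * d, 2 * d), dtype=np.int8)
    off = d // 2
    big[off:off + d, off:off + d] = small
    return big


def _raw_score(matrix: np.ndarray, filters: ScoreFilters) -> float:
    """Max over all filter offsets of (template·window - penalty·window).

    All inputs are integer-valued, so the FFT correlation is rounded back to
    integers to keep the score exact.
    """
    m = matrix.astype(np.float64)
    ct = _sig.correlate(m, filters.template.astype(np.float64), mode="full", method="auto")
    cp = _sig.correlate(m, filters.penalty.astype(np.float64), mode="full", method="auto")
    return float(np.max(np.rint(ct) - np.rint(cp)))


def score_snapshot(matrix: np.ndarray, filters: ScoreFilters) -> float:
    """Normalized pattern score of one 2d x 2d snapshot matrix."""
    if matrix.shape[0] != 2 * filters.d:
        raise ValueError("matrix was not built for these filters")
    return _raw_score(matrix, filters) / filters.max_score


def score_trajectory(snapshots, filters: ScoreFilters,
                     times=None) -> np.ndarray:
    """Scores of a sequence of occupancy snapshots, in order.

    ``snapshots`` holds d x d occupancy grids (cell codes); returns an array
    of scores, or a (time, score) record array when ``times`` is given.
    """
    scores = np.array([score_snapshot(snapshot_matrix(occ), filters)
                       for occ in snapshots])
    if times is not None:
        return np.rec.fromarrays([np.asarray(times), scores],
                                 names=("time", "score"))
    return scores


# ---------------------------------------------------------------------------
# trace and territory statistics

def final_quartile_slope(times, values) -> float:
    """Least-squares slope of the last quarter of a trace (per unit time)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    k = max(len(times) // 4, 2)
    t, v = times[-k:], values[-k:]
    if t[-1] == t[0]:
        return 0.0
    return float(np.polyfit(t - t[0], v, 1)[0])


def like_adjacency_fraction(occ: np.ndarray) -> float:
    """Fraction of A/B–A/B neighbour pairs whose two cells share a type.

    A contiguity (join-count) statistic over the 4-neighbour graph restricted
    to specialized cells; random mixing gives a value near the expected
    fraction under exchangeable labels, contiguous territories give values
    near 1.
    """
    occ = np.asarray(occ)
    same = 0
    total = 0
    for axis in (0, 1):
        a = occ[:-1, :] if axis == 0 else occ[:, :-1]
        b = occ[1:, :] if axis == 0 else occ[:, 1:]
        pair = (np.isin(a, (A, B))) & (np.isin(b, (A, B)))
        same += int((pair & (a == b)).sum())
        total += int(pair.sum())
    return same / total if total else float("nan")


def adjacency_permutation_test(occ: np.ndarray, n_perm: int = 200,
                               seed: int = 0) -> dict:
    """Compare like-type adjacency against a label-permutation null.

    Shuffles the A/B labels over the occupied specialized-cell positions and
    recomputes the statistic ``n_perm`` times; returns the observed value,
    the null mean/sd and an upper-tail p-value.
    """
    occ = np.asarray(occ).copy()
    obs = like_adjacency_fraction(occ)
    pos = np.argwhere(np.isin(occ, (A, B)))
    labels = occ[pos[:, 0], pos[:, 1]].copy()
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        rng.shuffle(labels)
        occ[pos[:, 0], pos[:, 1]] = labels
        null[i] = like_adjacency_fraction(occ)
    p = (1 + int((null >= obs).sum())) / (n_perm + 1)
    return {"observed": obs, "null_mean": float(null.mean()),
            "null_sd": float(null.std()), "p_value": p}
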