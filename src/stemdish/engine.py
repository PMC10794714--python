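"""Exact stochastic simulator of the patterned dish (Gillespie direct method).

Every reaction family of the model — determinant synthesis/degradation inside
S and P cells, cell division with binomial determinant partitioning and
basin-classified offspring fates, reversible S<->P transitions, movement,
controlled death of A/B cells, and production/degradation/diffusion of all
four signal species — contributes per-mesh propensities.  The direct method
draws an exponential waiting time from the total propensity and picks one
reaction proportional to its rate.

Implementation notes
--------------------
* The hot loop is compiled with numba.  Propensities are organised as
  ``NCH`` channel families, each holding a per-mesh weight table backed by a
  Fenwick (binary indexed) tree, so sampling a mesh within a channel and
  updating a weight are both O(log N).  Only meshes touched by an event are
  recomputed.  Channel-level factors that depend on global state (the
  density-modulated iota_xs(n), the adaptive death rates, phase gating) are
  cheap scalars recomputed every event.
* Weight tables are rebuilt from scratch periodically to cancel float
  accumulation drift, and on every phase change.
* The three phases: (1) signal maturation — only determinant dynamics,
  movement and the leading-signal reactions run; (2) divisions and
  transitions switch on and the tissue forms; (3) entered once both
  specialized types are established — the leading-signal reactions stop and
  its residual field is frozen (it still gates the signalling-effect
  coefficients wherever no territorial signal is present).
* The simulation ends when cumulative progenitor divisions per time-averaged
  progenitor reach the division target (or on the event/time caps).

The per-mesh propensity semantics mirror the reference functions in
:mod:`stemdish.signals` and :mod:`stemdish.switches`; a test compares the
kernel's weight tables against them directly.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING, Sequence

import numpy as np
from numba import njit

from . import lattice, signals, switches
from .adhesion import seed_disc_mask
from .death import death_rate, target_abundances
from .lattice import A, B, DishState, P, S

if TYPE_CHECKING:  # pragma: no cover
    from .config import SimConfig

# --------------------------------------------------------------------------
# channel / parameter / tally indices

CH_S_DIV, CH_S_TRANS, CH_S_MOVE = 0, 1, 2
CH_P_DIV, CH_P_TRANS, CH_P_MOVE = 3, 4, 5
CH_A_DEATH, CH_B_DEATH, CH_APOPT = 6, 7, 8
CH_XS_PROD, CH_YS_PROD, CH_XS_DEG, CH_YS_DEG = 9, 10, 11, 12
CH_XP_PROD, CH_YP_PROD, CH_XP_DEG, CH_YP_DEG = 13, 14, 15, 16
CH_S1_PROD, CH_S2_PROD, CH_S1_DEG, CH_S2_DEG = 17, 18, 19, 20
CH_S1_DIFF, CH_S2_DIFF = 21, 22
CH_SL_PROD, CH_SL_DEG, CH_SL_DIFF = 23, 24, 25
CH_SA_PROD, CH_SA_DEG, CH_SA_DIFF = 26, 27, 28
NCH = 29

CHANNEL_NAMES = [
    "s_division", "s_to_p", "s_move", "p_division", "p_to_s", "p_move",
    "a_death", "b_death", "apoptosis",
    "xs_prod", "ys_prod", "xs_deg", "ys_deg",
    "xp_prod", "yp_prod", "xp_deg", "yp_deg",
    "s1_prod", "s2_prod", "s1_deg", "s2_deg", "s1_diff", "s2_diff",
    "sl_prod", "sl_deg", "sl_diff", "sa_prod", "sa_deg", "sa_diff",
]

(P_RS, P_WP, P_MS, P_RP, P_WS, P_MP,
 P_IOTA_XS, P_IOTA_YS, P_BSN, P_NS, P_GAMMA_S,
 P_ALPHA_XP, P_ALPHA_YP, P_IOTA_XP, P_IOTA_YP, P_BPN, P_NP, P_GAMMA_P,
 P_EPS_A, P_EPS_B, P_SL_MAX,
 P_T_ALPHA, P_T_BN, P_T_N, P_T_K, P_T_D,
 P_ALPHA_SL, P_K_SL, P_D_SL,
 P_DL, P_DA, P_GSL, P_GSA, P_TA, P_TB, P_TC, P_SUP, P_SLO,
 P_NREF, P_NREF_EXP,
 P_VG, P_STEP_LO, P_STEP_HI, P_NSTAR_A, P_NSTAR_B, P_GA_FIX, P_GB_FIX,
 P_ADH_THR, P_ADH_MOVEPEN, P_ADH_APOP,
 P_MAP_RES, P_EPS_L0, P_EPS_STEP, P_IOTA_L0, P_IOTA_STEP,
 P_DIFF_MODE) = range(56)
NPV = 56

M_PHASE, M_SCEN, M_ADH, M_SRC_ALL, M_DEATH_MODE, M_STATUS, M_LEAD_ACTIVE = range(7)
NMV = 7

SCEN_STATIC, SCEN_DIFFUSIVE, SCEN_TURING = 0, 1, 2
DM_FIXED, DM_STEP, DM_LINEAR, DM_CUBE = 0, 1, 2, 3
ST_RUNNING, ST_STALLED, ST_DONE = 0, 1, 2

(T_SS, T_S_SP, T_S_PP, T_WP_CNT, T_WS_CNT,
 T_P_PP, T_P_PA, T_P_PB, T_P_AB, T_P_AA, T_P_BB,
 T_A_DEATH, T_B_DEATH, T_APOPT,
 T_BLOCKED_DIV, T_BLOCKED_MOVE, T_EVENTS, T_PDIV) = range(18)
NTL = 20

TALLY_NAMES = [
    "s_div_SS", "s_div_SP", "s_div_PP", "s_to_p", "p_to_s",
    "p_div_PP", "p_div_PA", "p_div_PB", "p_div_AB", "p_div_AA", "p_div_BB",
    "a_death", "b_death", "apoptosis",
    "blocked_division", "blocked_movement", "events", "p_divisions",
]


# --------------------------------------------------------------------------
# Fenwick trees (per-channel weight tables)

@njit(cache=True, inline="always")
def _fen_add(fenc, i, delta, n):
    j = i + 1
    while j <= n:
        fenc[j] += delta
        j += j & (-j)


@njit(cache=True, inline="always")
def _fen_find(fenc, u, n, topbit):
    """Smallest 0-based index whose prefix sum exceeds u."""
    pos = 0
    bm = topbit
    while bm > 0:
        nxt = pos + bm
        if nxt <= n and fenc[nxt] < u:
            pos = nxt
            u -= fenc[nxt]
        bm >>= 1
    if pos >= n:
        pos = n - 1
    return pos


@njit(cache=True, inline="always")
def _set_w(W, fen, tot, c, i, v, n):
    d = v - W[c, i]
    if d != 0.0:
        W[c, i] = v
        tot[c] += d
        _fen_add(fen[c], i, d, n)


# --------------------------------------------------------------------------
# per-mesh weights (kernel mirror of the reference propensity functions)

@njit(cache=True, inline="always")
def _eps_pair(sl_v, s1_v, s2_v, pvec, lead_active):
    a = pvec[P_EPS_A]
    b = pvec[P_EPS_B]
    g1 = a * s1_v / b if s1_v <= b else a
    g2 = a * s2_v / b if s2_v <= b else a
    f1 = 0.0
    f2 = 0.0
    if lead_active == 1:
        s_half = pvec[P_SL_MAX] * 0.5
        if s1_v == 0.0:
            u = (sl_v / s_half) ** 12
            f1 = a * u / (1.0 + u)
        if s2_v == 0.0:
            w = pvec[P_SL_MAX] - sl_v
            if w < 0.0:
                w = 0.0
            w = (w / s_half) ** 12
            f2 = a * w / (1.0 + w)
    return f1 + g1, f2 + g2


@njit(cache=True, inline="always")
def _diff_w(rate, count, nb, mode):
    """Diffusion propensity: constant per-mesh rate (as the rate table
    prints it, gated at zero count) or mass-action rate*count."""
    if mode == 0:
        return rate * nb if count > 0.0 else 0.0
    return rate * count * nb


@njit(cache=True)
def _mesh_weights(i, occ, xdet, ydet, s1, s2, sl, sa, nnbr, seeddisc,
                  pvec, mvec, wloc):
    for c in range(NCH):
        wloc[c] = 0.0
    o = occ[i]
    if o < 0:
        return
    scen = mvec[M_SCEN]
    phase = mvec[M_PHASE]
    adh = mvec[M_ADH]
    nb = float(nnbr[i])
    s1v = float(s1[i]); s2v = float(s2[i])
    slv = float(sl[i]); sav = float(sa[i])

    on_matrix = True
    if adh == 1:
        on_matrix = seeddisc[i] == 1 or (s1v + s2v + slv) >= pvec[P_ADH_THR]

    if o == 1:  # stem cell
        x = float(xdet[i]); y = float(ydet[i])
        bsn = pvec[P_BSN]; ns = pvec[P_NS]
        wloc[CH_XS_PROD] = bsn / (bsn + y ** ns)       # x iota_xs(n) factor
        wloc[CH_YS_PROD] = pvec[P_IOTA_YS] * bsn / (bsn + x ** ns)
        wloc[CH_XS_DEG] = pvec[P_GAMMA_S] * x
        wloc[CH_YS_DEG] = pvec[P_GAMMA_S] * y
        wloc[CH_S_DIV] = 1.0 if on_matrix else 0.0
        wloc[CH_S_TRANS] = 1.0
        wloc[CH_S_MOVE] = 1.0 if on_matrix else pvec[P_ADH_MOVEPEN]
    elif o == 2:  # progenitor
        x = float(xdet[i]); y = float(ydet[i])
        bpn = pvec[P_BPN]; npw = pvec[P_NP]
        e1, e2 = _eps_pair(slv, s1v, s2v, pvec, mvec[M_LEAD_ACTIVE])
        xn = x ** npw
        yn = y ** npw
        wloc[CH_XP_PROD] = (pvec[P_ALPHA_XP] + e1) * xn / (bpn + xn) \
            + pvec[P_IOTA_XP] * bpn / (bpn + yn)
        wloc[CH_YP_PROD] = (pvec[P_ALPHA_YP] + e2) * yn / (bpn + yn) \
            + pvec[P_IOTA_YP] * bpn / (bpn + xn)
        wloc[CH_XP_DEG] = pvec[P_GAMMA_P] * x
        wloc[CH_YP_DEG] = pvec[P_GAMMA_P] * y
        wloc[CH_P_DIV] = 1.0 if on_matrix else 0.0
        wloc[CH_P_TRANS] = 1.0
        wloc[CH_P_MOVE] = 1.0 if on_matrix else pvec[P_ADH_MOVEPEN]
    elif o == 3:  # A cell
        tbn = pvec[P_T_BN]; tn = pvec[P_T_N]
        wloc[CH_S1_PROD] = pvec[P_T_ALPHA] * tbn / (tbn + s2v ** tn)
        wloc[CH_A_DEATH] = 1.0
    elif o == 4:  # B cell
        tbn = pvec[P_T_BN]; tn = pvec[P_T_N]
        wloc[CH_S2_PROD] = pvec[P_T_ALPHA] * tbn / (tbn + s1v ** tn)
        wloc[CH_B_DEATH] = 1.0

    if adh == 1 and o >= 1 and not on_matrix:
        wloc[CH_APOPT] = 1.0

    # territorial signal bookkeeping at any in-region mesh
    wloc[CH_S1_DEG] = pvec[P_T_K] * s1v
    wloc[CH_S2_DEG] = pvec[P_T_K] * s2v
    dmode = int(pvec[P_DIFF_MODE])
    wloc[CH_S1_DIFF] = _diff_w(pvec[P_T_D], s1v, nb, dmode)
    wloc[CH_S2_DIFF] = _diff_w(pvec[P_T_D], s2v, nb, dmode)

    # leading signal and its Turing partner (off in phase 3 / static scenario)
    if phase < 3:
        if scen == SCEN_DIFFUSIVE:
            if o >= 1 or mvec[M_SRC_ALL] == 1:
                wloc[CH_SL_PROD] = pvec[P_ALPHA_SL]
            wloc[CH_SL_DEG] = pvec[P_K_SL] * slv
            wloc[CH_SL_DIFF] = _diff_w(pvec[P_D_SL], slv, nb, dmode)
        elif scen == SCEN_TURING:
            if slv < pvec[P_SUP]:
                wloc[CH_SL_PROD] = pvec[P_GSL] * (pvec[P_TA] * slv + pvec[P_TC])
            if slv > pvec[P_SLO]:
                wloc[CH_SL_DEG] = pvec[P_GSL] * sav
                wloc[CH_SL_DIFF] = _diff_w(pvec[P_DL], slv, nb, dmode)
            wloc[CH_SA_PROD] = pvec[P_GSA] * pvec[P_TB] * slv
            wloc[CH_SA_DEG] = pvec[P_GSA] * (sav + 1.0)
            wloc[CH_SA_DIFF] = _diff_w(pvec[P_DA], sav, nb, dmode)


@njit(cache=True)
def _refresh_mesh(i, occ, xdet, ydet, s1, s2, sl, sa, nnbr, seeddisc,
                  pvec, mvec, W, fen, tot, wloc, n):
    _mesh_weights(i, occ, xdet, ydet, s1, s2, sl, sa, nnbr, seeddisc,
                  pvec, mvec, wloc)
    for c in range(NCH):
        _set_w(W, fen, tot, c, i, wloc[c], n)


# Fast partial updates: most events only change one molecule count at a mesh,
# which touches a handful of channels.  With adhesion enabled a signal change
# can flip the matrix status of the mesh, so the caller falls back to the
# full refresh in that case.

@njit(cache=True, inline="always")
def _upd_p_prod(i, xdet, ydet, s1, s2, sl, pvec, mvec, W, fen, tot, n):
    """Re-derive the eps-dependent determinant production weights of a P mesh."""
    x = float(xdet[i]); y = float(ydet[i])
    bpn = pvec[P_BPN]; npw = pvec[P_NP]
    e1, e2 = _eps_pair(float(sl[i]), float(s1[i]), float(s2[i]), pvec,
                       mvec[M_LEAD_ACTIVE])
    xn = x ** npw
    yn = y ** npw
    _set_w(W, fen, tot, CH_XP_PROD, i,
           (pvec[P_ALPHA_XP] + e1) * xn / (bpn + xn)
           + pvec[P_IOTA_XP] * bpn / (bpn + yn), n)
    _set_w(W, fen, tot, CH_YP_PROD, i,
           (pvec[P_ALPHA_YP] + e2) * yn / (bpn + yn)
           + pvec[P_IOTA_YP] * bpn / (bpn + xn), n)


@njit(cache=True)
def _touch_s12(i, which, occ, xdet, ydet, s1, s2, sl, nnbr,
               pvec, mvec, W, fen, tot, n):
    nb = float(nnbr[i])
    tn = pvec[P_T_N]; tbn = pvec[P_T_BN]
    o = occ[i]
    dmode = int(pvec[P_DIFF_MODE])
    if which == 1:
        v = float(s1[i])
        _set_w(W, fen, tot, CH_S1_DEG, i, pvec[P_T_K] * v, n)
        _set_w(W, fen, tot, CH_S1_DIFF, i, _diff_w(pvec[P_T_D], v, nb, dmode), n)
        if o == 4:
            _set_w(W, fen, tot, CH_S2_PROD, i,
                   pvec[P_T_ALPHA] * tbn / (tbn + v ** tn), n)
    else:
        v = float(s2[i])
        _set_w(W, fen, tot, CH_S2_DEG, i, pvec[P_T_K] * v, n)
        _set_w(W, fen, tot, CH_S2_DIFF, i, _diff_w(pvec[P_T_D], v, nb, dmode), n)
        if o == 3:
            _set_w(W, fen, tot, CH_S1_PROD, i,
                   pvec[P_T_ALPHA] * tbn / (tbn + v ** tn), n)
    if o == 2:
        _upd_p_prod(i, xdet, ydet, s1, s2, sl, pvec, mvec, W, fen, tot, n)


@njit(cache=True)
def _touch_lead(i, occ, xdet, ydet, s1, s2, sl, sa, nnbr,
                pvec, mvec, W, fen, tot, n):
    nb = float(nnbr[i])
    slv = float(sl[i]); sav = float(sa[i])
    scen = mvec[M_SCEN]
    if mvec[M_PHASE] < 3:
        dmode = int(pvec[P_DIFF_MODE])
        if scen == SCEN_DIFFUSIVE:
            _set_w(W, fen, tot, CH_SL_DEG, i, pvec[P_K_SL] * slv, n)
            _set_w(W, fen, tot, CH_SL_DIFF, i,
                   _diff_w(pvec[P_D_SL], slv, nb, dmode), n)
        elif scen == SCEN_TURING:
            prod = pvec[P_GSL] * (pvec[P_TA] * slv + pvec[P_TC]) \
                if slv < pvec[P_SUP] else 0.0
            _set_w(W, fen, tot, CH_SL_PROD, i, prod, n)
            if slv > pvec[P_SLO]:
                _set_w(W, fen, tot, CH_SL_DEG, i, pvec[P_GSL] * sav, n)
                _set_w(W, fen, tot, CH_SL_DIFF, i,
                       _diff_w(pvec[P_DL], slv, nb, dmode), n)
            else:
                _set_w(W, fen, tot, CH_SL_DEG, i, 0.0, n)
                _set_w(W, fen, tot, CH_SL_DIFF, i, 0.0, n)
            _set_w(W, fen, tot, CH_SA_PROD, i, pvec[P_GSA] * pvec[P_TB] * slv, n)
            _set_w(W, fen, tot, CH_SA_DEG, i, pvec[P_GSA] * (sav + 1.0), n)
            _set_w(W, fen, tot, CH_SA_DIFF, i,
                   _diff_w(pvec[P_DA], sav, nb, dmode), n)
    if occ[i] == 2:
        _upd_p_prod(i, xdet, ydet, s1, s2, sl, pvec, mvec, W, fen, tot, n)


@njit(cache=True)
def _touch_dets(i, occ, xdet, ydet, s1, s2, sl, pvec, mvec, W, fen, tot, n):
    x = float(xdet[i]); y = float(ydet[i])
    if occ[i] == 1:
        bsn = pvec[P_BSN]; ns = pvec[P_NS]
        _set_w(W, fen, tot, CH_XS_PROD, i, bsn / (bsn + y ** ns), n)
        _set_w(W, fen, tot, CH_YS_PROD, i,
               pvec[P_IOTA_YS] * bsn / (bsn + x ** ns), n)
        _set_w(W, fen, tot, CH_XS_DEG, i, pvec[P_GAMMA_S] * x, n)
        _set_w(W, fen, tot, CH_YS_DEG, i, pvec[P_GAMMA_S] * y, n)
    else:
        _set_w(W, fen, tot, CH_XP_DEG, i, pvec[P_GAMMA_P] * x, n)
        _set_w(W, fen, tot, CH_YP_DEG, i, pvec[P_GAMMA_P] * y, n)
        _upd_p_prod(i, xdet, ydet, s1, s2, sl, pvec, mvec, W, fen, tot, n)


@njit(cache=True)
def _rebuild(occ, xdet, ydet, s1, s2, sl, sa, nnbr, seeddisc,
             pvec, mvec, W, fen, tot, wloc):
    n = occ.shape[0]
    for c in range(NCH):
        tot[c] = 0.0
        for j in range(n + 1):
            fen[c, j] = 0.0
    for i in range(n):
        _mesh_weights(i, occ, xdet, ydet, s1, s2, sl, sa, nnbr, seeddisc,
                      pvec, mvec, wloc)
        for c in range(NCH):
            W[c, i] = wloc[c]
            tot[c] += wloc[c]
            fen[c, i + 1] = wloc[c]
    # O(N) Fenwick build
    for c in range(NCH):
        for i in range(1, n + 1):
            j = i + (i & (-i))
            if j <= n:
                fen[c, j] += fen[c, i]


@njit(cache=True, inline="always")
def _emp_add(emp_list, emp_pos, emp_count, j):
    emp_list[emp_count[0]] = j
    emp_pos[j] = emp_count[0]
    emp_count[0] += 1


@njit(cache=True, inline="always")
def _emp_remove(emp_list, emp_pos, emp_count, j):
    k = emp_pos[j]
    last = emp_count[0] - 1
    m = emp_list[last]
    emp_list[k] = m
    emp_pos[m] = k
    emp_pos[j] = -1
    emp_count[0] = last


@njit(cache=True, inline="always")
def _iota_of_n(n_tot, pvec):
    k = pvec[P_NREF_EXP]
    nr = pvec[P_NREF] ** k
    return 2.0 * pvec[P_IOTA_XS] * nr / (nr + n_tot ** k)


@njit(cache=True, inline="always")
def _death_factor(n_i, n_star, mode, fixed_rate, pvec):
    if mode == DM_FIXED:
        return fixed_rate
    if n_star <= 0.0:
        return 0.0
    if mode == DM_STEP:
        return pvec[P_STEP_LO] if n_i < n_star else pvec[P_STEP_HI]
    r = n_i / n_star
    if mode == DM_LINEAR:
        return r * pvec[P_VG]
    return r ** (1.0 / 3.0) * pvec[P_VG]


@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _classify(bmap, x, y, res):
    side = bmap.shape[0]
    xi = int(x / res + 0.5)
    yi = int(y / res + 0.5)
    if xi >= side:
        xi = side - 1
    if yi >= side:
        yi = side - 1
    return bmap[xi, yi]


@njit(cache=True, inline="always")
def _level_index(v, lev0, step, nlev):
    q = int((v - lev0) / step + 0.5)
    if q < 0:
        q = 0
    if q >= nlev:
        q = nlev - 1
    return q


@njit(cache=True)
def _advance(occ, xdet, ydet, s1, s2, sl, sa, nbr, nnbr, seeddisc,
             W, fen, tot, pvec, mvec, s_maps, p_maps, pts_s, pts_pmid,
             emp_list, emp_pos, emp_count,
             counts, accs, tallies, tvar, wloc,
             max_events, t_stop, div_target):
    """Run up to ``max_events`` reaction events; returns the number executed.

    Stops early at ``t_stop``, at the division target, or when the total
    propensity vanishes (status in ``mvec[M_STATUS]``).
    """
    n = occ.shape[0]
    topbit = 1
    while topbit * 2 <= n:
        topbit *= 2
    fac = np.empty(NCH)
    cand = np.empty(4, dtype=np.int64)
    dmode = mvec[M_DEATH_MODE]
    ev = 0
    t = tvar[0]

    while ev < max_events and t < t_stop:
        phase = mvec[M_PHASE]
        n_tot = float(counts[0] + counts[1] + counts[2] + counts[3])
        for c in range(NCH):
            fac[c] = 1.0
        fac[CH_S_DIV] = pvec[P_RS] if phase >= 2 else 0.0
        fac[CH_S_TRANS] = pvec[P_WP] if phase >= 2 else 0.0
        fac[CH_S_MOVE] = pvec[P_MS]
        fac[CH_P_DIV] = pvec[P_RP]
        fac[CH_P_TRANS] = pvec[P_WS]
        fac[CH_P_MOVE] = pvec[P_MP]
        fac[CH_A_DEATH] = _death_factor(float(counts[2]), pvec[P_NSTAR_A],
                                        dmode, pvec[P_GA_FIX], pvec)
        fac[CH_B_DEATH] = _death_factor(float(counts[3]), pvec[P_NSTAR_B],
                                        dmode, pvec[P_GB_FIX], pvec)
        fac[CH_APOPT] = pvec[P_ADH_APOP]
        fac[CH_XS_PROD] = _iota_of_n(n_tot, pvec)

        total = 0.0
        for c in range(NCH):
            total += fac[c] * tot[c]
        if total <= 0.0:
            mvec[M_STATUS] = ST_STALLED
            break

        dt = np.random.exponential(1.0 / total)
        t += dt
        accs[0] += counts[0] * dt
        accs[1] += counts[1] * dt
        accs[2] += counts[2] * dt
        accs[3] += counts[3] * dt

        r = np.random.random() * total
        ch = NCH - 1
        acc = 0.0
        for c in range(NCH):
            acc += fac[c] * tot[c]
            if r < acc:
                ch = c
                break
        resid = r - (acc - fac[ch] * tot[ch])
        u = resid / fac[ch]
        if u >= tot[ch]:
            u = tot[ch] * 0.9999999999
        i = _fen_find(fen[ch], u, n, topbit)
        ev += 1
        tallies[T_EVENTS] += 1
        if W[ch, i] <= 0.0:
            continue  # float-drift guard: treat as null event

        # ------------------------------------------------ event application
        if ch == CH_S_DIV or ch == CH_P_DIV:
            if ch == CH_P_DIV:
                # the division clock counts channel firings; a firing without
                # an empty neighbour is still a no-op for the state
                tallies[T_PDIV] += 1
            k = 0
            for q in range(nnbr[i]):
                j = nbr[i, q]
                if occ[j] == 0:
                    cand[k] = j
                    k += 1
            if k == 0:
                tallies[T_BLOCKED_DIV] += 1
            else:
                j = cand[np.random.randint(k)]
                x1 = np.random.binomial(xdet[i], 0.5)
                y1 = np.random.binomial(ydet[i], 0.5)
                x2 = xdet[i] - x1
                y2 = ydet[i] - y1
                res = pvec[P_MAP_RES]
                if ch == CH_S_DIV:
                    # classify against the stem basins at the current
                    # density-modulated iota_xs(n)
                    li = _level_index(fac[CH_XS_PROD], pvec[P_IOTA_L0],
                                      pvec[P_IOTA_STEP], s_maps.shape[0])
                    s_map = s_maps[li]
                    f1 = _classify(s_map, x1, y1, res)
                    f2 = _classify(s_map, x2, y2, res)
                    nsp = (1 if f1 == 2 else 0) + (1 if f2 == 2 else 0)
                    if nsp == 0:
                        tallies[T_SS] += 1
                    elif nsp == 1:
                        tallies[T_S_SP] += 1
                    else:
                        tallies[T_S_PP] += 1
                else:
                    # classify against the progenitor basins shifted by the
                    # mother mesh's local signalling coefficients
                    e1, e2 = _eps_pair(float(sl[i]), float(s1[i]),
                                       float(s2[i]), pvec, mvec[M_LEAD_ACTIVE])
                    q1 = _level_index(e1, pvec[P_EPS_L0], pvec[P_EPS_STEP],
                                      p_maps.shape[0])
                    q2 = _level_index(e2, pvec[P_EPS_L0], pvec[P_EPS_STEP],
                                      p_maps.shape[1])
                    p_map = p_maps[q1, q2]
                    f1 = _classify(p_map, x1, y1, res)
                    f2 = _classify(p_map, x2, y2, res)
                    na = (1 if f1 == 3 else 0) + (1 if f2 == 3 else 0)
                    nb_ = (1 if f1 == 4 else 0) + (1 if f2 == 4 else 0)
                    if na == 0 and nb_ == 0:
                        tallies[T_P_PP] += 1
                    elif na == 1 and nb_ == 0:
                        tallies[T_P_PA] += 1
                    elif na == 0 and nb_ == 1:
                        tallies[T_P_PB] += 1
                    elif na == 1 and nb_ == 1:
                        tallies[T_P_AB] += 1
                    elif na == 2:
                        tallies[T_P_AA] += 1
                    else:
                        tallies[T_P_BB] += 1
                counts[occ[i] - 1] -= 1
                # offspring 1 in the mother's mesh, offspring 2 next door
                occ[i] = f1
                occ[j] = f2
                if f1 == 3 or f1 == 4:
                    xdet[i] = 0
                    ydet[i] = 0
                elif ch == CH_S_DIV and f1 == 2:
                    q1 = np.random.randint(pts_pmid.shape[0])
                    xdet[i] = pts_pmid[q1, 0]
                    ydet[i] = pts_pmid[q1, 1]
                else:
                    xdet[i] = x1
                    ydet[i] = y1
                if f2 == 3 or f2 == 4:
                    xdet[j] = 0
                    ydet[j] = 0
                elif ch == CH_S_DIV and f2 == 2:
                    q2 = np.random.randint(pts_pmid.shape[0])
                    xdet[j] = pts_pmid[q2, 0]
                    ydet[j] = pts_pmid[q2, 1]
                else:
                    xdet[j] = x2
                    ydet[j] = y2
                counts[f1 - 1] += 1
                counts[f2 - 1] += 1
                _emp_remove(emp_list, emp_pos, emp_count, j)
                _refresh_mesh(i, occ, xdet, ydet, s1, s2, sl, sa, nnbr,
                              seeddisc, pvec, mvec, W, fen, tot, wloc, n)
                _refresh_mesh(j, occ, xdet, ydet, s1, s2, sl, sa, nnbr,
                              seeddisc, pvec, mvec, W, fen, tot, wloc, n)

        elif ch == CH_S_TRANS:
            occ[i] = 2
            q1 = np.random.randint(pts_pmid.shape[0])
            xdet[i] = pts_pmid[q1, 0]
            ydet[i] = pts_pmid[q1, 1]
            counts[0] -= 1
            counts[1] += 1
            tallies[T_WP_CNT] += 1
            _refresh_mesh(i, occ, xdet, ydet, s1, s2, sl, sa, nnbr, seeddisc,
                          pvec, mvec, W, fen, tot, wloc, n)

        elif ch == CH_P_TRANS:
            occ[i] = 1
            q1 = np.random.randint(pts_s.shape[0])
            xdet[i] = pts_s[q1, 0]
            ydet[i] = pts_s[q1, 1]
            counts[1] -= 1
            counts[0] += 1
            tallies[T_WS_CNT] += 1
            _refresh_mesh(i, occ, xdet, ydet, s1, s2, sl, sa, nnbr, seeddisc,
                          pvec, mvec, W, fen, tot, wloc, n)

        elif ch == CH_S_MOVE or ch == CH_P_MOVE:
            j = -1
            if mvec[M_ADH] == 1:
                # restricted migration: neighbour-local in the open medium
                k = 0
                for q in range(nnbr[i]):
                    jj = nbr[i, q]
                    if occ[jj] == 0:
                        cand[k] = jj
                        k += 1
                if k > 0:
                    j = cand[np.random.randint(k)]
            elif emp_count[0] > 0:
                j = emp_list[np.random.randint(emp_count[0])]
            if j < 0:
                tallies[T_BLOCKED_MOVE] += 1
            else:
                _emp_remove(emp_list, emp_pos, emp_count, j)
                _emp_add(emp_list, emp_pos, emp_count, i)
                occ[j] = occ[i]
                xdet[j] = xdet[i]
                ydet[j] = ydet[i]
                occ[i] = 0
                xdet[i] = 0
                ydet[i] = 0
                _refresh_mesh(i, occ, xdet, ydet, s1, s2, sl, sa, nnbr,
                              seeddisc, pvec, mvec, W, fen, tot, wloc, n)
                _refresh_mesh(j, occ, xdet, ydet, s1, s2, sl, sa, nnbr,
                              seeddisc, pvec, mvec, W, fen, tot, wloc, n)

        elif ch == CH_A_DEATH or ch == CH_B_DEATH or ch == CH_APOPT:
            if ch == CH_A_DEATH:
                tallies[T_A_DEATH] += 1
            elif ch == CH_B_DEATH:
                tallies[T_B_DEATH] += 1
            else:
                tallies[T_APOPT] += 1
            counts[occ[i] - 1] -= 1
            occ[i] = 0
            xdet[i] = 0
            ydet[i] = 0
            _emp_add(emp_list, emp_pos, emp_count, i)
            _refresh_mesh(i, occ, xdet, ydet, s1, s2, sl, sa, nnbr, seeddisc,
                          pvec, mvec, W, fen, tot, wloc, n)

        elif ch >= CH_XS_PROD and ch <= CH_YP_DEG:
            if ch == CH_XS_PROD or ch == CH_XP_PROD:
                xdet[i] += 1
            elif ch == CH_YS_PROD or ch == CH_YP_PROD:
                ydet[i] += 1
            elif ch == CH_XS_DEG or ch == CH_XP_DEG:
                xdet[i] -= 1
            else:
                ydet[i] -= 1
            _touch_dets(i, occ, xdet, ydet, s1, s2, sl, pvec, mvec,
                        W, fen, tot, n)

        elif ch >= CH_S1_PROD and ch <= CH_S2_DIFF:
            which = 1 if (ch == CH_S1_PROD or ch == CH_S1_DEG
                          or ch == CH_S1_DIFF) else 2
            j = -1
            if ch == CH_S1_PROD:
                s1[i] += 1
            elif ch == CH_S2_PROD:
                s2[i] += 1
            elif ch == CH_S1_DEG:
                s1[i] -= 1
            elif ch == CH_S2_DEG:
                s2[i] -= 1
            elif ch == CH_S1_DIFF:
                j = nbr[i, np.random.randint(nnbr[i])]
                s1[i] -= 1
                s1[j] += 1
            else:
                j = nbr[i, np.random.randint(nnbr[i])]
                s2[i] -= 1
                s2[j] += 1
            if mvec[M_ADH] == 1:
                _refresh_mesh(i, occ, xdet, ydet, s1, s2, sl, sa, nnbr,
                              seeddisc, pvec, mvec, W, fen, tot, wloc, n)
                if j >= 0:
                    _refresh_mesh(j, occ, xdet, ydet, s1, s2, sl, sa, nnbr,
                                  seeddisc, pvec, mvec, W, fen, tot, wloc, n)
            else:
                _touch_s12(i, which, occ, xdet, ydet, s1, s2, sl, nnbr,
                           pvec, mvec, W, fen, tot, n)
                if j >= 0:
                    _touch_s12(j, which, occ, xdet, ydet, s1, s2, sl, nnbr,
                               pvec, mvec, W, fen, tot, n)

        else:  # leading signal / Turing partner
            j = -1
            if ch == CH_SL_PROD:
                sl[i] += 1
            elif ch == CH_SL_DEG:
                sl[i] -= 1
            elif ch == CH_SL_DIFF:
                j = nbr[i, np.random.randint(nnbr[i])]
                # a full target mesh rejects the molecule (bounds hold always)
                if mvec[M_SCEN] == SCEN_TURING and sl[j] >= int(pvec[P_SUP]):
                    continue
                sl[i] -= 1
                sl[j] += 1
            elif ch == CH_SA_PROD:
                sa[i] += 1
            elif ch == CH_SA_DEG:
                # the (s_a + 1) propensity fires as a null event at zero count
                if sa[i] == 0:
                    continue
                sa[i] -= 1
            else:
                j = nbr[i, np.random.randint(nnbr[i])]
                sa[i] -= 1
                sa[j] += 1
            if mvec[M_ADH] == 1:
                _refresh_mesh(i, occ, xdet, ydet, s1, s2, sl, sa, nnbr,
                              seeddisc, pvec, mvec, W, fen, tot, wloc, n)
                if j >= 0:
                    _refresh_mesh(j, occ, xdet, ydet, s1, s2, sl, sa, nnbr,
                                  seeddisc, pvec, mvec, W, fen, tot, wloc, n)
            else:
                _touch_lead(i, occ, xdet, ydet, s1, s2, sl, sa, nnbr,
                            pvec, mvec, W, fen, tot, n)
                if j >= 0:
                    _touch_lead(j, occ, xdet, ydet, s1, s2, sl, sa, nnbr,
                                pvec, mvec, W, fen, tot, n)

        # stop rule: cumulative P divisions per time-averaged P population
        if div_target > 0.0 and (ev & 4095) == 0 and t > 0.0:
            avg_p = accs[1] / t
            if avg_p > 0.0 and tallies[T_PDIV] >= div_target * avg_p:
                mvec[M_STATUS] = ST_DONE
                tvar[0] = t
                return ev

    tvar[0] = t
    return ev


# --------------------------------------------------------------------------
# driver

def _clip_points(pts: np.ndarray, xmax: float, ymax: float) -> np.ndarray:
    keep = (pts[:, 0] <= xmax) & (pts[:, 1] <= ymax)
    out = pts[keep] if keep.any() else pts
    return np.ascontiguousarray(out)

@dataclasses.dataclass
class Trajectory:
    """Snapshots, abundance traces and event tallies of one simulation run."""

    times: np.ndarray
    snapshots: list[np.ndarray]
    counts: np.ndarray        # (n_snap, 4): n_S, n_P, n_A, n_B
    tallies: np.ndarray       # (n_snap, NTL) cumulative event tallies
    accs: np.ndarray          # (n_snap, 4) cumulative time-integrals of counts
    gammas: np.ndarray        # (n_snap, 2) realized death rates
    final_state: DishState
    sl_pattern: np.ndarray    # leading field at phase-2 entry (scoring template)
    n_star: tuple[float, float]
    status: str
    events: int
    config: "SimConfig"

    def abundances_frame(self):
        import pandas as pd

        return pd.DataFrame(
            np.column_stack([self.times, self.counts]),
            columns=["time", "n_S", "n_P", "n_A", "n_B"],
        )

    def tally(self, name: str) -> int:
        return int(self.tallies[-1, TALLY_NAMES.index(name)])

    def empirical_rates(self, start_frac: float = 0.75) -> dict:
        """Per-capita division-channel rates measured over the trace tail.

        Rates are event counts divided by the time-integral of the relevant
        population over the window, i.e. maximum-likelihood estimates of the
        emergent channel rates of the mean-field model.
        """
        i0 = min(int(len(self.times) * start_frac), len(self.times) - 2)
        dtl = self.tallies[-1] - self.tallies[i0]
        dacc = self.accs[-1] - self.accs[i0]
        dt = self.times[-1] - self.times[i0]
        s_t, p_t, a_t, b_t = (max(v, 1e-300) for v in dacc)
        rates = {
            "eta_s": dtl[T_SS] / s_t, "eta": dtl[T_S_SP] / s_t,
            "eta_p": dtl[T_S_PP] / s_t, "w_p": dtl[T_WP_CNT] / s_t,
            "w_s": dtl[T_WS_CNT] / p_t,
            "lam_p": dtl[T_P_PP] / p_t, "lam_a": dtl[T_P_PA] / p_t,
            "lam_b": dtl[T_P_PB] / p_t, "mu_d": dtl[T_P_AB] / p_t,
            "mu_a": dtl[T_P_AA] / p_t, "mu_b": dtl[T_P_BB] / p_t,
            "gamma_a": dtl[T_A_DEATH] / a_t, "gamma_b": dtl[T_B_DEATH] / b_t,
        }
        rates["mean_counts"] = tuple(dacc / max(dt, 1e-300))
        return rates

    def mean_p_divisions(self) -> float:
        t = self.times[-1]
        if t <= 0:
            return 0.0
        avg_p = self.accs[-1, 1] / t
        return self.tallies[-1, T_PDIV] / avg_p if avg_p > 0 else 0.0


class Simulation:
    """Owns the packed kernel state for one configured run."""

    def __init__(self, config: "SimConfig", initial_state: DishState | None = None):
        self.config = config
        cfg = config
        self.adh = cfg.adhesion.enabled

        s_map, p_map = switches.fate_maps(cfg.sswitch, cfg.pswitch)
        fam = switches.fate_map_families(cfg.sswitch, cfg.pswitch)
        self.s_maps = np.ascontiguousarray(fam["s_maps"])
        self.p_maps = np.ascontiguousarray(fam["p_maps"])
        self._families = fam
        # newborn determinants are drawn from the basin restricted to the
        # dynamically reachable region (synthesis / degradation bound): the
        # classification map is wider only so that any count pair has a label
        ss, ps = cfg.sswitch, cfg.pswitch
        s_xmax = 2.0 * ss.iota_x / ss.gamma
        s_ymax = ss.iota_y / ss.gamma
        p_max = (ps.alpha_x + ps.iota_x) / ps.gamma
        self.pts_s = _clip_points(s_map.points(S), s_xmax, s_ymax)
        self.pts_pmid = _clip_points(p_map.points(P), p_max, p_max)

        if self.adh:
            side = int(np.ceil(cfg.adhesion.grid_factor * (2 * cfg.radius + 1)))
            mask = np.ones((side, side), dtype=bool)
            self.seed_disc = seed_disc_mask(side, cfg.radius)
        else:
            mask = lattice.dish_mask(cfg.radius)
            side = mask.shape[0]
            self.seed_disc = np.zeros((side, side), dtype=bool)
        self.mask = mask
        self.side = side
        n_in = int((self.seed_disc if self.adh else mask).sum())

        if initial_state is not None:
            state = initial_state.copy()
        else:
            n_stem = cfg.n_stem if cfg.n_stem is not None else int(
                round(cfg.stem_fraction * n_in))
            if self.adh:
                state = lattice.DishState(
                    radius=cfg.radius,
                    occ=np.zeros((side, side), np.int8),
                    xdet=np.zeros((side, side), np.int64),
                    ydet=np.zeros((side, side), np.int64),
                    s1=np.zeros((side, side), np.int64),
                    s2=np.zeros((side, side), np.int64),
                    sl=np.zeros((side, side), np.int64),
                    sa=np.zeros((side, side), np.int64), seed=cfg.seed)
                rng = np.random.default_rng(cfg.seed)
                idx = np.flatnonzero(self.seed_disc.ravel())
                chosen = rng.choice(idx, size=min(n_stem, idx.size), replace=False)
                det = rng.integers(0, len(self.pts_s), size=chosen.size)
                state.occ.ravel()[chosen] = S
                state.xdet.ravel()[chosen] = self.pts_s[det, 0]
                state.ydet.ravel()[chosen] = self.pts_s[det, 1]
            else:
                state = lattice.init_dish(cfg.radius, n_stem, self.pts_s,
                                          seed=cfg.seed)

        lead = cfg.leading
        if lead.scenario == "fixed":
            if cfg.sl_field is not None:
                field = np.asarray(cfg.sl_field, dtype=np.int64)
            else:
                field = signals.fixed_pattern(lead.pattern, cfg.radius)
            if field.shape != state.sl.shape:
                if field.shape[0] > state.sl.shape[0]:
                    raise ValueError("sl_field larger than the grid")
                off = (state.sl.shape[0] - field.shape[0]) // 2
                big = np.zeros_like(state.sl)
                big[off:off + field.shape[0], off:off + field.shape[1]] = field
                field = big
            state.sl = field.copy()
        elif lead.scenario == "turing":
            s0, sa0 = signals.turing_uniform_start(lead)
            state.sl = np.where(mask, s0, 0).astype(np.int64)
            state.sa = np.where(mask, sa0, 0).astype(np.int64)
        self.state = state

        # flat views
        self.occ = state.occ.ravel()
        self.xdet = state.xdet.ravel()
        self.ydet = state.ydet.ravel()
        self.s1 = state.s1.ravel()
        self.s2 = state.s2.ravel()
        self.sl = state.sl.ravel()
        self.sa = state.sa.ravel()
        self.nbr, self.nnbr = lattice.neighbor_table(mask)
        self.seeddisc_flat = self.seed_disc.ravel().astype(np.uint8)

        self.n = self.occ.size
        # swap-remove registry of empty in-region meshes (global movement)
        region = (np.ones_like(self.occ, dtype=bool) if self.adh
                  else mask.ravel())
        empties = np.flatnonzero(region & (self.occ == 0))
        self.emp_list = np.full(self.n, -1, dtype=np.int32)
        self.emp_pos = np.full(self.n, -1, dtype=np.int32)
        self.emp_list[:empties.size] = empties
        self.emp_pos[empties] = np.arange(empties.size, dtype=np.int32)
        self.emp_count = np.array([empties.size], dtype=np.int64)
        self.W = np.zeros((NCH, self.n))
        self.fen = np.zeros((NCH, self.n + 1))
        self.tot = np.zeros(NCH)
        self.wloc = np.zeros(NCH)
        self.counts = np.array(lattice.recount_abundances(state), dtype=np.int64)
        self.accs = np.zeros(4)
        self.tallies = np.zeros(NTL, dtype=np.int64)
        self.tvar = np.array([state.time])

        self.n_in_dish = n_in
        n_ref = cfg.n_ref if cfg.n_ref is not None else 0.85 * n_in
        self.pvec = self._pack_pvec(n_ref)
        self.mvec = self._pack_mvec()
        self.sl_pattern = state.sl.copy().reshape(side, side)
        self._set_n_star()
        _seed_rng(int(cfg.seed) % (2**31 - 1))
        self.rebuild()

    # -- packing -----------------------------------------------------------
    def _pack_pvec(self, n_ref) -> np.ndarray:
        cfg = self.config
        e, ss, ps, ts, ld, dc, ad = (cfg.engine, cfg.sswitch, cfg.pswitch,
                                     cfg.territory, cfg.leading, cfg.death,
                                     cfg.adhesion)
        p = np.zeros(NPV)
        p[P_RS], p[P_WP], p[P_MS] = e.r_s, e.w_p, e.m_s
        p[P_RP], p[P_WS], p[P_MP] = e.r_p, e.w_s, e.m_p
        p[P_IOTA_XS], p[P_IOTA_YS] = ss.iota_x, ss.iota_y
        p[P_BSN], p[P_NS], p[P_GAMMA_S] = ss.beta**ss.hill_n, ss.hill_n, ss.gamma
        p[P_ALPHA_XP], p[P_ALPHA_YP] = ps.alpha_x, ps.alpha_y
        p[P_IOTA_XP], p[P_IOTA_YP] = ps.iota_x, ps.iota_y
        p[P_BPN], p[P_NP], p[P_GAMMA_P] = ps.beta**ps.hill_n, ps.hill_n, ps.gamma
        p[P_EPS_A], p[P_EPS_B] = ps.eps_a, ps.eps_b
        # the complementary response tracks the actual leading-signal scale
        p[P_SL_MAX] = (ld.s_upper if ld.scenario == "turing" else ps.sl_max)
        p[P_T_ALPHA], p[P_T_BN] = ts.alpha, ts.beta**ts.hill_n
        p[P_T_N], p[P_T_K], p[P_T_D] = ts.hill_n, ts.k, ts.D / ts.h**2
        p[P_ALPHA_SL], p[P_K_SL], p[P_D_SL] = ld.alpha_sl, ld.k_sl, ld.D_sl
        p[P_DL], p[P_DA], p[P_GSL], p[P_GSA] = ld.d_l, ld.d_a, ld.gamma_sl, ld.gamma_sa
        p[P_TA], p[P_TB], p[P_TC] = ld.A, ld.B, ld.C
        p[P_SUP], p[P_SLO] = ld.s_upper, ld.s_lower
        p[P_NREF], p[P_NREF_EXP] = n_ref, ss.n_ref_exp
        p[P_VG], p[P_STEP_LO], p[P_STEP_HI] = dc.v_g, dc.step_low, dc.step_high
        p[P_GA_FIX], p[P_GB_FIX] = dc.gamma_A_fixed, dc.gamma_B_fixed
        p[P_ADH_THR] = ad.matrix_threshold
        p[P_ADH_MOVEPEN] = ad.movement_penalty
        p[P_ADH_APOP] = ad.apoptosis_rate if ad.enabled else 0.0
        fam = self._families
        p[P_MAP_RES] = fam["resolution"]
        p[P_EPS_L0] = fam["eps_levels"][0]
        p[P_EPS_STEP] = fam["eps_levels"][1] - fam["eps_levels"][0]
        p[P_IOTA_L0] = fam["iota_levels"][0]
        p[P_IOTA_STEP] = fam["iota_levels"][1] - fam["iota_levels"][0]
        p[P_DIFF_MODE] = 0.0 if cfg.diffusion_kinetics == "table" else 1.0
        return p

    def _pack_mvec(self) -> np.ndarray:
        cfg = self.config
        m = np.zeros(NMV, dtype=np.int64)
        m[M_PHASE] = self.state.phase
        m[M_SCEN] = {"none": SCEN_STATIC, "fixed": SCEN_STATIC,
                     "diffusive": SCEN_DIFFUSIVE,
                     "turing": SCEN_TURING}[cfg.leading.scenario]
        m[M_ADH] = 1 if cfg.adhesion.enabled else 0
        m[M_SRC_ALL] = 1 if cfg.leading.sources == "all" else 0
        m[M_DEATH_MODE] = {"fixed": DM_FIXED, "step": DM_STEP,
                           "linear": DM_LINEAR, "cube_root": DM_CUBE}[cfg.death.mode]
        m[M_STATUS] = ST_RUNNING
        m[M_LEAD_ACTIVE] = 0 if cfg.leading.scenario == "none" else 1
        return m

    def _set_n_star(self):
        """Targets from the death config, or from the leading pattern."""
        dc = self.config.death
        if dc.mode == "fixed":
            na = nb = 0.0
        elif dc.n_star_A is not None and dc.n_star_B is not None:
            na, nb = dc.n_star_A, dc.n_star_B
        else:
            region = self.seed_disc if self.adh else self.mask
            peak = float(self.sl_pattern.max())
            if peak <= 0:
                # no pattern: split the occupancy budget evenly
                half = 0.5 * dc.occupancy_fraction * region.sum()
                na = nb = half
            else:
                na, nb = target_abundances(self.sl_pattern, region,
                                           dc.occupancy_fraction, peak / 2.0)
        self.pvec[P_NSTAR_A] = na
        self.pvec[P_NSTAR_B] = nb

    # -- stepping ----------------------------------------------------------
    def rebuild(self):
        _rebuild(self.occ, self.xdet, self.ydet, self.s1, self.s2, self.sl,
                 self.sa, self.nnbr, self.seeddisc_flat, self.pvec, self.mvec,
                 self.W, self.fen, self.tot, self.wloc)

    def set_phase(self, phase: int):
        self.state.phase = phase
        self.mvec[M_PHASE] = phase
        if phase == 2:
            self.sl_pattern = self.sl.reshape(self.side, self.side).copy()
            self._set_n_star()
        self.rebuild()

    def advance(self, max_events: int, t_stop: float = np.inf,
                div_target: float = 0.0) -> int:
        ev = _advance(self.occ, self.xdet, self.ydet, self.s1, self.s2,
                      self.sl, self.sa, self.nbr, self.nnbr,
                      self.seeddisc_flat, self.W, self.fen, self.tot,
                      self.pvec, self.mvec, self.s_maps, self.p_maps,
                      self.pts_s, self.pts_pmid,
                      self.emp_list, self.emp_pos, self.emp_count,
                      self.counts, self.accs,
                      self.tallies, self.tvar, self.wloc,
                      max_events, t_stop, div_target)
        self.state.time = float(self.tvar[0])
        return ev

    @property
    def status(self) -> int:
        return int(self.mvec[M_STATUS])

    def gamma_now(self) -> tuple[float, float]:
        dm = int(self.mvec[M_DEATH_MODE])
        dc = self.config.death
        if dm == DM_FIXED:
            return dc.gamma_A_fixed, dc.gamma_B_fixed
        na, nb = self.pvec[P_NSTAR_A], self.pvec[P_NSTAR_B]
        ga = death_rate(int(self.counts[2]), na, dc) if na > 0 else 0.0
        gb = death_rate(int(self.counts[3]), nb, dc) if nb > 0 else 0.0
        return ga, gb


def run_simulation(config: "SimConfig", initial_state: DishState | None = None,
                   phases: Sequence[int] = (1, 2, 3)) -> Trajectory:
    """Run the configured simulation through the requested phases.

    Snapshots (occupancy grids, abundances, cumulative tallies, realized
    death rates) are recorded every ``config.snapshot_events`` events.  Fully
    reproducible under a fixed seed.
    """
    sim = Simulation(config, initial_state)
    cfg = config
    times, snaps, counts_h, tallies_h, accs_h, gammas_h = [], [], [], [], [], []

    def record():
        times.append(sim.state.time)
        snaps.append(sim.occ.reshape(sim.side, sim.side).copy())
        counts_h.append(sim.counts.copy())
        tallies_h.append(sim.tallies.copy())
        accs_h.append(sim.accs.copy())
        gammas_h.append(sim.gamma_now())

    record()
    total_ev = 0
    rebuild_every = 5_000_000
    since_rebuild = 0

    # ---- phase 1: signal maturation (skipped when starting mid-run)
    if 1 in phases and sim.state.phase == 1:
        if cfg.phase1_time is not None:
            t_end = sim.state.time + cfg.phase1_time
            while sim.state.time < t_end and sim.status == ST_RUNNING:
                budget = min(cfg.snapshot_events, cfg.max_events - total_ev)
                if budget <= 0:
                    break
                ev = sim.advance(budget, t_stop=t_end)
                total_ev += ev
                since_rebuild += ev
                if since_rebuild >= rebuild_every:
                    sim.rebuild()
                    since_rebuild = 0
                record()
                if ev == 0:
                    break
        else:
            remaining = cfg.phase1_iterations
            while remaining > 0 and sim.status == ST_RUNNING:
                ev = sim.advance(min(cfg.snapshot_events, remaining))
                total_ev += ev
                remaining -= ev
                record()
                if ev == 0:
                    break

    if 2 in phases and sim.status != ST_STALLED:
        sim.mvec[M_STATUS] = ST_RUNNING
        sim.set_phase(max(2, sim.state.phase))
        while (sim.status == ST_RUNNING and total_ev < cfg.max_events
               and sim.state.time < cfg.max_time):
            ev = sim.advance(min(cfg.snapshot_events, cfg.max_events - total_ev),
                             t_stop=cfg.max_time,
                             div_target=cfg.division_target)
            total_ev += ev
            since_rebuild += ev
            if since_rebuild >= rebuild_every:
                sim.rebuild()
                since_rebuild = 0
            record()
            if (3 in phases and sim.state.phase == 2
                    and sim.counts[2] >= cfg.ab_threshold
                    and sim.counts[3] >= cfg.ab_threshold):
                sim.set_phase(3)
            if ev == 0:
                break

    status = {ST_RUNNING: "event_budget", ST_STALLED: "stalled",
              ST_DONE: "division_target"}[sim.status]
    sim.state.occ = sim.occ.reshape(sim.side, sim.side)
    return Trajectory(
        times=np.array(times), snapshots=snaps,
        counts=np.array(counts_h), tallies=np.array(tallies_h),
        accs=np.array(accs_h), gammas=np.array(gammas_h),
        final_state=sim.state, sl_pattern=sim.sl_pattern,
        n_star=(float(sim.pvec[P_NSTAR_A]), float(sim.pvec[P_NSTAR_B])),
        status=status, events=total_ev, config=config,
    )
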