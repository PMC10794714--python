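"""Well-mixed mean-field model of the cell-type densities.

The lattice model coarse-grains to four densities (n_S, n_P, n_A, n_B)
driven by the division channels of stem cells (S -> S+P at eta, S -> S+S at
eta_S(n), S -> P+P at eta_P), the reversible S <-> P transitions (w_P, w_S),
the six progenitor division channels (P -> P+P at lambda_P, P -> A+P / B+P
at lambda_A/B, P -> A+B at mu_d, P -> A+A / B+B at mu_A/B) and death of the
specialized cells (gamma_A, gamma_B):

    dn_S/dt = n_S eta_S - n_S eta_P + n_P w_S - n_S w_P
    dn_P/dt = n_S eta + 2 n_S eta_P + n_S w_P - n_P w_S
              - n_P (-lambda_P + mu_d + mu_A + mu_B)
    dn_A/dt = n_P (lambda_A + mu_d + 2 mu_A) - n_A gamma_A
    dn_B/dt = n_P (lambda_B + mu_d + 2 mu_B) - n_B gamma_B

The system has a stable homeostatic state (n_A*, n_B*, n_P*, n*) provided
eta_S'(n) < 0 and lambda_P < mu_d + mu_A + mu_B.  In the lattice model the
division channels are emergent (they arise from binomial determinant
partitioning and basin classification), so the channel rates here are either
chosen directly or measured empirically from engine event logs; this module
then serves as a consistency oracle for the engine.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from scipy import integrate, optimize


@dataclasses.dataclass
class MeanFieldParams:
    eta: float            # S -> S + P
    eta_s: Callable[[float], float] | float   # S -> S + S, decreasing in n
    eta_p: float          # S -> P + P
    w_p: float            # S -> P
    w_s: float            # P -> S
    lam_p: float          # P -> P + P
    lam_a: float          # P -> A + P
    lam_b: float          # P -> B + P
    mu_d: float           # P -> A + B
    mu_a: float           # P -> A + A
    mu_b: float           # P -> B + B
    gamma_a: float
    gamma_b: float

    def eta_s_at(self, n: float) -> float:
        return self.eta_s(n) if callable(self.eta_s) else float(self.eta_s)


def decreasing_eta_s(eta_s_ref: float, n_ref: float, exponent: float = 4.0):
    """Hill-decay self-renewal rate anchored to ``eta_s_ref`` at ``n_ref``."""
    def eta_s(n):
        return 2.0 * eta_s_ref * n_ref**exponent / (n_ref**exponent + float(n) ** exponent)
    return eta_s


def meanfield_rhs(n_vec, params: MeanFieldParams):
    """Time derivatives (dn_S, dn_P, dn_A, dn_B)."""
    n_s, n_p, n_a, n_b = (float(v) for v in n_vec)
    if min(n_s, n_p, n_a, n_b) < 0:
        raise ValueError("densities must be non-negative")
    n = n_s + n_p + n_a + n_b
    eta_s = params.eta_s_at(n)
    d_s = n_s * eta_s - n_s * params.eta_p + n_p * params.w_s - n_s * params.w_p
    d_p = (n_s * params.eta + 2.0 * n_s * params.eta_p + n_s * params.w_p
           - n_p * params.w_s
           - n_p * (-params.lam_p + params.mu_d + params.mu_a + params.mu_b))
    d_a = n_p * (params.lam_a + params.mu_d + 2.0 * params.mu_a) - n_a * params.gamma_a
    d_b = n_p * (params.lam_b + params.mu_d + 2.0 * params.mu_b) - n_b * params.gamma_b
    return d_s, d_p, d_a, d_b


def check_stability_conditions(params: MeanFieldParams,
                               n_range: tuple[float, float] = (1.0, 1e4),
                               n_samples: int = 64) -> tuple[bool, dict]:
    """Verify eta_S'(n) < 0 over a density range and lambda_P < mu_d+mu_A+mu_B."""
    ns = np.geomspace(max(n_range[0], 1e-9), n_range[1], n_samples)
    vals = np.array([params.eta_s_at(n) for n in ns])
    decreasing = bool(np.all(np.diff(vals) < 0))
    asym = params.mu_d + params.mu_a + params.mu_b
    division_ok = params.lam_p < asym
    report = {
        "eta_s_decreasing": decreasing,
        "lambda_p": params.lam_p,
        "asymmetric_total": asym,
        "division_condition": division_ok,
    }
    return decreasing and division_ok, report


class ConvergenceError(RuntimeError):
    def __init__(self, msg, tail=None):
        super().__init__(msg)
        self.tail = tail


@dataclasses.dataclass
class SteadyState:
    n_s: float
    n_p: float
    n_a: float
    n_b: float
    eigenvalues: np.ndarray

    @property
    def n(self) -> float:
        return self.n_s + self.n_p + self.n_a + self.n_b

    def as_tuple(self):
        """(n_A*, n_B*, n_P*, n*)."""
        return self.n_a, self.n_b, self.n_p, self.n


def _jacobian(params, v, h=1e-6):
    jac = np.zeros((4, 4))
    for j in range(4):
        vp = v.copy(); vm = v.copy()
        step = h * max(1.0, abs(v[j]))
        vp[j] += step
        vm[j] = max(vm[j] - step, 0.0)
        fp = np.array(meanfield_rhs(vp, params))
        fm = np.array(meanfield_rhs(vm, params))
        jac[:, j] = (fp - fm) / (vp[j] - vm[j])
    return jac


def steady_state(params: MeanFieldParams, initial, horizon: float = 2000.0,
                 tol: float = 1e-9) -> SteadyState:
    """Homeostatic fixed point found by forward integration plus root polish.

    Integrates from ``initial`` until the RHS norm drops below ``tol`` (then
    polishes with a Newton solve), raising :class:`ConvergenceError` with
    the trajectory tail otherwise.  The Jacobian's eigenvalues at the
    returned point all have negative real part.
    """
    y0 = np.asarray(initial, dtype=float)
    sol = integrate.solve_ivp(lambda t, y: meanfield_rhs(np.maximum(y, 0.0), params),
                              (0.0, horizon), y0, method="LSODA",
                              rtol=1e-10, atol=1e-10, dense_output=False)
    yT = np.maximum(sol.y[:, -1], 0.0)
    root = optimize.root(lambda v: np.array(meanfield_rhs(np.maximum(v, 0.0), params)),
                         yT, method="hybr", tol=1e-13)
    v = np.maximum(root.x, 0.0)
    resid = np.linalg.norm(meanfield_rhs(v, params))
    # judge by the residual itself: the hybrid solver sometimes reports
    # failure (step-size underflow) at an already-converged point
    if resid > tol:
        raise ConvergenceError(
            f"no steady state within horizon (residual {resid:.3g})",
            tail=sol.y[:, -10:])
    # a diverging trajectory can still be polished onto some unrelated root
    # (e.g. the absorbing origin); demand that the integration itself settled
    if np.linalg.norm(v - yT) > 1e-2 * (1.0 + np.linalg.norm(yT)):
        raise ConvergenceError("trajectory did not settle within the horizon",
                               tail=sol.y[:, -10:])
    eig = np.linalg.eigvals(_jacobian(params, v))
    if np.real(eig).max() > 0:
        raise ConvergenceError("reached fixed point is not attracting",
                               tail=sol.y[:, -10:])
    return SteadyState(*v, eigenvalues=eig)
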