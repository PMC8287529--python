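"""Muscle recruitment: the redundancy problem at a fixed joint state.

Only the three rotational (moment) equations about the GH center enter
recruitment; the three translational equations are resolved separately
by the force-dependent-kinematics loop.  Given the moment-arm matrix R
(3 x n, N·m per N of muscle force) and the external moment M_ext
(gravity + contact + spring), the solver finds nonnegative,
strength-bounded muscle forces minimizing the polynomial criterion

    minimize  sum_i (f_i / N_i)^p      subject to  R f = -M_ext,
              0 <= f_i <= bound_i,

with p = 2 by default (the quadratic polynomial criterion); p is a
configuration knob used by the sensitivity sweep.  Deficient muscles
keep their strength N_i for normalization but carry a zero upper bound.
Infeasibility is a reported status, not an exception, so sweeps can
record failed steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import GHState, ShoulderModel, abduction_rotation

__all__ = ["EquilibriumSystem", "RecruitmentSolution", "muscle_geometry",
           "moment_arms", "solve_recruitment"]


@dataclass
class EquilibriumSystem:
    """Moment balance R f = -M_ext with box bounds on muscle forces."""

    moment_arms: np.ndarray        # (m, n): N·m per N, about the GH center
    external_moment: np.ndarray    # (m,), N·m
    strengths: np.ndarray          # (n,), N — activation normalization
    bounds: np.ndarray = None      # (n,), N — upper bounds (0 if deficient)

    def __post_init__(self):
        self.moment_arms = np.atleast_2d(np.asarray(self.moment_arms, float))
        self.external_moment = np.atleast_1d(
            np.asarray(self.external_moment, float))
        self.strengths = np.atleast_1d(np.asarray(self.strengths, float))
        if self.bounds is None:
            self.bounds = self.strengths.copy()
        self.bounds = np.atleast_1d(np.asarray(self.bounds, float))
        m, n = self.moment_arms.shape
        if self.external_moment.shape != (m,):
            raise ValueError("external moment dimension mismatch")
        if self.strengths.shape != (n,) or self.bounds.shape != (n,):
            raise ValueError("strength/bound dimension mismatch")
        if not np.all(np.isfinite(self.moment_arms)):
            raise ValueError("moment arms must be finite")
        if np.any(self.strengths <= 0) or np.any(self.bounds < 0):
            raise ValueError("strengths must be positive, bounds nonnegative")


@dataclass
class RecruitmentSolution:
    """Outcome of one recruitment solve."""

    forces: np.ndarray             # N
    activations: np.ndarray        # f_i / N_i
    objective: float               # sum of activations**p
    status: str                    # "optimal" | "infeasible"
    residual: float = 0.0          # ||R f + M_ext||, N·m

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def muscle_geometry(model: ShoulderModel, state: GHState):
    """Attachment points and unit pull directions at a joint state.

    For each muscle, the force on the humerus acts at the first
    humerus-bound path point and pulls toward the adjacent fixed
    (ground) point; straight polyline paths, no wrapping.  Returns
    ``(attachments (n,3), directions (n,3))`` in the ground frame.
    """
    angle = state.abduction_angle * model.rhythm_fraction
    R = abduction_rotation(angle)
    u = state.translation
    attach = np.empty((len(model.muscles), 3))
    dirs = np.empty((len(model.muscles), 3))
    for i, mus in enumerate(model.muscles):
        segs = [seg for seg, _ in mus.path]
        try:
            ih = segs.index("humerus")
        except ValueError:
            raise ValueError(
                f"muscle {mus.name!r}: no humerus-bound path point") from None
        p_h = R @ mus.path[ih][1] + u
        # adjacent ground point (prefer the proximal neighbour)
        j = ih - 1 if ih > 0 else ih + 1
        seg_j, p_j = mus.path[j]
        target = p_j if seg_j != "humerus" else mus.path[ih + 1][1]
        if seg_j == "humerus":
            target = R @ target + u
        line = target - p_h
        length = np.linalg.norm(line)
        if length < 1e-12:
            raise ValueError(f"muscle {mus.name!r}: zero-length path segment")
        attach[i] = p_h
        dirs[i] = line / length
    return attach, dirs


def moment_arms(model: ShoulderModel, state: GHState) -> np.ndarray:
    """Moment-arm matrix (3 x n) about the translated GH center.

    Column i is ``(p_i - c) x u_i`` where ``p_i`` is the humeral
    attachment, ``u_i`` the unit line of action and ``c`` the head
    center (GH origin plus translation).
    """
    attach, dirs = muscle_geometry(model, state)
    c = state.translation
    return np.cross(attach - c, dirs).T


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def _polish_equality(A, b, x, lo, hi):
    """Project x onto the affine constraint A x = b, then clip to bounds."""
    r = b - A @ x
    AAT = A @ A.T
    try:
        lam = np.linalg.solve(AAT, r)
    except np.linalg.LinAlgError:
        lam, *_ = np.linalg.lstsq(AAT, r, rcond=None)
    return np.clip(x + A.T @ lam, lo, hi)


def solve_recruitment(system: EquilibriumSystem,
                      criterion_order: int = 2) -> RecruitmentSolution:
    """Minimize the polynomial criterion subject to the moment balance.

    Works in activation space (x = f / N) for conditioning; solved with
    SLSQP from a feasible interior start found by linear programming.
    ``status="infeasible"`` is returned when no bounded force vector can
    balance the moment (within the LP tolerance).
    """
    p = int(criterion_order)
    if p < 2:
        raise ValueError("criterion order must be >= 2")
    R, b = system.moment_arms, -system.external_moment
    N, ub = system.strengths, system.bounds
    m, n = R.shape
    moment_scale = max(1.0, np.linalg.norm(b))

    # scaled problem: A x = b with x = f / N in [0, xmax]
    A = R * N[None, :]
    xmax = ub / N

    active = xmax > 0.0
    if not active.any():
        forces = np.zeros(n)
        resid = float(np.linalg.norm(R @ forces - b))
        if resid <= 1e-6 * moment_scale:
            return RecruitmentSolution(forces, forces / N, 0.0, "optimal",
                                       resid)
        return RecruitmentSolution(forces, forces / N, np.inf, "infeasible",
                                   resid)

    Aa = A[:, active]
    xm = xmax[active]
    na = int(active.sum())

    lp = optimize.linprog(np.zeros(na), A_eq=Aa, b_eq=b,
                          bounds=list(zip(np.zeros(na), xm)),
                          method="highs")
    if not lp.success:
        forces = np.zeros(n)
        return RecruitmentSolution(forces, forces / N, np.inf, "infeasible",
                                   float(np.linalg.norm(b)))

    def fun(x):
        return float(np.sum(x ** p))

    def grad(x):
        return p * x ** (p - 1)

    x0 = np.clip(lp.x, 0.0, xm)
    res = optimize.minimize(
        fun, x0, jac=grad, method="SLSQP",
        bounds=[(0.0, float(h)) for h in xm],
        constraints=[{"type": "eq", "fun": lambda x: Aa @ x - b,
                      "jac": lambda x: Aa}],
        options={"ftol": 1e-14, "maxiter": 300})
    x = np.clip(res.x, 0.0, xm)
    x = _polish_equality(Aa, b, x, 0.0, xm)
    resid = float(np.linalg.norm(Aa @ x - b))
    if resid > 1e-6 * moment_scale:
        # one more attempt from the LP vertex with a tighter run
        res2 = optimize.minimize(
            fun, _polish_equality(Aa, b, x0, 0.0, xm), jac=grad,
            method="SLSQP", bounds=[(0.0, float(h)) for h in xm],
            constraints=[{"type": "eq", "fun": lambda x: Aa @ x - b,
                          "jac": lambda x: Aa}],
            options={"ftol": 1e-16, "maxiter": 1000})
        x2 = _polish_equality(Aa, b, np.clip(res2.x, 0.0, xm), 0.0, xm)
        if np.linalg.norm(Aa @ x2 - b) < resid:
            x, resid = x2, float(np.linalg.norm(Aa @ x2 - b))

    activ = np.zeros(n)
    activ[active] = x
    forces = activ * N
    status = "optimal" if resid <= 1e-6 * moment_scale else "infeasible"
    return RecruitmentSolution(forces, activ, float(np.sum(activ ** p)),
                               status, resid)
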