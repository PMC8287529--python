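"""Force-dependent kinematics (FDK) for the glenohumeral translations.

At each driven abduction angle the three GH translations are not
prescribed kinematically but found from quasi-static force equilibrium:
the solver searches for the translation vector ``u`` at which the net
residual force on the humerus

    R(u) = sum_i f_i(u) * uhat_i(u)   (muscles, from recruitment)
         + m g                        (arm weight)
         + F_contact(u)               (implant contact on the head)
         + F_spring(u)                (capsule spring)
         + F_ext                      (optional test perturbation)

drops below the force tolerance (20 N by default).  Muscle recruitment
is re-solved inside every residual evaluation, mirroring the FDK
decomposition: moments are balanced by the muscles, translations by the
released degrees of freedom.

The root search is a damped Newton iteration with a forward
finite-difference Jacobian and an Armijo-style backtracking line search
on the residual norm; after repeated stagnation it falls back to a
derivative-free Nelder–Mead polish.  The contact force is only
piecewise-smooth in ``u`` (mesh quadrature), so the damping is what
keeps the iteration from chattering.  Internally the solver aims for a
residual well below the convergence tolerance (5% of it) so that the
converged state is insensitive to the iteration path; convergence is
reported against the stated tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .contact import ContactResult, contact_force, translation_pose
from .core import GHState, ShoulderModel, abduction_rotation, spring_force
from .recruitment import (EquilibriumSystem, RecruitmentSolution,
                          muscle_geometry, solve_recruitment)

__all__ = ["FDKSettings", "FDKResult", "RecruitmentInfeasible",
           "fdk_residual", "fdk_solve_step"]

#: fraction of the tolerance the iteration actually aims for
_TARGET_FRACTION = 0.05
#: hard cap on a single Newton step, m
_MAX_STEP = 2e-3


class RecruitmentInfeasible(RuntimeError):
    """No bounded muscle-force vector balances the moment at this state."""

    def __init__(self, state: GHState, solution: RecruitmentSolution):
        super().__init__(
            f"recruitment infeasible at angle "
            f"{state.abduction_angle:.1f}°, u = {state.translation}")
        self.state = state
        self.solution = solution


@dataclass
class FDKSettings:
    """Solver controls; the 20 N default is the model's residual-force
    convergence tolerance."""

    tolerance: float = 20.0        # N
    max_iterations: int = 50
    fd_step: float = 1e-5          # m, forward-difference step
    warm_start: bool = True

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")


@dataclass
class FDKResult:
    """Converged (or best-found) state of one FDK step."""

    state: GHState
    residual_norm: float           # N
    iterations: int
    recruitment: RecruitmentSolution | None
    contact: ContactResult | None
    converged: bool


def _evaluate(model: ShoulderModel, state: GHState):
    """Residual force and its ingredients at one state.

    Pure function of (model, state); raises
    :class:`RecruitmentInfeasible` when the moment balance has no
    bounded solution.
    """
    u = state.translation
    total = np.zeros(3)
    contact = None
    contact_on_head = np.zeros(3)
    contact_moment_on_head = np.zeros(3)

    if model.head_mesh is not None and model.insert_mesh is not None:
        # insert fixed (slave); head translated by u (master)
        contact = contact_force(model.insert_mesh, model.head_mesh,
                                pose=translation_pose(u),
                                params=model.contact, gh_center=u)
        contact_on_head = contact.force_on_master
        contact_moment_on_head = -contact.resultant_moment

    gravity_force = np.zeros(3)
    gravity_moment = np.zeros(3)
    if model.arm is not None:
        angle = state.abduction_angle * model.rhythm_fraction
        com = abduction_rotation(angle) @ model.arm.com  # about head center
        gravity_force = model.arm.mass * model.gravity
        gravity_moment = np.cross(com, gravity_force)

    recruitment = None
    muscle_force = np.zeros(3)
    if model.muscles:
        from .recruitment import moment_arms
        R = moment_arms(model, state)
        m_ext = gravity_moment + contact_moment_on_head
        system = EquilibriumSystem(
            R, m_ext,
            strengths=np.array([m.strength for m in model.muscles]),
            bounds=np.array([m.bound for m in model.muscles]))
        recruitment = solve_recruitment(system, model.criterion_order)
        if not recruitment.optimal:
            raise RecruitmentInfeasible(state, recruitment)
        _, dirs = muscle_geometry(model, state)
        muscle_force = (recruitment.forces[:, None] * dirs).sum(axis=0)

    total = (muscle_force + gravity_force + contact_on_head
             + spring_force(u, model.spring) + model.external_force)
    return total, recruitment, contact


def fdk_residual(model: ShoulderModel, state: GHState) -> np.ndarray:
    """Net residual force (N) on the humerus at a given state."""
    residual, _, _ = _evaluate(model, state)
    return residual


def fdk_solve_step(model: ShoulderModel, angle: float, u0=None,
                   settings: FDKSettings | None = None) -> FDKResult:
    """Solve one FDK step: find u with ||residual(u)|| below tolerance.

    Deterministic given (model, angle, u0, settings).  On iteration
    exhaustion the best-found state is returned with
    ``converged=False``; recruitment infeasibility at the initial state
    propagates as :class:`RecruitmentInfeasible`.
    """
    settings = FDKSettings() if settings is None else settings
    if not 0.0 <= angle <= 90.0:
        raise ValueError("abduction angle must lie in [0, 90] degrees")
    u = np.zeros(3) if u0 is None else np.asarray(u0, float).copy()
    target = _TARGET_FRACTION * settings.tolerance

    def res_norm(uv):
        try:
            r, rec, con = _evaluate(model, GHState(angle, uv))
        except RecruitmentInfeasible:
            return np.inf, None, None, None
        return float(np.linalg.norm(r)), r, rec, con

    norm, r, rec, con = res_norm(u)
    if norm == np.inf:
        raise RecruitmentInfeasible(GHState(angle, u), None)
    best = (norm, u.copy(), rec, con)
    iterations = 0
    stagnant = 0

    for iterations in range(1, settings.max_iterations + 1):
        if norm <= target:
            break
        # forward-difference Jacobian
        J = np.empty((3, 3))
        h = settings.fd_step
        for k in range(3):
            up = u.copy()
            up[k] += h
            nk, rk, _, _ = res_norm(up)
            if rk is None:
                up[k] -= 2 * h
                nk, rk, _, _ = res_norm(up)
                if rk is None:
                    rk = r
                J[:, k] = (r - rk) / h
            else:
                J[:, k] = (rk - r) / h
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        slen = np.linalg.norm(step)
        if slen > _MAX_STEP:
            step *= _MAX_STEP / slen

        improved = False
        alpha = 1.0
        for _ in range(10):
            cand = u + alpha * step
            ncand, rcand, reccand, concand = res_norm(cand)
            if ncand < norm * (1.0 - 1e-4 * alpha):
                u, norm, r, rec, con = cand, ncand, rcand, reccand, concand
                if ncand < best[0]:
                    best = (ncand, cand.copy(), reccand, concand)
                improved = True
                break
            alpha *= 0.5
        if not improved:
            stagnant += 1
            if stagnant >= 3:
                # derivative-free fallback on the residual norm
                nm = optimize.minimize(
                    lambda x: res_norm(x)[0], best[1], method="Nelder-Mead",
                    options={"xatol": 1e-8, "fatol": target * 0.1,
                             "maxiter": 200})
                nnm, rnm, recnm, connm = res_norm(nm.x)
                if nnm < best[0]:
                    best = (nnm, np.asarray(nm.x).copy(), recnm, connm)
                u = best[1].copy()
                norm, r, rec, con = res_norm(u)
                stagnant = 0
            if best[0] <= settings.tolerance:
                break
        else:
            stagnant = 0

    norm, u_best, rec, con = best
    return FDKResult(state=GHState(angle, u_best), residual_norm=norm,
                     iterations=iterations, recruitment=rec, contact=con,
                     converged=bool(norm <= settings.tolerance))
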