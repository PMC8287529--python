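"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pytest

import atsasim


@pytest.fixture(scope="session")
def default_model():
    return atsasim.assemble_model()


@pytest.fixture(scope="session")
def toys():
    return atsasim.toy_models()


# ---------------------------------------------------------------------------
# brute-force recruitment oracle
# ---------------------------------------------------------------------------

def _kkt_active_set_enumeration(R, b, N, ub):
    """Exact quadratic-criterion optimum by active-set enumeration.

    For p = 2 the problem is a convex QP; its optimum has each force
    either free, at 0, or at its bound.  Enumerating all 3^n
    assignments (n <= 3 here) and solving the equality-constrained
    stationarity system in closed form for the free block recovers the
    exact optimum among the primal-feasible candidates.
    """
    m, n = R.shape
    tol = 1e-9 * max(1.0, np.abs(ub).max(), np.linalg.norm(b))
    best = np.inf
    for assign in itertools.product((0, 1, 2), repeat=n):
        f = np.zeros(n)
        fixed = [i for i, a in enumerate(assign) if a != 0]
        freev = [i for i, a in enumerate(assign) if a == 0]
        for i in fixed:
            f[i] = 0.0 if assign[i] == 1 else ub[i]
        rhs = b - R[:, fixed] @ f[fixed] if fixed else b.copy()
        if freev:
            Rf = R[:, freev]
            D2 = np.diag(N[freev] ** 2)
            G = Rf @ D2 @ Rf.T
            lam, *_ = np.linalg.lstsq(G, rhs, rcond=None)
            ff = D2 @ Rf.T @ lam
            if np.linalg.norm(Rf @ ff - rhs) > tol:
                continue
            f[freev] = ff
        elif np.linalg.norm(rhs) > tol:
            continue
        if np.any(f < -tol) or np.any(f > ub + tol):
            continue
        best = min(best, float(np.sum((np.clip(f, 0, ub) / N) ** 2)))
    return best


def brute_force_recruitment(R, M_ext, strengths, bounds=None, p=2,
                            grid=15, iters=14, shrink=2.0):
    """Independent minimizer of the polynomial criterion.

    Two independent stages, neither sharing code with the production
    solver: a refining grid search over the constraint manifold (any
    order p), and for p = 2 an exact closed-form active-set enumeration
    (see :func:`_kkt_active_set_enumeration`); the better of the two is
    returned.  ``np.inf`` signals that no feasible point was found.
    Intended for n <= 3 muscles and 1-2 constraints.
    """
    R = np.atleast_2d(np.asarray(R, float))
    b = -np.atleast_1d(np.asarray(M_ext, float))
    N = np.atleast_1d(np.asarray(strengths, float))
    ub = N.copy() if bounds is None else np.atleast_1d(np.asarray(bounds,
                                                                  float))
    m, n = R.shape

    def objective(f):
        return float(np.sum((f / N) ** p))

    if n == m:
        try:
            f = np.linalg.solve(R, b)
        except np.linalg.LinAlgError:
            return np.inf
        tol = 1e-9 * max(1.0, np.abs(ub).max())
        if np.all(f >= -tol) and np.all(f <= ub + tol):
            return objective(np.clip(f, 0.0, ub))
        return np.inf

    # pick the best-conditioned dependent column subset
    best_det, dep = 0.0, None
    for combo in itertools.combinations(range(n), m):
        det = abs(np.linalg.det(R[:, combo]))
        if det > best_det:
            best_det, dep = det, combo
    if dep is None or best_det < 1e-14:
        return np.inf
    free = [i for i in range(n) if i not in dep]
    Rd, Rf = R[:, dep], R[:, free]
    ubd, ubf = ub[list(dep)], ub[free]

    Rd_inv = np.linalg.inv(Rd)
    Nf, Nd = N[free], N[list(dep)]
    tol = 1e-9 * max(1.0, np.abs(ub).max())

    lo = np.zeros(len(free))
    hi = ubf.copy()
    best_obj, best_ff = np.inf, None
    for _ in range(iters):
        axes = [np.linspace(lo[k], hi[k], grid) for k in range(len(free))]
        pts = np.stack([a.ravel() for a in np.meshgrid(*axes,
                                                       indexing="ij")],
                       axis=1)                       # (G, n_free)
        fd = (b[None, :] - pts @ Rf.T) @ Rd_inv.T    # (G, m)
        feas = np.all(fd >= -tol, axis=1) & np.all(fd <= ubd + tol, axis=1)
        if feas.any():
            fdc = np.clip(fd[feas], 0.0, ubd)
            obj = (np.sum((pts[feas] / Nf) ** p, axis=1)
                   + np.sum((fdc / Nd) ** p, axis=1))
            k = int(np.argmin(obj))
            if obj[k] < best_obj:
                best_obj, best_ff = float(obj[k]), pts[feas][k]
        if best_ff is None:
            break
        span = (hi - lo) / shrink
        lo = np.maximum(0.0, best_ff - span / 2)
        hi = np.minimum(ubf, best_ff + span / 2)

    if p == 2:
        best_obj = min(best_obj, _kkt_active_set_enumeration(R, b, N, ub))
    return best_obj


@pytest.fixture(scope="session")
def recruitment_oracle():
    return brute_force_recruitment


def random_recruitment_instance(rng):
    """Feasible-by-construction random instance with <=3 muscles."""
    n = int(rng.integers(1, 4))
    m = int(rng.integers(1, min(n, 2) + 1))
    R = rng.uniform(-0.03, 0.03, size=(m, n))
    N = rng.uniform(100.0, 1000.0, size=n)
    f_star = rng.uniform(0.0, 0.8) * rng.uniform(0.0, 1.0, size=n) * N
    M_ext = -(R @ f_star)
    return atsasim.EquilibriumSystem(R, M_ext, N)


@pytest.fixture(scope="session")
def random_instance_factory():
    return random_recruitment_instance
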