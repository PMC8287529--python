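"""Elastic-foundation penalty contact between implant meshes.

The polyethylene insert is treated as a bed of independent springs
(elastic foundation): each slave vertex that penetrates the master
surface contributes a force

    F_i = P_V * V_i,        V_i = d_i * A_i,

where ``d_i`` is the penetration depth, ``A_i`` the vertex tributary
area and ``P_V`` the contact pressure module (N/m³).  The pressure
module itself can be derived from the foundation theory for a
nonlinear polyethylene layer,

    P_V = (1 - v) / ((1 + v)(1 - 2v)) * (1/h) * (2 p_o / eps_o)
          * [1 + n (p_i / p_o)^(n-1)],

with Poisson's ratio ``v``, layer thickness ``h``, material constants
``eps_o``, ``p_o``, ``n`` and a reference contact pressure ``p_i``.
The shipped default bypasses this formula and uses the constant
2.74e11 N/m³ directly, so sweep results never depend on the reading of
the derivation; the formula is exposed for sensitivity studies.
Contact is normal-only: no friction, no tangential stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import Sphere, TriMesh

__all__ = ["ContactParams", "ContactResult", "vertex_penetration",
           "contact_force", "pressure_module", "identity_pose",
           "translation_pose"]


def identity_pose() -> np.ndarray:
    return np.eye(4)


def translation_pose(t) -> np.ndarray:
    T = np.eye(4)
    T[:3, 3] = np.asarray(t, float)
    return T


def _check_rigid(pose: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pose = np.asarray(pose, float)
    if pose.shape != (4, 4):
        raise ValueError("pose must be a 4x4 homogeneous transform")
    R, t = pose[:3, :3], pose[:3, 3]
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or \
            not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
        raise ValueError("pose must be a rigid transform (orthonormal, det +1)")
    return R, t


@dataclass
class ContactParams:
    """Material and geometric constants of the foundation model (SI)."""

    pressure_module: float = 2.74e11   # P_V, N/m³
    eps_o: float = 0.0597              # dimensionless
    p_o: float = 18.4e6                # Pa
    n: float = 3.0
    poisson: float = 0.46
    thickness: float = 6e-3            # insert layer thickness h, m

    def __post_init__(self):
        if self.pressure_module <= 0:
            raise ValueError("pressure module must be positive")
        if not 0.0 < self.poisson < 0.5:
            raise ValueError("Poisson's ratio must lie in (0, 0.5)")
        if self.thickness <= 0:
            raise ValueError("insert thickness must be positive")


@dataclass
class ContactResult:
    """Per-vertex and resultant contact quantities for one pose.

    ``resultant_force`` is the force exerted on the slave mesh (each
    vertex force acts along the slave's inward normal); the equal and
    opposite force acts on the master.
    """

    depth: np.ndarray = field(repr=False)      # d_i, m
    volume: np.ndarray = field(repr=False)     # V_i, m³
    force: np.ndarray = field(repr=False)      # F_i, N (magnitudes)
    resultant_force: np.ndarray = None         # on the slave, N
    resultant_moment: np.ndarray = None        # about gh_center, N·m
    contact_area: float = 0.0                  # m²
    center_of_pressure: np.ndarray | None = None

    @property
    def total_load(self) -> float:
        """Sum of vertex force magnitudes (total normal load), N."""
        return float(self.force.sum())

    @property
    def force_on_master(self) -> np.ndarray:
        return -self.resultant_force

    @property
    def in_contact(self) -> bool:
        return bool(np.any(self.depth > 0.0))


def vertex_penetration(slave: TriMesh, master: TriMesh,
                       pose=None) -> np.ndarray:
    """Penetration depth of each slave vertex into the master material.

    ``pose`` is a rigid 4x4 transform applied to the master (the slave
    stays in its stored placement).  Depths are nonnegative; vertices
    outside the master material get exactly zero.  When the master
    carries an analytic sphere the depth is the exact signed distance to
    that sphere; otherwise the master mesh is queried by nearest-point
    projection with the sign taken from its outward normals.
    """
    pose = identity_pose() if pose is None else pose
    R, t = _check_rigid(pose)
    p = slave.vertices

    if master.analytic is not None:
        s = master.analytic
        c = R @ s.center_arr + t
        r = np.linalg.norm(p - c, axis=1)
        if not s.concave:
            d = s.radius - r
        else:
            d = r - s.radius
            # material exists only inside the cap cone
            axis = R @ s.axis_arr
            cosang = (p - c) @ axis / np.maximum(r, 1e-30)
            d[cosang < np.cos(np.radians(s.cap_angle_deg))] = 0.0
        return np.maximum(d, 0.0)

    # generic mesh master: nearest-point projection (naive variant: no
    # spatial index dependency; this path is a fallback for imported
    # geometry, not the hot loop)
    from trimesh.proximity import closest_point_naive
    tm = master.to_trimesh()
    tm.apply_transform(pose)
    closest, dist, tri_id = closest_point_naive(tm, p)
    normals = tm.face_normals[tri_id]
    inside = np.einsum("ij,ij->i", p - closest, normals) < 0.0
    d = np.where(inside, dist, 0.0)
    return np.maximum(d, 0.0)


def contact_force(slave: TriMesh, master: TriMesh, pose=None,
                  params: ContactParams | None = None,
                  gh_center=(0.0, 0.0, 0.0)) -> ContactResult:
    """Evaluate the foundation contact law over the slave mesh.

    Per-vertex: ``V_i = d_i A_i`` and ``F_i = P_V V_i`` along the slave
    inward normal.  Resultants are exact sums; the moment is taken about
    ``gh_center``.  No contact yields an all-zero result.
    """
    params = ContactParams() if params is None else params
    gh_center = np.asarray(gh_center, float)
    d = vertex_penetration(slave, master, pose)
    V = d * slave.vertex_areas
    F = params.pressure_module * V
    dirs = -slave.vertex_normals              # inward
    fvec = F[:, None] * dirs
    resultant = fvec.sum(axis=0)
    moment = np.cross(slave.vertices - gh_center, fvec).sum(axis=0)
    area = float(slave.vertex_areas[d > 0.0].sum())
    total = F.sum()
    cop = (F[:, None] * slave.vertices).sum(axis=0) / total if total > 0 else None
    return ContactResult(depth=d, volume=V, force=F,
                         resultant_force=resultant, resultant_moment=moment,
                         contact_area=area, center_of_pressure=cop)


def pressure_module(params: ContactParams, reference_pressure: float) -> float:
    """Foundation-theory contact pressure module, N/m³.

    ``reference_pressure`` is the contact pressure ``p_i`` (Pa) at which
    the nonlinear bracket is evaluated.  Pure function of its arguments;
    the model default does *not* call this — it ships the constant
    2.74e11 N/m³ (see module docstring).
    """
    v, h = params.poisson, params.thickness
    if not 0.0 < v < 0.5:
        raise ValueError("Poisson's ratio must lie in (0, 0.5); v = 0.5 "
                         "is the incompressible singularity")
    if h <= 0:
        raise ValueError("layer thickness must be positive")
    if reference_pressure <= 0:
        raise ValueError("reference pressure must be positive")
    p_i, p_o, eps_o, n = reference_pressure, params.p_o, params.eps_o, params.n
    elastic = (1.0 - v) / ((1.0 + v) * (1.0 - 2.0 * v))
    bracket = 1.0 + n * (p_i / p_o) ** (n - 1.0)
    return elastic / h * (2.0 * p_o / eps_o) * bracket
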