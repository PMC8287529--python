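"""Triangle-mesh container with per-vertex quadrature data.

The elastic-foundation contact model integrates pressure over mesh
vertices, so every mesh carries per-vertex tributary areas (one third of
the incident triangle areas) and outward unit normals.  Meshes generated
from spherical primitives keep a reference to the analytic sphere so that
penetration depths can be evaluated exactly instead of by nearest-point
projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

__all__ = ["Sphere", "TriMesh", "icosphere_cap", "subdivisions_for_triangles"]


@dataclass(frozen=True)
class Sphere:
    """Analytic sphere backing a generated mesh.

    ``concave=True`` means the mesh is the inner surface of a spherical
    cavity (material lies outside the sphere), in which case the outward
    surface normal points toward the center.  ``cap_axis``/``cap_angle_deg``
    record the angular extent of the cap for concave surfaces, where the
    material only exists inside the cap cone.
    """

    center: tuple[float, float, float]
    radius: float
    concave: bool = False
    cap_axis: tuple[float, float, float] = (0.0, 0.0, -1.0)
    cap_angle_deg: float = 180.0

    @property
    def center_arr(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    @property
    def axis_arr(self) -> np.ndarray:
        a = np.asarray(self.cap_axis, dtype=float)
        return a / np.linalg.norm(a)


@dataclass
class TriMesh:
    """Triangulated surface in meters with vertex quadrature data.

    Invariants (enforced at construction): unit vertex normals to 1e-9,
    vertex areas summing exactly to the polyhedral surface area, faces
    wound consistently with the stored normals.
    """

    vertices: np.ndarray          # (V, 3) float64, m
    faces: np.ndarray             # (F, 3) int
    vertex_areas: np.ndarray = field(repr=False, default=None)
    vertex_normals: np.ndarray = field(repr=False, default=None)
    analytic: Sphere | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.vertex_areas is None or self.vertex_normals is None:
            self._compute_quadrature()
        norms = np.linalg.norm(self.vertex_normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("vertex normals must be unit length")

    def _compute_quadrature(self) -> None:
        v, f = self.vertices, self.faces
        e1 = v[f[:, 1]] - v[f[:, 0]]
        e2 = v[f[:, 2]] - v[f[:, 0]]
        cross = np.cross(e1, e2)
        face_area2 = np.linalg.norm(cross, axis=1)  # 2 * area
        areas = np.zeros(len(v))
        # one third of each incident triangle area
        for k in range(3):
            np.add.at(areas, f[:, k], face_area2 / 6.0)
        self.vertex_areas = areas
        if self.analytic is not None:
            s = self.analytic
            radial = v - s.center_arr
            radial /= np.linalg.norm(radial, axis=1, keepdims=True)
            self.vertex_normals = -radial if s.concave else radial
        else:
            normals = np.zeros_like(v)
            for k in range(3):
                np.add.at(normals, f[:, k], cross)
            lens = np.linalg.norm(normals, axis=1, keepdims=True)
            lens[lens == 0.0] = 1.0
            self.vertex_normals = normals / lens

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def total_area(self) -> float:
        """Polyhedral surface area, equal to the sum of vertex areas."""
        return float(self.vertex_areas.sum())

    # -- interchange --------------------------------------------------------

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                                process=False)

    def export_stl(self, path) -> None:
        """Write the mesh as STL (binary or ASCII chosen by trimesh)."""
        self.to_trimesh().export(path)

    @classmethod
    def from_stl(cls, path, analytic: Sphere | None = None) -> "TriMesh":
        m = _trimesh.load(path, force="mesh", process=False)
        return cls(np.asarray(m.vertices), np.asarray(m.faces),
                   analytic=analytic)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(),
                       self.vertex_areas.copy(), self.vertex_normals.copy(),
                       self.analytic)


def subdivisions_for_triangles(target: int, cap_fraction: float) -> int:
    """Icosphere subdivision level whose cap keeps >= ``target`` triangles.

    A level-``s`` icosphere has ``20 * 4**s`` faces; a cap covering a
    fraction ``cap_fraction`` of the sphere keeps roughly that share.
    """
    if target < 1:
        raise ValueError("target triangle count must be positive")
    s = 0
    while 20 * 4 ** s * cap_fraction < target and s < 8:
        s += 1
    return s


def _orthonormal_to(axis: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(axis @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e = trial - (trial @ axis) * axis
    return e / np.linalg.norm(e)


def icosphere_cap(radius: float, cap_angle_deg: float,
                  center=(0.0, 0.0, 0.0), pole=(0.0, 0.0, -1.0),
                  subdivisions: int = 4, concave: bool = False) -> TriMesh:
    """Spherical cap sampled from a subdivided icosahedron.

    The cap spans polar angles ``[0, cap_angle_deg]`` about ``pole``.
    Vertices of boundary-crossing faces are clamped onto the rim circle
    (polar angle fixed, azimuth kept) so the rim is clean and the mesh
    area matches the analytic cap area to second order in edge length.
    Generation is deterministic for a given argument set.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 < cap_angle_deg <= 180:
        raise ValueError("cap_angle_deg must lie in (0, 180]")
    pole = np.asarray(pole, dtype=float)
    pole = pole / np.linalg.norm(pole)
    center = np.asarray(center, dtype=float)
    theta = np.radians(cap_angle_deg)

    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(ico.vertices, dtype=float)
    f = np.asarray(ico.faces, dtype=np.int64)

    cosphi = np.clip(v @ pole, -1.0, 1.0)
    phi = np.arccos(cosphi)
    inside = phi <= theta + 1e-12
    keep = inside[f].any(axis=1)
    f = f[keep]

    used = np.unique(f)
    remap = -np.ones(len(v), dtype=np.int64)
    remap[used] = np.arange(len(used))
    v = v[used].copy()
    phi_u = phi[used]
    f = remap[f]

    # clamp exterior vertices onto the rim, preserving azimuth
    out = phi_u > theta
    if out.any():
        vo = v[out]
        tang = vo - np.cos(phi_u[out])[:, None] * pole
        tlen = np.linalg.norm(tang, axis=1, keepdims=True)
        # vertex at the antipode has no azimuth; pick an arbitrary one
        bad = tlen[:, 0] < 1e-14
        if bad.any():
            tang[bad] = _orthonormal_to(pole)
            tlen[bad] = 1.0
        v[out] = np.cos(theta) * pole + np.sin(theta) * (tang / tlen)

    # drop faces that collapsed to zero area on the rim
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    area2 = np.linalg.norm(np.cross(e1, e2), axis=1)
    f = f[area2 > 1e-14]

    if len(f) < 1:
        raise ValueError("cap resolution too low: no faces generated")

    v = center + radius * v
    if concave:
        f = f[:, ::-1]  # wind toward the center
    sphere = Sphere(tuple(center), float(radius), concave=concave,
                    cap_axis=tuple(pole), cap_angle_deg=float(cap_angle_deg))
    return TriMesh(v, f, analytic=sphere)
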