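"""Synthetic model stage: implant meshes, muscle fixtures, toy models.

Everything downstream is testable without any external download: this
module procedurally generates the articular surfaces of the implant, a
muscle attachment table with anatomically plausible moment arms, and a
set of degenerate toy models with closed-form equilibria used to
exercise the solvers.

The implant emulates a 48 mm humeral head articulating against a
polyethylene insert with an 8 mm mismatch.  The mismatch is read as a
*diametral* mismatch of curvature (standard usage for this implant
family), so the insert articular radius is (48 + 8)/2 = 28 mm; the
convention is isolated in :class:`ImplantSpec`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (GRAVITY, BodySegment, Frame, MuscleUnit, ShoulderModel,
                   SpringRestraint, ValidationError, muscle_strength,
                   REQUIRED_MUSCLES)
from .contact import ContactParams
from .mesh import TriMesh, icosphere_cap, subdivisions_for_triangles

__all__ = ["ImplantSpec", "build_implant_meshes", "default_muscle_fixture",
           "muscles_from_table", "toy_models"]

_MIN_TRIANGLES = 100


@dataclass
class ImplantSpec:
    """Geometry of the prosthetic articulation (lengths in mm).

    ``mismatch`` is diametral: insert articular radius =
    ``(head_diameter + mismatch) / 2``.  ``coverage_angle`` is the polar
    half-angle of the insert's spherical cap; the head is generated as a
    larger cap (default 120°) so the contact patch stays inside both
    meshes at every sweep angle.
    """

    head_diameter: float = 48.0
    mismatch: float = 8.0
    insert_thickness: float = 6.0
    coverage_angle: float = 60.0
    head_coverage_angle: float = 120.0
    mesh_resolution: int = 5000     # target insert triangle count

    def __post_init__(self):
        if self.head_diameter <= 0:
            raise ValidationError("head diameter must be positive")
        if self.mismatch < 0:
            raise ValidationError("mismatch must be nonnegative")
        if self.insert_thickness <= 0:
            raise ValidationError("insert thickness must be positive")
        if not 0 < self.coverage_angle <= 90:
            raise ValidationError("coverage angle must lie in (0, 90]")

    @property
    def head_radius_m(self) -> float:
        return self.head_diameter / 2.0 * 1e-3

    @property
    def insert_radius_m(self) -> float:
        return (self.head_diameter + self.mismatch) / 2.0 * 1e-3


def build_implant_meshes(spec: ImplantSpec) -> tuple[TriMesh, TriMesh]:
    """Generate (head, insert) articular surface meshes in the GH frame.

    The head is a convex spherical cap centered at the origin with its
    pole pointing medially (-ML); the insert is a concave cap whose
    curvature center sits ``R_insert - R_head`` lateral of the origin so
    the two surfaces are exactly tangent at the pole when the GH
    translation is zero.  Generation is deterministic for a given spec.
    """
    if spec.mesh_resolution < _MIN_TRIANGLES:
        raise ValidationError(
            f"mesh resolution below minimum ({_MIN_TRIANGLES} triangles)")
    r_h, r_i = spec.head_radius_m, spec.insert_radius_m
    pole = (0.0, 0.0, -1.0)

    frac_i = 0.5 * (1.0 - np.cos(np.radians(spec.coverage_angle)))
    sub_i = subdivisions_for_triangles(spec.mesh_resolution, frac_i)
    insert_center = np.array([0.0, 0.0, r_i - r_h])
    insert = icosphere_cap(r_i, spec.coverage_angle, center=insert_center,
                           pole=pole, subdivisions=sub_i, concave=True)

    frac_h = 0.5 * (1.0 - np.cos(np.radians(spec.head_coverage_angle)))
    sub_h = subdivisions_for_triangles(spec.mesh_resolution, frac_h)
    head = icosphere_cap(r_h, spec.head_coverage_angle, center=(0, 0, 0),
                         pole=pole, subdivisions=sub_h, concave=False)
    return head, insert


# ---------------------------------------------------------------------------
# muscle attachment fixture
# ---------------------------------------------------------------------------

# Columns: muscle, point_index, segment, x, y, z (m, GH frame at 0°), pcsa (cm²).
# Coordinates are literature-style landmark positions for a right shoulder
# (x anterior, y superior, z lateral; origin at the GH joint center):
# scapular points (segment=ground, the scapula is fixed) sit medial of the
# joint, humeral insertions on the proximal humerus.  The subscapularis
# anchor is placed at its effective (anterior) line of action where the
# muscle wraps the anterior capsule, not at the fossa centroid, since the
# paths are straight lines.  PCSAs follow the usual
# ordering (deltoid largest, subscapularis the largest cuff muscle,
# teres minor smallest).  The resulting signed moment arms are checked by
# the test suite: deltoid and supraspinatus abduct, subscapularis rotates
# internally while infraspinatus/teres minor rotate externally, pectoralis
# major and latissimus dorsi adduct (antagonists).
_FIXTURE_CSV = """muscle,point_index,segment,x,y,z,pcsa,group
deltoideus_clavicular,0,ground,0.025,0.025,0.000,8.0,deltoid
deltoideus_clavicular,1,humerus,0.008,-0.105,0.012,8.0,deltoid
deltoideus_scapular,0,ground,-0.005,0.030,0.015,14.0,deltoid
deltoideus_scapular,1,humerus,0.000,-0.110,0.018,14.0,deltoid
supraspinatus,0,ground,0.000,0.015,-0.060,6.0,rotator_cuff
supraspinatus,1,humerus,0.002,0.015,0.020,6.0,rotator_cuff
infraspinatus,0,ground,-0.015,-0.005,-0.065,10.0,rotator_cuff
infraspinatus,1,humerus,-0.015,0.008,0.018,10.0,rotator_cuff
subscapularis,0,ground,0.030,-0.005,-0.045,16.0,rotator_cuff
subscapularis,1,humerus,0.016,0.005,0.012,16.0,rotator_cuff
teres_minor,0,ground,-0.012,-0.035,-0.055,3.0,rotator_cuff
teres_minor,1,humerus,-0.014,-0.005,0.016,3.0,rotator_cuff
pectoralis_major,0,ground,0.030,-0.020,-0.050,13.0,other
pectoralis_major,1,humerus,0.012,-0.040,0.008,13.0,other
latissimus_dorsi,0,ground,-0.025,-0.060,-0.055,12.0,other
latissimus_dorsi,1,humerus,0.010,-0.030,0.004,12.0,other
"""


def default_muscle_fixture() -> pd.DataFrame:
    """Muscle attachment table for the reduced shoulder model.

    Returns the six required muscles (two deltoid parts and the four
    rotator cuff muscles) plus two adductor antagonists (pectoralis
    major, latissimus dorsi) needed to close the moment balance when the
    whole cuff is lost.  See the CSV block in the source for the column
    schema and landmark rationale.
    """
    return pd.read_csv(io.StringIO(_FIXTURE_CSV))


def muscles_from_table(table: pd.DataFrame) -> list:
    """Convert an attachment table into validated :class:`MuscleUnit`s."""
    required = {"muscle", "point_index", "segment", "x", "y", "z", "pcsa"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"muscle table missing columns: {sorted(missing)}")
    units = []
    for name, grp in table.groupby("muscle", sort=False):
        grp = grp.sort_values("point_index")
        pcsa = float(grp["pcsa"].iloc[0])
        if pcsa <= 0:
            raise ValidationError(f"muscle {name!r}: pcsa must be > 0")
        path = [(str(row.segment), np.array([row.x, row.y, row.z]))
                for row in grp.itertuples()]
        group = str(grp["group"].iloc[0]) if "group" in grp.columns else (
            "rotator_cuff" if name in REQUIRED_MUSCLES[2:] else "other")
        units.append(MuscleUnit(name=str(name), path=path, pcsa=pcsa,
                                strength=muscle_strength(pcsa), group=group))
    return units


# ---------------------------------------------------------------------------
# toy models
# ---------------------------------------------------------------------------

def toy_models() -> dict:
    """Degenerate models with closed-form equilibria for solver tests.

    * ``spring_only`` — no muscles, no contact, no gravity: under a
      constant external force F the equilibrium translation is F/k.
    * ``single_muscle`` — one abductor 20 mm above the joint center;
      the recruitment constraint has a unique feasible point.
    * ``two_muscle_symmetric`` — two mirror-image abductors of equal
      strength: the quadratic criterion splits the load equally.
    * ``centered_contact`` — implant contact plus spring, zero gravity,
      no muscles: the equilibrium translation is exactly zero.
    """
    spring = SpringRestraint()
    zero_g = np.zeros(3)
    contact = ContactParams()

    spring_only = ShoulderModel(
        gh_frame=Frame(), arm=None, muscles=[], head_mesh=None,
        insert_mesh=None, contact=contact, spring=SpringRestraint(),
        gravity=zero_g)

    def abductor(name, sign):
        # origin above the joint, insertion on the shaft; mirrored in AP
        path = [("ground", np.array([sign * 0.010, 0.030, 0.010])),
                ("humerus", np.array([sign * 0.010, -0.100, 0.015]))]
        return MuscleUnit(name=name, path=path, pcsa=10.0,
                          strength=muscle_strength(10.0), group="other")

    single = ShoulderModel(
        gh_frame=Frame(), arm=BodySegment("arm", 4.0, [0, -0.30, 0]),
        muscles=[abductor("abductor", 0)], head_mesh=None, insert_mesh=None,
        contact=contact, spring=SpringRestraint(), gravity=GRAVITY.copy())

    symmetric = ShoulderModel(
        gh_frame=Frame(), arm=BodySegment("arm", 4.0, [0, -0.30, 0]),
        muscles=[abductor("abductor_ant", +1), abductor("abductor_post", -1)],
        head_mesh=None, insert_mesh=None, contact=contact,
        spring=SpringRestraint(), gravity=GRAVITY.copy())

    spec = ImplantSpec()
    head, insert = build_implant_meshes(spec)
    centered = ShoulderModel(
        gh_frame=Frame(), arm=None, muscles=[], head_mesh=head,
        insert_mesh=insert, contact=contact, spring=SpringRestraint(),
        gravity=zero_g)

    return {"spring_only": spring_only, "single_muscle": single,
            "two_muscle_symmetric": symmetric, "centered_contact": centered}
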