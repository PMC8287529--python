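"""Domain types, units, coordinate conventions and model assembly.

Conventions
-----------
All internal quantities are SI (m, kg, N, N·m, s); angles cross the user
interface in degrees and are converted once at the boundary.  The
glenohumeral (GH) frame is a right-handed right-shoulder frame with

* +x = AP, anterior
* +y = SI, superior
* +z = ML, lateral

and origin at the GH joint center.  The scapula (and with it the glenoid
insert) is fixed in the ground frame; abduction elevates the humerus in
the frontal (y-z) plane, taking the humeral long axis from -SI at 0° to
+ML at 90°.  The humeral head center translates by the force-dependent
translation vector ``u``.

Muscle strengths follow the usual specific-tension scaling: maximum
isometric force = PCSA × 27 N/cm².
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .mesh import TriMesh

__all__ = [
    "SPECIFIC_TENSION", "REQUIRED_MUSCLES", "GRAVITY",
    "ValidationError", "Frame", "BodySegment", "MuscleUnit",
    "SpringRestraint", "GHState", "ShoulderModel",
    "muscle_strength", "spring_force",
    "abduction_rotation", "humeral_axis",
    "default_config", "load_config", "assemble_model",
]

#: specific muscle tension, N per cm² of physiological cross-section
SPECIFIC_TENSION = 27.0

#: muscles every assembled shoulder model must contain
REQUIRED_MUSCLES = (
    "deltoideus_clavicular",
    "deltoideus_scapular",
    "supraspinatus",
    "infraspinatus",
    "subscapularis",
    "teres_minor",
)

GRAVITY = np.array([0.0, -9.81, 0.0])

_GROUPS = {"deltoid", "rotator_cuff", "other"}
_ROTATOR_CUFF = {"supraspinatus", "infraspinatus", "subscapularis",
                 "teres_minor"}


class ValidationError(ValueError):
    """A model or configuration violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Frame:
    """Right-handed orthonormal reference frame (axes as rows: AP, SI, ML)."""

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "axes", np.asarray(self.axes, float))
        A = self.axes
        if not np.allclose(A @ A.T, np.eye(3), atol=1e-12):
            raise ValidationError("frame axes must be orthonormal to 1e-12")
        if not np.isclose(np.linalg.det(A), 1.0, atol=1e-12):
            raise ValidationError("frame must be right-handed (det +1)")


@dataclass
class BodySegment:
    """Lumped rigid segment: the arm hanging from the GH joint."""

    name: str
    mass: float                      # kg
    com: np.ndarray                  # m, in the segment's local frame

    def __post_init__(self):
        self.com = np.asarray(self.com, float)
        if self.mass <= 0:
            raise ValidationError(f"segment {self.name!r}: mass must be > 0")


@dataclass
class MuscleUnit:
    """Ideal bounded force actuator routed along a straight polyline.

    Path points are (segment, xyz) pairs; points on the ``humerus``
    segment move with the abduction angle and the GH translation, points
    on ``ground`` (scapula/thorax) are fixed.
    """

    name: str
    path: list            # [(segment: str, point: (3,) m), ...]
    pcsa: float           # cm²
    strength: float       # N, = SPECIFIC_TENSION * pcsa
    deficient: bool = False
    group: str = "other"

    def __post_init__(self):
        self.path = [(seg, np.asarray(p, float)) for seg, p in self.path]
        if len(self.path) < 2:
            raise ValidationError(
                f"muscle {self.name!r}: path needs at least 2 points")
        if self.pcsa <= 0:
            raise ValidationError(f"muscle {self.name!r}: pcsa must be > 0")
        if not np.isclose(self.strength, SPECIFIC_TENSION * self.pcsa,
                          rtol=1e-12):
            raise ValidationError(
                f"muscle {self.name!r}: strength must equal "
                f"{SPECIFIC_TENSION} N/cm² × pcsa")
        if self.group not in _GROUPS:
            raise ValidationError(
                f"muscle {self.name!r}: unknown group {self.group!r}")

    @property
    def bound(self) -> float:
        """Force upper bound in N (zero when the muscle is deficient)."""
        return 0.0 if self.deficient else self.strength


@dataclass
class SpringRestraint:
    """Linear capsule/ligament spring acting at the GH center."""

    stiffness: float = 1.74e4        # N/m
    rest_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rest_point = np.asarray(self.rest_point, float)
        if self.stiffness <= 0:
            raise ValidationError("spring stiffness must be > 0")


@dataclass
class GHState:
    """Driven abduction angle plus the three released GH translations."""

    abduction_angle: float                       # degrees
    translation: np.ndarray = field(
        default_factory=lambda: np.zeros(3))     # (u_AP, u_SI, u_ML), m

    def __post_init__(self):
        self.translation = np.asarray(self.translation, float)


@dataclass
class ShoulderModel:
    """Assembled rigid-body / muscle / contact / spring shoulder model.

    Built through :func:`assemble_model`, which validates all structural
    invariants; direct construction skips validation (used by the toy
    models, which deliberately omit muscles or meshes).
    """

    gh_frame: Frame
    arm: BodySegment | None
    muscles: list
    head_mesh: TriMesh | None
    insert_mesh: TriMesh | None
    contact: "object"                 # ContactParams; kept loose to avoid cycle
    spring: SpringRestraint
    gravity: np.ndarray = field(default_factory=lambda: GRAVITY.copy())
    external_force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    criterion_order: int = 2
    rhythm_fraction: float = 1.0      # glenohumeral share of the driven angle

    def __post_init__(self):
        self.gravity = np.asarray(self.gravity, float)
        self.external_force = np.asarray(self.external_force, float)

    def muscle(self, name: str) -> MuscleUnit:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def muscle_names(self) -> list:
        return [m.name for m in self.muscles]

    def copy(self) -> "ShoulderModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# elementary laws
# ---------------------------------------------------------------------------

def muscle_strength(pcsa: float) -> float:
    """Maximum isometric force (N) from PCSA (cm²) at 27 N/cm²."""
    if pcsa <= 0:
        raise ValidationError("pcsa must be positive")
    return SPECIFIC_TENSION * pcsa


def spring_force(u, spring: SpringRestraint) -> np.ndarray:
    """Linear restoring force of the capsule spring, N.

    ``F = -k (u - rest_point)``; exactly linear and odd about the rest
    point.
    """
    u = np.asarray(u, float)
    return -spring.stiffness * (u - spring.rest_point)


# ---------------------------------------------------------------------------
# humeral kinematics
# ---------------------------------------------------------------------------

def abduction_rotation(angle_deg: float) -> np.ndarray:
    """Rotation of the humerus for a given abduction angle.

    Maps humerus-local coordinates to the ground frame: a rotation about
    the AP axis taking the local -SI long axis toward +ML, so the arm
    hangs at 0° and points laterally at 90°.
    """
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    # rotation about +x by -a
    return np.array([[1.0, 0.0, 0.0],
                     [0.0, c, s],
                     [0.0, -s, c]])


def humeral_axis(angle_deg: float) -> np.ndarray:
    """Unit vector along the humeral shaft (toward the elbow)."""
    return abduction_rotation(angle_deg) @ np.array([0.0, -1.0, 0.0])


# ---------------------------------------------------------------------------
# configuration and assembly
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Default model configuration (all units documented per key).

    Matches the reference implant and material constants: 48 mm head,
    8 mm diametral mismatch, contact pressure module 2.74e11 N/m³,
    capsule spring 1.74e4 N/m, specific tension 27 N/cm², 20 N force
    residual tolerance, 90 s / 0-90° abduction drive.
    """
    return {
        "implant": {
            "head_diameter_mm": 48.0,
            "mismatch_mm": 8.0,
            "insert_thickness_mm": 6.0,
            "coverage_angle_deg": 60.0,
            "head_coverage_angle_deg": 120.0,
            "mesh_resolution": 5000,       # target insert triangles
        },
        "contact": {
            "pressure_module": 2.74e11,    # N/m³
            "eps_o": 0.0597,
            "p_o_mpa": 18.4,
            "n": 3.0,
            "poisson": 0.46,
        },
        "spring": {
            "stiffness": 1.74e4,           # N/m
            "rest_point": [0.0, 0.0, 0.0],
        },
        "arm": {
            "mass_kg": 4.0,
            "com_offset_m": 0.30,          # along the humeral shaft
        },
        "gravity": [0.0, -9.81, 0.0],
        "muscles": None,                   # None -> built-in fixture; or CSV path
        "recruitment": {"criterion_order": 2},
        "rhythm_fraction": 1.0,
        "driver": {"duration_s": 90.0, "n_steps": 91, "coefficients": None},
        "fdk": {"tolerance_n": 20.0, "max_iterations": 50,
                "fd_step_m": 1e-5, "warm_start": True},
    }


def load_config(path) -> dict:
    """Read a YAML configuration file and merge it over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(default_config(), user)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def assemble_model(config: dict | str | Path | None = None) -> ShoulderModel:
    """Build and validate a :class:`ShoulderModel` from a configuration.

    ``config`` may be ``None`` (all defaults), a mapping following the
    :func:`default_config` schema, or a path to a YAML file.  Muscle
    strengths are always recomputed from PCSA.
    """
    from .contact import ContactParams
    from .synthetic import (ImplantSpec, build_implant_meshes,
                            default_muscle_fixture, muscles_from_table)

    if config is None:
        cfg = default_config()
    elif isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = _merge(default_config(), dict(config))

    imp = cfg["implant"]
    spec = ImplantSpec(
        head_diameter=float(imp["head_diameter_mm"]),
        mismatch=float(imp["mismatch_mm"]),
        insert_thickness=float(imp["insert_thickness_mm"]),
        coverage_angle=float(imp["coverage_angle_deg"]),
        head_coverage_angle=float(imp["head_coverage_angle_deg"]),
        mesh_resolution=int(imp["mesh_resolution"]),
    )
    head, insert = build_implant_meshes(spec)

    con = cfg["contact"]
    params = ContactParams(
        pressure_module=float(con["pressure_module"]),
        eps_o=float(con["eps_o"]),
        p_o=float(con["p_o_mpa"]) * 1e6,
        n=float(con["n"]),
        poisson=float(con["poisson"]),
        thickness=float(imp["insert_thickness_mm"]) * 1e-3,
    )

    mus_cfg = cfg["muscles"]
    if mus_cfg is None:
        table = default_muscle_fixture()
    elif isinstance(mus_cfg, (str, Path)):
        import pandas as pd
        table = pd.read_csv(mus_cfg)
    else:
        import pandas as pd
        table = pd.DataFrame(mus_cfg)
    muscles = muscles_from_table(table)

    names = [m.name for m in muscles]
    if len(set(names)) != len(names):
        raise ValidationError("muscle names must be unique")
    for req in REQUIRED_MUSCLES:
        if req not in names:
            raise ValidationError(f"required muscle missing: {req}")

    arm_cfg = cfg["arm"]
    arm = BodySegment("arm", float(arm_cfg["mass_kg"]),
                      [0.0, -float(arm_cfg["com_offset_m"]), 0.0])

    spr = cfg["spring"]
    model = ShoulderModel(
        gh_frame=Frame(),
        arm=arm,
        muscles=muscles,
        head_mesh=head,
        insert_mesh=insert,
        contact=params,
        spring=SpringRestraint(float(spr["stiffness"]),
                               np.asarray(spr["rest_point"], float)),
        gravity=np.asarray(cfg["gravity"], float),
        criterion_order=int(cfg["recruitment"]["criterion_order"]),
        rhythm_fraction=float(cfg["rhythm_fraction"]),
    )
    return model
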