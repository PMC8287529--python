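"""Abduction driver: the angle-vs-time profile of the 90 s motion.

The driven arm elevation is a finite Fourier expansion

    Pos(t) = sum_j A_j * cos(w_j * t + B_j)      (degrees, t in s)

over a 90 s motion from 0° to 90°.  The shipped default is the two-term
cosine ramp ``Pos(t) = 45 - 45 cos(pi t / 90)``, written in the Fourier
form with terms (A, B, w) = (45, 0, 0) and (45, pi, pi/90): it starts
and stops smoothly, hits both endpoints exactly, and is user-overridable
through the configuration file.  Any user-supplied coefficient set is
validated at load time against the endpoint and monotonicity invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DriverSpec", "abduction_angle", "time_grid"]

_DEFAULT_COEFFS = ((45.0, 0.0, 0.0), (45.0, np.pi, np.pi / 90.0))


@dataclass
class DriverSpec:
    """Fourier coefficients (A_j degrees, B_j rad, w_j rad/s) and grid."""

    coefficients: tuple = _DEFAULT_COEFFS
    duration: float = 90.0      # s
    n_steps: int = 91

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")
        self.coefficients = tuple(
            (float(a), float(b), float(w)) for a, b, w in self.coefficients)
        start = _evaluate(0.0, self.coefficients)
        end = _evaluate(self.duration, self.coefficients)
        if abs(start) > 1e-9 or abs(end - 90.0) > 1e-9:
            raise ValueError(
                f"driver must run 0° -> 90°; got {start:.3g}° -> {end:.3g}°")
        t = np.linspace(0.0, self.duration, max(10 * self.n_steps, 1000))
        pos = _evaluate(t, self.coefficients)
        if np.any(np.diff(pos) < -1e-9):
            raise ValueError("driver position must be nondecreasing")


def _evaluate(t, coefficients):
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    for a, b, w in coefficients:
        out = out + a * np.cos(w * t + b)
    return out if out.ndim else float(out)


def abduction_angle(t: float, spec: DriverSpec) -> float:
    """Driven abduction angle (degrees) at time ``t`` in [0, duration]."""
    if t < 0.0 or t > spec.duration:
        raise ValueError(f"t = {t} outside [0, {spec.duration}]")
    return float(_evaluate(float(t), spec.coefficients))


def time_grid(spec: DriverSpec) -> np.ndarray:
    """Uniform (t, angle) grid over the motion; shape (n_steps, 2).

    First angle 0°, last 90°, angles nondecreasing along the grid.
    """
    t = np.linspace(0.0, spec.duration, spec.n_steps)
    ang = _evaluate(t, spec.coefficients)
    # pin the endpoints exactly (the spec guarantees them to 1e-9)
    ang[0], ang[-1] = 0.0, 90.0
    return np.column_stack([t, ang])
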