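"""Abduction sweeps, summaries, curve comparison and sensitivity runs.

A sweep drives the abduction angle over the time grid, solves one FDK
step per grid point (warm-starting each step from the previous
converged translation) and records angle, GH translations, per-muscle
forces, contact force components and the force residual in an
:class:`AbductionTrace`.  Summaries report per-muscle force peaks and
contact forces at query angles (78° by default, matching the reporting
convention for cuff-deficiency comparisons), as percent change against
the intact cuff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ShoulderModel, assemble_model, default_config
from .driver import DriverSpec, time_grid
from .fdk import FDKSettings, RecruitmentInfeasible, fdk_solve_step
from .scenarios import ScenarioSpec, apply_scenario, get_scenario

__all__ = ["SweepAborted", "AbductionTrace", "SummaryStats",
           "run_abduction_sweep", "summarize", "percent_change",
           "rmse_curves", "sensitivity_sweep", "driver_from_config",
           "fdk_settings_from_config"]


class SweepAborted(RuntimeError):
    """More than half of the sweep steps failed to converge."""


@dataclass
class AbductionTrace:
    """Per-step sweep record; ``data`` columns are documented in
    :func:`run_abduction_sweep`."""

    scenario: str
    data: pd.DataFrame

    @property
    def muscle_columns(self) -> list:
        return [c for c in self.data.columns if c.startswith("f_")]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path, scenario: str | None = None) -> "AbductionTrace":
        name = scenario or Path(path).stem.replace("trace_", "")
        return cls(name, pd.read_csv(path))


@dataclass
class SummaryStats:
    """Cross-scenario summary tables.

    ``peaks``: per (scenario, muscle) peak force and angle at peak;
    ``contact_peak``: per-scenario peak contact force;
    ``contact_at``: contact force at each query angle;
    percent-change columns are relative to INTACT.
    """

    peaks: pd.DataFrame
    contact_peak: pd.DataFrame
    contact_at: pd.DataFrame
    query_angles: tuple


def driver_from_config(config: dict, n_steps: int | None = None) -> DriverSpec:
    d = config["driver"]
    coeffs = d.get("coefficients")
    kwargs = {"duration": float(d["duration_s"]),
              "n_steps": int(n_steps or d["n_steps"])}
    if coeffs:
        kwargs["coefficients"] = [tuple(c) for c in coeffs]
    return DriverSpec(**kwargs)


def fdk_settings_from_config(config: dict) -> FDKSettings:
    f = config["fdk"]
    return FDKSettings(tolerance=float(f["tolerance_n"]),
                       max_iterations=int(f["max_iterations"]),
                       fd_step=float(f["fd_step_m"]),
                       warm_start=bool(f["warm_start"]))


def run_abduction_sweep(model: ShoulderModel,
                        scenario: ScenarioSpec | str = "INTACT",
                        driver: DriverSpec | None = None,
                        settings: FDKSettings | None = None) -> AbductionTrace:
    """Sweep the abduction drive and record one row per grid step.

    Columns: ``t`` (s), ``angle`` (deg), ``u_ap/u_si/u_ml`` (m),
    ``f_<muscle>`` (N, 0 for deficient muscles), ``c_ap/c_si/c_ml``
    (contact force on the humeral head, N), ``contact_force``
    (magnitude, N), ``residual`` (N), ``converged``, ``iterations``.
    Failed steps keep NaN force entries and ``converged=False``;
    if more than half the steps fail the sweep aborts with a
    diagnostic.  Deterministic end-to-end for a fixed configuration.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    model = apply_scenario(model, scenario)
    driver = DriverSpec() if driver is None else driver
    settings = FDKSettings() if settings is None else settings

    grid = time_grid(driver)
    names = model.muscle_names
    rows = []
    u_prev = np.zeros(3)
    n_failed = 0
    for t, angle in grid:
        u0 = u_prev if settings.warm_start else np.zeros(3)
        row = {"t": t, "angle": angle}
        try:
            res = fdk_solve_step(model, angle, u0=u0, settings=settings)
        except RecruitmentInfeasible:
            res = None
        if res is None or not res.converged:
            n_failed += 1
        if res is None:
            row.update({"u_ap": np.nan, "u_si": np.nan, "u_ml": np.nan})
            row.update({f"f_{n}": np.nan for n in names})
            row.update({"c_ap": np.nan, "c_si": np.nan, "c_ml": np.nan,
                        "contact_force": np.nan, "residual": np.nan,
                        "converged": False, "iterations": 0})
        else:
            u = res.state.translation
            row.update({"u_ap": u[0], "u_si": u[1], "u_ml": u[2]})
            forces = (res.recruitment.forces if res.recruitment is not None
                      else np.zeros(len(names)))
            row.update({f"f_{n}": f for n, f in zip(names, forces)})
            c = (res.contact.force_on_master if res.contact is not None
                 else np.zeros(3))
            row.update({"c_ap": c[0], "c_si": c[1], "c_ml": c[2],
                        "contact_force": float(np.linalg.norm(c)),
                        "residual": res.residual_norm,
                        "converged": res.converged,
                        "iterations": res.iterations})
            if res.converged:
                u_prev = u.copy()
        rows.append(row)
    if n_failed > 0.5 * len(grid):
        raise SweepAborted(
            f"scenario {scenario.id}: {n_failed}/{len(grid)} steps failed")
    return AbductionTrace(scenario.id, pd.DataFrame(rows))


def percent_change(reference: float, value: float) -> float:
    """Percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (value - reference) / reference


def _interp_at(trace: AbductionTrace, column: str, angle: float) -> float:
    df = trace.data[trace.data["converged"].astype(bool)]
    return float(np.interp(angle, df["angle"].to_numpy(),
                           df[column].to_numpy()))


def summarize(traces: dict, query_angles=(78.0,)) -> SummaryStats:
    """Peak and query-angle summaries with percent change vs INTACT.

    ``traces`` maps scenario id to :class:`AbductionTrace`; the INTACT
    trace is required.  Query-angle values use linear interpolation on
    the converged rows of each trace.
    """
    if "INTACT" not in traces:
        raise ValueError("summary requires an INTACT trace")
    query_angles = tuple(float(a) for a in query_angles)

    peak_rows, cpeak_rows, cat_rows = [], [], []
    for sid, tr in traces.items():
        ok = tr.data[tr.data["converged"].astype(bool)]
        for col in tr.muscle_columns:
            i = ok[col].idxmax()
            peak_rows.append({"scenario": sid, "muscle": col[2:],
                              "peak_force": float(ok[col].max()),
                              "angle_at_peak": float(ok.loc[i, "angle"])})
        i = ok["contact_force"].idxmax()
        cpeak_rows.append({"scenario": sid,
                           "peak_contact": float(ok["contact_force"].max()),
                           "angle_at_peak": float(ok.loc[i, "angle"])})
        for qa in query_angles:
            cat_rows.append({"scenario": sid, "angle": qa,
                             "contact_force": _interp_at(tr, "contact_force",
                                                         qa)})

    peaks = pd.DataFrame(peak_rows)
    cpeak = pd.DataFrame(cpeak_rows)
    cat = pd.DataFrame(cat_rows)

    ref = peaks[peaks.scenario == "INTACT"].set_index("muscle")["peak_force"]
    peaks["pct_change"] = peaks.apply(
        lambda r: percent_change(ref[r.muscle], r.peak_force)
        if ref[r.muscle] != 0 else np.nan, axis=1)
    cref = float(cpeak.loc[cpeak.scenario == "INTACT", "peak_contact"].iloc[0])
    cpeak["pct_change"] = [percent_change(cref, v)
                           for v in cpeak["peak_contact"]]
    aref = cat[cat.scenario == "INTACT"].set_index("angle")["contact_force"]
    cat["pct_change"] = cat.apply(
        lambda r: percent_change(float(aref[r.angle]), r.contact_force),
        axis=1)
    return SummaryStats(peaks, cpeak, cat, query_angles)


def rmse_curves(a, b) -> float:
    """Root-mean-square difference of two force-vs-angle curves (N).

    Each curve is an (n, 2) array or DataFrame whose first two columns
    are angle (deg) and force (N).  Curves are linearly resampled onto
    the overlap of their angle ranges before differencing.
    """
    def as_xy(c):
        arr = np.asarray(c.iloc[:, :2] if isinstance(c, pd.DataFrame) else c,
                         float)
        order = np.argsort(arr[:, 0])
        return arr[order, 0], arr[order, 1]

    xa, ya = as_xy(a)
    xb, yb = as_xy(b)
    lo, hi = max(xa[0], xb[0]), min(xa[-1], xb[-1])
    if hi <= lo:
        raise ValueError("curves have no overlapping angle range")
    grid = np.union1d(xa[(xa >= lo) & (xa <= hi)], xb[(xb >= lo) & (xb <= hi)])
    fa = np.interp(grid, xa, ya)
    fb = np.interp(grid, xb, yb)
    return float(np.sqrt(np.mean((fa - fb) ** 2)))


def sensitivity_sweep(base_config: dict | None, grid: dict,
                      n_steps: int = 19) -> pd.DataFrame:
    """One-at-a-time sensitivity of the peak GH contact force.

    ``grid`` maps parameter name in {"pressure_module", "criterion_order",
    "n_steps"} to a list of values.  Each cell reruns a reduced INTACT
    sweep (``n_steps`` grid points by default, trading angle resolution
    for runtime) and reports the percent change of the peak contact
    force against the base run; cells whose sweep aborts are marked
    failed rather than stopping the table.
    """
    allowed = {"pressure_module", "criterion_order", "n_steps"}
    bad = set(grid) - allowed
    if bad:
        raise ValueError(f"unknown sensitivity parameters: {sorted(bad)}")
    cfg = default_config() if base_config is None else base_config

    def run(pressure=None, order=None, steps=None):
        import copy
        c = copy.deepcopy(cfg)
        if pressure is not None:
            c["contact"]["pressure_module"] = float(pressure)
        if order is not None:
            c["recruitment"]["criterion_order"] = int(order)
        model = assemble_model(c)
        driver = driver_from_config(c, n_steps=steps or n_steps)
        trace = run_abduction_sweep(model, "INTACT", driver,
                                    fdk_settings_from_config(c))
        ok = trace.data[trace.data["converged"].astype(bool)]
        return float(ok["contact_force"].max())

    base_peak = run()
    rows = []
    for param, values in grid.items():
        for val in values:
            try:
                if param == "pressure_module":
                    peak = run(pressure=val)
                elif param == "criterion_order":
                    peak = run(order=val)
                else:
                    peak = run(steps=int(val))
                rows.append({"parameter": param, "value": val,
                             "peak_contact": peak,
                             "pct_change": percent_change(base_peak, peak),
                             "status": "ok"})
            except (SweepAborted, RecruitmentInfeasible) as exc:
                rows.append({"parameter": param, "value": val,
                             "peak_contact": np.nan, "pct_change": np.nan,
                             "status": f"failed: {exc}"})
    return pd.DataFrame(rows)
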