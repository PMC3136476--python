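"""Post-processing and in-silico experiments on simulation results.

Covers the derived readouts used throughout the study: concentration
profiles along the radius, time courses at a probe radius, integrated
(area-under-curve) responses, dose-response and cell-density sweeps, the
endocytic-downregulation ratio R, lag/peak timing metrics, and detection of
ligand-profile inversion.

Probe conventions: "the center of the cell" is r = 0; "the cell surface"
is the mid-shell radius (the model alternates between the R1 and R2
wordings, so a single convention is fixed here and documented).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    DiffusionCoefficients,
    Geometry,
    InitialConditions,
    KineticParameters,
)
from .inputs import LigandInputProgram
from .mesh import SPECIES_DOMAIN
from .spatial import SimulationResult, simulate

__all__ = [
    "ResponseCurve",
    "TimingMetrics",
    "profile_at_time",
    "timecourse_at_radius",
    "volume_average",
    "integrated_response",
    "dose_response_curve",
    "density_response",
    "downregulation_ratio",
    "response_timing_metrics",
    "detect_profile_inversion",
    "half_max_x",
]


@dataclass(frozen=True)
class ResponseCurve:
    """A response sampled over a strictly monotone independent variable."""

    x: np.ndarray
    y: np.ndarray
    x_name: str
    y_name: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        if x.size > 1:
            dx = np.diff(x)
            if not (np.all(dx > 0) or np.all(dx < 0)):
                raise ValueError("independent variable must be strictly monotone")


def _species_domain(result: SimulationResult, species: str):
    if species not in result.fields:
        raise KeyError(f"unknown species {species!r}")
    return result.mesh.domain(SPECIES_DOMAIN[species])


def profile_at_time(
    result: SimulationResult, species: str, t: float
) -> tuple[np.ndarray, np.ndarray]:
    """Concentration vs radius at time ``t`` (linear interpolation between
    snapshots); radii are the cell centers of the species' domain."""
    dom = _species_domain(result, species)
    times = result.times
    if not (times[0] <= t <= times[-1]):
        raise ValueError(f"t={t:g} outside result horizon "
                         f"[{times[0]:g}, {times[-1]:g}] s")
    arr = result.fields[species]
    j = int(np.searchsorted(times, t, side="right") - 1)
    j = min(j, times.size - 2)
    w = (t - times[j]) / (times[j + 1] - times[j])
    return dom.centers.copy(), (1.0 - w) * arr[j] + w * arr[j + 1]


def timecourse_at_radius(
    result: SimulationResult, species: str, r: float, mode: str = "linear"
) -> tuple[np.ndarray, np.ndarray]:
    """Concentration vs time at probe radius ``r``.

    ``mode`` is "linear" (interpolate between the two bracketing cell
    centers, clamped at domain edges) or "nearest" (nearest cell center).
    """
    dom = _species_domain(result, species)
    if not (dom.faces[0] <= r <= dom.faces[-1]):
        raise ValueError(
            f"r={r:g} µm outside the {species} domain "
            f"[{dom.faces[0]:g}, {dom.faces[-1]:g}] µm")
    arr = result.fields[species]
    if mode == "nearest":
        i = int(np.argmin(np.abs(dom.centers - r)))
        return result.times.copy(), arr[:, i].copy()
    if mode != "linear":
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    c = dom.centers
    if r <= c[0]:
        return result.times.copy(), arr[:, 0].copy()
    if r >= c[-1]:
        return result.times.copy(), arr[:, -1].copy()
    i = int(np.searchsorted(c, r) - 1)
    w = (r - c[i]) / (c[i + 1] - c[i])
    return result.times.copy(), (1.0 - w) * arr[:, i] + w * arr[:, i + 1]


def volume_average(result: SimulationResult, species: str) -> np.ndarray:
    """Volume-averaged concentration of a species over its domain vs time."""
    dom = _species_domain(result, species)
    return (result.fields[species] @ dom.volumes) / dom.volumes.sum()


def probe_radius(geometry: Geometry, where: str) -> float:
    """Named probe radii: 'center' (r=0), 'surface' (mid-shell), 'r1', 'r2',
    'outer' (R3)."""
    table = {
        "center": 0.0,
        "surface": geometry.r_cell + 0.5 * geometry.shell_thickness,
        "r1": geometry.r_cell,
        "r2": geometry.r_shell_outer,
        "outer": geometry.r_outer,
    }
    if where not in table:
        raise ValueError(f"unknown probe {where!r}; choose from {sorted(table)}")
    return table[where]


def integrated_response(
    result: SimulationResult,
    species: str,
    r: float,
    horizon: float = 36000.0,
) -> float:
    """Area under the probed concentration-time course, in nM·min.

    Trapezoidal quadrature of the time course at radius ``r`` from t = 0 to
    ``horizon`` (s), with concentration in nM and time in minutes.
    """
    if horizon > result.times[-1] + 1e-9:
        raise ValueError(f"horizon {horizon:g} s exceeds result horizon "
                         f"{result.times[-1]:g} s")
    times, values = timecourse_at_radius(result, species, r)
    mask = times <= horizon + 1e-9
    return float(np.trapezoid(values[mask], times[mask] / 60.0))


def dose_response_curve(
    params: KineticParameters,
    diffusion: DiffusionCoefficients,
    geometry: Geometry,
    initial: InitialConditions,
    doses: np.ndarray,
    *,
    species: str = "LRI",
    probe: str = "center",
    horizon: float = 36000.0,
    n_snapshots: int = 181,
    resolution: tuple[int, int, int] = (40, 8, 120),
) -> ResponseCurve:
    """Integrated response at each bolus dose (one fresh simulation per dose).

    Failed simulations are marked NaN rather than aborting the sweep.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be nonnegative and strictly increasing")
    t_eval = np.linspace(0.0, horizon, n_snapshots)
    r = probe_radius(geometry, probe)
    responses = np.empty_like(doses)
    failures: list[float] = []
    for i, dose in enumerate(doses):
        try:
            res = simulate(
                params, diffusion, geometry, initial,
                LigandInputProgram.bolus(dose), t_eval, resolution=resolution,
            )
            responses[i] = integrated_response(res, species, r, horizon)
        except (RuntimeError, FloatingPointError):
            responses[i] = np.nan
            failures.append(float(dose))
    return ResponseCurve(
        x=doses, y=responses, x_name="dose_nM", y_name=f"auc_{species}_nM_min",
        metadata={"species": species, "probe": probe, "probe_radius_um": r,
                  "horizon_s": horizon, "density_per_ml": geometry.density,
                  "failed_doses": failures},
    )


def density_response(
    params: KineticParameters,
    diffusion: DiffusionCoefficients,
    base_geometry: Geometry,
    initial: InitialConditions,
    r_outer_grid: np.ndarray,
    *,
    dose: float = 1.0,
    t_probe: float = 3600.0,
    resolution: tuple[int, int, int] = (40, 8, 120),
    species: tuple[str, ...] = ("RS", "LRS", "RI", "LRI"),
) -> dict[str, ResponseCurve]:
    """Species concentrations at ``t_probe`` across an outer-radius grid.

    Surface species are probed mid-shell, internalized species at the cell
    center.  Each grid point is an independent simulation of a bolus of
    ``dose`` nM.
    """
    r_outer_grid = np.asarray(r_outer_grid, dtype=float)
    if np.any(np.diff(r_outer_grid) <= 0):
        raise ValueError("r_outer grid must be strictly increasing")
    t_eval = np.linspace(0.0, t_probe, 61)
    values = {sp: np.empty_like(r_outer_grid) for sp in species}
    for i, r3 in enumerate(r_outer_grid):
        geom = replace(base_geometry, r_outer=float(r3))
        try:
            res = simulate(params, diffusion, geom, initial,
                           LigandInputProgram.bolus(dose), t_eval,
                           resolution=resolution)
            for sp in species:
                where = "surface" if SPECIES_DOMAIN[sp] == "shell" else "center"
                _, series = timecourse_at_radius(
                    res, sp, probe_radius(geom, where))
                values[sp][i] = series[-1]
        except (RuntimeError, FloatingPointError):
            for sp in species:
                values[sp][i] = np.nan
    return {
        sp: ResponseCurve(
            x=r_outer_grid, y=values[sp], x_name="r_outer_um",
            y_name=f"{sp}_nM",
            metadata={"species": sp, "dose_nM": dose, "t_probe_s": t_probe},
        )
        for sp in species
    }


def downregulation_ratio(params: KineticParameters) -> float:
    """Endocytic-downregulation ratio R = k_int_bound / k_int_free, the
    standard estimate of ligand-induced internalization enhancement."""
    if params.k_int_free == 0:
        raise ValueError("R is undefined when k_int_free is zero")
    return params.k_int_bound / params.k_int_free


@dataclass(frozen=True)
class TimingMetrics:
    """Lag/peak descriptors of a single response time course."""

    lag_time: float          # first time above lag_fraction * peak, s
    peak_time: float         # s
    peak_value: float        # nM
    decay_fraction: float    # (peak - final) / peak
    defined: bool = True


def response_timing_metrics(
    times: np.ndarray, values: np.ndarray, lag_fraction: float = 0.05
) -> TimingMetrics:
    """Lag time, peak time/value and end-of-horizon decay of a series.

    The lag threshold defaults to 5 % of the peak.  For a monotone rising
    series the peak sits at the end of the horizon; an all-zero series
    yields undefined (NaN) metrics.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValueError("series is empty")
    peak_idx = int(np.argmax(values))
    peak = float(values[peak_idx])
    if peak <= 0:
        return TimingMetrics(math.nan, math.nan, 0.0, math.nan, defined=False)
    above = np.nonzero(values >= lag_fraction * peak)[0]
    lag = float(times[above[0]]) if above.size else math.nan
    decay = (peak - float(values[-1])) / peak
    return TimingMetrics(
        lag_time=lag, peak_time=float(times[peak_idx]), peak_value=peak,
        decay_fraction=decay,
    )


def _slope_sign(radii: np.ndarray, conc: np.ndarray, rel_tol: float) -> int:
    """Sign of the least-squares slope of concentration vs radius; 0 when the
    profile is flat relative to its mean level."""
    if conc.size < 2 or np.ptp(conc) <= rel_tol * max(abs(conc).max(), 1e-30):
        return 0
    slope = np.polyfit(radii, conc, 1)[0]
    scale = max(abs(conc).max(), 1e-30) / np.ptp(radii)
    if abs(slope) <= rel_tol * scale:
        return 0
    return 1 if slope > 0 else -1


def detect_profile_inversion(
    result: SimulationResult,
    species: str,
    t_early: float,
    t_late: float,
    rel_tol: float = 1e-6,
) -> dict:
    """Compare the radial gradient sign of a species at two times.

    Returns ``{"early_sign", "late_sign", "inverted"}``; inversion means the
    two least-squares slope signs are nonzero and opposite — e.g. ligand
    initially decreasing toward the cell (uptake) and later increasing
    (release from the surface).
    """
    radii, early = profile_at_time(result, species, t_early)
    _, late = profile_at_time(result, species, t_late)
    s_early = _slope_sign(radii, early, rel_tol)
    s_late = _slope_sign(radii, late, rel_tol)
    return {
        "early_sign": s_early,
        "late_sign": s_late,
        "inverted": bool(s_early != 0 and s_late != 0 and s_early != s_late),
    }


def half_max_x(curve: ResponseCurve) -> float:
    """Interpolated x at which a nondecreasing response reaches half its
    maximum; used to quantify dose-response shifts with cell density."""
    y = curve.y
    if np.any(np.isnan(y)):
        raise ValueError("curve contains failed points")
    target = 0.5 * float(np.max(y))
    above = np.nonzero(y >= target)[0]
    if above.size == 0:
        raise ValueError("curve never reaches half-maximum")
    i = int(above[0])
    if i == 0:
        return float(curve.x[0])
    x0, x1 = curve.x[i - 1], curve.x[i]
    y0, y1 = y[i - 1], y[i]
    return float(x0 + (target - y0) * (x1 - x0) / (y1 - y0))
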