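"""Non-spatial (well-mixed) comparator: a six-variable trafficking ODE.

All receptor species (RS, LRS, RI, LRI) are referenced to a single
compartment volume, as non-spatial trafficking models do; shell-side ligand
is identical to extracellular ligand (LS ≡ L).  Ligand depletion by surface
binding is scaled by the reaction-volume to extracellular-volume ratio, so
the extracellular volume per cell enters only the ligand equation.

Because the single reference volume ignores the different domain volumes of
the spatial model, the two models make genuinely different mass-balance
predictions from the same printed numbers: with saturating ligand and no
recycling/degradation the well-mixed maximum of RI + LRI is
``rs0 + ri0`` (650 + 450 = 1100 nM with the default initial conditions),
whereas the spatial model caps LRI at the shell-to-cell conversion of rs0
(≈26.3 nM).  Converting mass-transfer coefficients with
:func:`spatial_to_wellmixed_params` (and initial conditions with
:func:`wellmixed_initial_from_spatial`) instead makes the well-mixed model
the exact fast-diffusion limit of the spatial one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import Geometry, InitialConditions, KineticParameters
from .inputs import LigandInputProgram, input_rate

__all__ = [
    "WellMixedParameters",
    "WellMixedResult",
    "spatial_to_wellmixed_params",
    "wellmixed_initial_from_spatial",
    "simulate_wellmixed",
    "wellmixed_mass_balance",
]

_WM_SPECIES = ("L", "RS", "LRS", "RI", "LRI")


@dataclass(frozen=True)
class WellMixedParameters:
    """First-order constants of the non-spatial model (1/s unless noted)."""

    k_on: float          # 1/(nM·s)
    k_off: float         # 1/s
    k_syn: float         # nM/s, referenced to the reaction volume
    k_int_free: float
    k_int_bound: float
    k_rec_free: float
    k_rec_bound: float
    k_deg_free: float
    k_deg_bound: float
    k_dephos: float
    vol_ratio: float     # reaction volume / extracellular volume (dimensionless)

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_syn", "k_int_free", "k_int_bound",
                     "k_rec_free", "k_rec_bound", "k_deg_free", "k_deg_bound",
                     "k_dephos"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.vol_ratio <= 0:
            raise ValueError("vol_ratio must be > 0")


def spatial_to_wellmixed_params(
    params: KineticParameters, geometry: Geometry
) -> WellMixedParameters:
    """Convert mass-transfer coefficients to first-order rate constants.

    Each coefficient k (µm/s) acting across the R1 interface of area
    A = 4πR1² becomes ``k·A/V`` where V is the volume of the compartment the
    species leaves: the shell for internalization, the cell for recycling.
    For a thin shell A/V_shell ≈ 1/δ.  The synthesis boundary flux becomes a
    volumetric rate over the shell, and the ligand-depletion ratio is
    V_shell/V_ext (extracellular volume, not total).
    """
    a1 = geometry.a_cell
    v_shell, v_cell = geometry.v_shell, geometry.v_cell
    return WellMixedParameters(
        k_on=params.k_on,
        k_off=params.k_off,
        k_syn=params.q_syn * a1 / v_shell,
        k_int_free=params.k_int_free * a1 / v_shell,
        k_int_bound=params.k_int_bound * a1 / v_shell,
        k_rec_free=params.k_rec_free * a1 / v_cell,
        k_rec_bound=params.k_rec_bound * a1 / v_cell,
        k_deg_free=params.k_deg_free,
        k_deg_bound=params.k_deg_bound,
        k_dephos=params.k_dephos,
        vol_ratio=v_shell / geometry.v_ext,
    )


def wellmixed_initial_from_spatial(
    initial: InitialConditions, geometry: Geometry
) -> InitialConditions:
    """Re-reference intracellular initial concentrations to the shell volume.

    Used when the well-mixed model should agree with the spatial one in the
    fast-diffusion limit; non-spatial models taken at face value instead use
    the printed numbers unchanged (the source of the 1100 vs 476.3 nM
    discrepancy).
    """
    scale = geometry.v_cell / geometry.v_shell
    return replace(initial, ri0=initial.ri0 * scale, lri0=initial.lri0 * scale)


@dataclass
class WellMixedResult:
    """ODE trajectories plus cumulative ledger (same layout idea as the
    spatial result; concentrations are single-compartment nM)."""

    times: np.ndarray
    series: dict[str, np.ndarray]   # L, LS, RS, LRS, RI, LRI -> (nt,)
    ledger: dict[str, np.ndarray]   # nM referenced to the reaction volume
    params: WellMixedParameters
    initial: InitialConditions
    program: LigandInputProgram
    diagnostics: dict


def _wm_rhs(t: float, y: np.ndarray, p: WellMixedParameters,
            q: float) -> np.ndarray:
    lig, rs, lrs, ri, lri = y[:5]
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite state at t={t:g} s")
    bind = p.k_on * lig * rs - p.k_off * lrs
    d_lig = q - p.vol_ratio * bind
    d_rs = -bind + p.k_syn + p.k_rec_free * ri - p.k_int_free * rs
    d_lrs = bind + p.k_rec_bound * lri - p.k_int_bound * lrs
    d_ri = p.k_int_free * rs - p.k_rec_free * ri - p.k_deg_free * ri \
        + p.k_dephos * lri
    d_lri = p.k_int_bound * lrs - p.k_rec_bound * lri \
        - (p.k_deg_bound + p.k_dephos) * lri
    # ledger: synthesized/degraded receptor, injected/degraded ligand
    d_syn = p.k_syn
    d_degr = p.k_deg_free * ri + p.k_deg_bound * lri
    d_inj = q / p.vol_ratio  # reaction-volume units
    d_degl = (p.k_deg_bound + p.k_dephos) * lri
    return np.array([d_lig, d_rs, d_lrs, d_ri, d_lri,
                     d_syn, d_degr, d_inj, d_degl])


def simulate_wellmixed(
    wm_params: WellMixedParameters,
    initial: InitialConditions,
    program: LigandInputProgram | None = None,
    t_eval: np.ndarray | None = None,
    *,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> WellMixedResult:
    """Integrate the well-mixed trafficking ODEs and snapshot at ``t_eval``."""
    if program is None:
        program = LigandInputProgram.bolus(0.0)
    if t_eval is None:
        t_eval = np.linspace(0.0, 3600.0, 121)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.ndim != 1 or t_eval.size < 2 or np.any(np.diff(t_eval) <= 0):
        raise ValueError("t_eval must be a 1-D strictly increasing array")
    if t_eval[0] < 0:
        raise ValueError("t_eval must start at t >= 0")

    l0 = initial.l0 + (program.bolus_conc if program.mode == "bolus" else 0.0)
    y0 = np.array([l0, initial.rs0, initial.lrs0, initial.ri0, initial.lri0,
                   0.0, 0.0, 0.0, 0.0])
    t_end = float(t_eval[-1])
    edges = program.breakpoints()
    stops = np.unique(np.concatenate(
        ([0.0, t_end], edges[(edges > 0.0) & (edges < t_end)])))

    states = np.empty((t_eval.size, y0.size))
    filled = np.zeros(t_eval.size, dtype=bool)
    if t_eval[0] == 0.0:
        states[0] = y0
        filled[0] = True
    y = y0
    n_pts = 0
    for a, b in zip(stops[:-1], stops[1:]):
        inner = t_eval[(t_eval > a) & (t_eval < b)]
        seg_eval = np.unique(np.concatenate((inner, [b])))
        # the source rate is constant within each segment between breakpoints
        q_seg = input_rate(program, 0.5 * (a + b))
        sol = solve_ivp(_wm_rhs, (a, b), y, method=method, t_eval=seg_eval,
                        rtol=rtol, atol=atol, args=(wm_params, q_seg))
        if not sol.success:
            raise RuntimeError(f"integrator failed on [{a:g}, {b:g}] s: "
                               f"{sol.message}")
        n_pts += sol.t.size
        for j, tj in enumerate(sol.t):
            hits = np.nonzero(np.isclose(t_eval, tj, rtol=0, atol=1e-9))[0]
            for h in hits:
                states[h] = sol.y[:, j]
                filled[h] = True
        y = sol.y[:, -1]
    if not np.all(filled):
        raise RuntimeError("internal error: missing snapshot times")

    series = {name: states[:, i] for i, name in enumerate(_WM_SPECIES)}
    series["LS"] = series["L"]  # shell-side ligand is the same pool
    ledger = {
        "synthesized_receptor": states[:, 5],
        "degraded_receptor": states[:, 6],
        "injected_ligand": states[:, 7],
        "degraded_ligand": states[:, 8],
    }
    return WellMixedResult(
        times=t_eval, series=series, ledger=ledger, params=wm_params,
        initial=initial, program=program,
        diagnostics={"method": method, "rtol": rtol, "atol": atol,
                     "n_accepted_points": n_pts},
    )


def wellmixed_mass_balance(result: WellMixedResult) -> dict[str, float]:
    """Max relative drift of the ligand and receptor conservation ledgers.

    In reaction-volume units the conserved totals are
    ``L/vol_ratio + LRS + LRI + degraded − injected`` (ligand) and
    ``RS + LRS + RI + LRI + degraded − synthesized`` (receptor).
    """
    p = result.params
    s, led = result.series, result.ledger
    ligand = (s["L"] / p.vol_ratio + s["LRS"] + s["LRI"]
              + led["degraded_ligand"] - led["injected_ligand"])
    receptor = (s["RS"] + s["LRS"] + s["RI"] + s["LRI"]
                + led["degraded_receptor"] - led["synthesized_receptor"])
    lig_scale = max(abs(ligand[0]), abs(led["injected_ligand"][-1]), 1e-30)
    rec_scale = max(abs(receptor[0]), 1e-30)
    return {
        "ligand_max_rel": float(np.max(np.abs(ligand - ligand[0])) / lig_scale),
        "receptor_max_rel": float(np.max(np.abs(receptor - receptor[0]))
                                  / rec_scale),
    }
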