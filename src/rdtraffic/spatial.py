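"""The spatial trafficking model: radial reaction-diffusion in three domains.

Species and domains (concentrations in nM):

* extracellular medium: free ligand ``L`` (+ volumetric source Q_L(t)),
* cell-surface shell: shell-side ligand ``LS``, free receptor ``RS`` and
  surface complex ``LRS`` coupled by mass action,
* intracellular space: internalized receptor ``RI`` and complex ``LRI``
  with first-order degradation and dephosphorylation.

Transport is spherically symmetric diffusion, discretized with cell-centered
conservative finite volumes: the area-integrated flux across a face of
radius r is ``D · 4πr² · (c_out − c_in)/Δr`` between adjacent cell centers.
Heterogeneous processes act as interface fluxes rather than volumetric
rates: at R1, internalization/recycling/synthesis exchange receptor species
between shell and cell (mass-transfer coefficients, µm/s); at R2, ``L`` and
``LS`` are coupled by concentration continuity and diffusive flux
continuity.  Zero flux holds at r = 0 (symmetry), at R3 (insulation), for
``RS``/``LRS`` at R2 and for ``LS`` at R1.

Cumulative sources/sinks (synthesis, degradation, injected ligand) are
integrated alongside the fields, so every run carries an exact mass-balance
ledger: total ligand and total receptor amounts, corrected by the ledger,
are linear invariants of the semi-discrete system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.sparse.linalg import spsolve

from .geometry import (
    DiffusionCoefficients,
    Geometry,
    InitialConditions,
    KineticParameters,
)
from .inputs import LigandInputProgram, input_rate
from .mesh import DomainMesh, RadialMesh, build_mesh

__all__ = [
    "SpatialProblem",
    "SimulationResult",
    "MassBalanceReport",
    "simulate",
    "mass_balance",
    "apply_diffusion",
    "steady_dirichlet_profile",
]

SPECIES = ("RI", "LRI", "LS", "RS", "LRS", "L")
LEDGER = ("synthesized_receptor", "degraded_receptor",
          "injected_ligand", "degraded_ligand")


def apply_diffusion(
    domain: DomainMesh,
    d_coef: float,
    c: np.ndarray,
    flux_inner: float = 0.0,
    flux_outer: float = 0.0,
) -> np.ndarray:
    """Finite-volume diffusion operator on one domain.

    ``flux_inner``/``flux_outer`` are prescribed area-integrated fluxes
    (nM·µm³/s, positive in the +r direction) through the two boundary
    faces; interior faces use the two-point conductance.  Returns dc/dt.
    """
    n = domain.n
    flux = np.empty(n + 1)
    flux[0] = flux_inner
    flux[-1] = flux_outer
    dr = np.diff(domain.centers)
    flux[1:n] = -d_coef * domain.areas[1:n] * (c[1:] - c[:-1]) / dr
    return (flux[:-1] - flux[1:]) / domain.volumes


class SpatialProblem:
    """Pre-assembled right-hand side of the semi-discrete system.

    The state vector concatenates ``RI, LRI`` (intracellular nodes),
    ``LS, RS, LRS`` (shell nodes), ``L`` (extracellular nodes) and the four
    cumulative ledger amounts (nM·µm³).
    """

    def __init__(
        self,
        params: KineticParameters,
        diffusion: DiffusionCoefficients,
        geometry: Geometry,
        mesh: RadialMesh | None = None,
        program: LigandInputProgram | None = None,
        resolution: tuple[int, int, int] = (40, 8, 120),
    ):
        self.params = params
        self.diffusion = diffusion
        self.geometry = geometry
        self.mesh = mesh if mesh is not None else build_mesh(geometry, resolution)
        self.program = program if program is not None else LigandInputProgram.bolus(0.0)

        nc, ns, ne = self.mesh.cell.n, self.mesh.shell.n, self.mesh.ext.n
        self.slices: dict[str, slice] = {}
        offset = 0
        for name, size in (("RI", nc), ("LRI", nc), ("LS", ns), ("RS", ns),
                           ("LRS", ns), ("L", ne)):
            self.slices[name] = slice(offset, offset + size)
            offset += size
        self.ledger_slice = slice(offset, offset + len(LEDGER))
        self.n_state = offset + len(LEDGER)

        # per-domain interior-face conductances: flux*area = g*(c_in - c_out)
        def conductance(dom: DomainMesh, d_coef: float) -> np.ndarray:
            return d_coef * dom.areas[1:-1] / np.diff(dom.centers)

        m = self.mesh
        self._g = {
            "RI": conductance(m.cell, diffusion.d_free_cell),
            "LRI": conductance(m.cell, diffusion.d_complex_cell),
            "LS": conductance(m.shell, diffusion.d_free_surface),
            "RS": conductance(m.shell, diffusion.d_free_surface),
            "LRS": conductance(m.shell, diffusion.d_complex_surface),
            "L": conductance(m.ext, diffusion.d_ligand_ext),
        }
        # L <-> LS coupling at R2: series conductance of the two half-cells
        dr_s = m.shell.centers[-1] - m.shell.faces[-1]   # negative half-width
        dr_e = m.ext.centers[0] - m.ext.faces[0]
        resistance = (-dr_s) / diffusion.d_free_surface + dr_e / diffusion.d_ligand_ext
        self._g_r2 = m.shell.areas[-1] / resistance
        self._a1 = geometry.a_cell
        self._v_ext_total = float(m.ext.volumes.sum())
        #: per-segment constant source rate (set by `simulate` between input
        #: breakpoints so edge values never leak across a discontinuity)
        self.rate_override: float | None = None

    def initial_state(self, initial: InitialConditions) -> np.ndarray:
        """Uniform fields; a bolus program adds to the extracellular ligand."""
        y0 = np.zeros(self.n_state)
        values = {
            "RI": initial.ri0, "LRI": initial.lri0, "LS": 0.0,
            "RS": initial.rs0, "LRS": initial.lrs0,
            "L": initial.l0 + (self.program.bolus_conc
                               if self.program.mode == "bolus" else 0.0),
        }
        for name, value in values.items():
            y0[self.slices[name]] = value
        return y0

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(
                f"non-finite state encountered at t={t:g} s; integration aborted"
            )
        p, m = self.params, self.mesh
        s = self.slices
        ri, lri = y[s["RI"]], y[s["LRI"]]
        ls, rs, lrs = y[s["LS"]], y[s["RS"]], y[s["LRS"]]
        lig = y[s["L"]]
        dy = np.zeros_like(y)

        # diffusion (zero-flux closures; interface terms added below)
        for name, dom in (("RI", m.cell), ("LRI", m.cell), ("LS", m.shell),
                          ("RS", m.shell), ("LRS", m.shell), ("L", m.ext)):
            c = y[s[name]]
            g = self._g[name]
            flux = np.zeros(dom.n + 1)
            flux[1:-1] = g * (c[:-1] - c[1:])
            dy[s[name]] += (flux[:-1] - flux[1:]) / dom.volumes

        # mass action in the shell
        rate = p.k_on * ls * rs - p.k_off * lrs
        dy[s["LS"]] -= rate
        dy[s["RS"]] -= rate
        dy[s["LRS"]] += rate

        # intracellular degradation and dephosphorylation
        dy[s["RI"]] += -p.k_deg_free * ri + p.k_dephos * lri
        dy[s["LRI"]] += -(p.k_deg_bound + p.k_dephos) * lri

        # R1 interface: synthesis, internalization, recycling (area-integrated)
        a1 = self._a1
        vs0 = m.shell.volumes[0]
        vcn = m.cell.volumes[-1]
        phi_rs = a1 * (p.q_syn + p.k_rec_free * ri[-1] - p.k_int_free * rs[0])
        phi_ri = a1 * (p.k_int_free * rs[0] - p.k_rec_free * ri[-1])
        phi_lrs = a1 * (p.k_rec_bound * lri[-1] - p.k_int_bound * lrs[0])
        phi_lri = a1 * (p.k_int_bound * lrs[0] - p.k_rec_bound * lri[-1])
        dy[s["RS"].start] += phi_rs / vs0
        dy[s["RI"].stop - 1] += phi_ri / vcn
        dy[s["LRS"].start] += phi_lrs / vs0
        dy[s["LRI"].stop - 1] += phi_lri / vcn

        # R2 interface: L <-> LS continuity flux
        phi_l = self._g_r2 * (lig[0] - ls[-1])
        dy[s["LS"].stop - 1] += phi_l / m.shell.volumes[-1]
        dy[s["L"].start] -= phi_l / m.ext.volumes[0]

        # ligand source
        if self.rate_override is not None:
            q = self.rate_override
        else:
            q = input_rate(self.program, max(t, 0.0))
        if q != 0.0:
            dy[s["L"]] += q

        # cumulative ledgers (amounts, nM·µm³)
        led = self.ledger_slice.start
        vc = m.cell.volumes
        dy[led + 0] = p.q_syn * a1
        dy[led + 1] = float(np.dot(p.k_deg_free * ri + p.k_deg_bound * lri, vc))
        dy[led + 2] = q * self._v_ext_total
        dy[led + 3] = float(np.dot((p.k_deg_bound + p.k_dephos) * lri, vc))
        return dy

    def jac_sparsity(self) -> sparse.csr_matrix:
        """Structural Jacobian for grouped finite-difference evaluation."""
        s = self.slices
        jac = sparse.lil_matrix((self.n_state, self.n_state), dtype=np.int8)

        def tridiag(sl: slice) -> None:
            n = sl.stop - sl.start
            idx = np.arange(sl.start, sl.stop)
            jac[idx, idx] = 1
            jac[idx[:-1], idx[1:]] = 1
            jac[idx[1:], idx[:-1]] = 1

        for name in SPECIES:
            tridiag(s[name])
        ns = s["LS"].stop - s["LS"].start
        for i in range(ns):  # mass action couples LS, RS, LRS nodewise
            trio = (s["LS"].start + i, s["RS"].start + i, s["LRS"].start + i)
            for a in trio:
                for b in trio:
                    jac[a, b] = 1
        nc = s["RI"].stop - s["RI"].start
        for i in range(nc):  # dephosphorylation couples LRI -> RI
            jac[s["RI"].start + i, s["LRI"].start + i] = 1
        # R1 interface couplings
        for a, b in (
            (s["RS"].start, s["RI"].stop - 1), (s["RI"].stop - 1, s["RS"].start),
            (s["LRS"].start, s["LRI"].stop - 1), (s["LRI"].stop - 1, s["LRS"].start),
            (s["RS"].start, s["RS"].start), (s["RI"].stop - 1, s["RI"].stop - 1),
        ):
            jac[a, b] = 1
        # R2 interface couplings
        jac[s["LS"].stop - 1, s["L"].start] = 1
        jac[s["L"].start, s["LS"].stop - 1] = 1
        # ledger rows depend on intracellular fields
        led = self.ledger_slice.start
        jac[led + 1, s["RI"]] = 1
        jac[led + 1, s["LRI"]] = 1
        jac[led + 3, s["LRI"]] = 1
        return jac.tocsr()


@dataclass
class SimulationResult:
    """Time-stamped concentration fields plus the mass-balance ledger."""

    times: np.ndarray                  # (nt,) s
    fields: dict[str, np.ndarray]      # species -> (nt, n_nodes) nM
    ledger: dict[str, np.ndarray]      # ledger name -> (nt,) nM·µm³
    mesh: RadialMesh
    params: KineticParameters
    diffusion: DiffusionCoefficients
    geometry: Geometry
    initial: InitialConditions
    program: LigandInputProgram
    diagnostics: dict = field(default_factory=dict)

    def field_at(self, species: str, i_time: int) -> np.ndarray:
        return self.fields[species][i_time]


def simulate(
    params: KineticParameters,
    diffusion: DiffusionCoefficients,
    geometry: Geometry,
    initial: InitialConditions,
    program: LigandInputProgram | None = None,
    t_eval: np.ndarray | None = None,
    *,
    mesh: RadialMesh | None = None,
    resolution: tuple[int, int, int] = (40, 8, 120),
    method: str = "BDF",
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> SimulationResult:
    """Integrate the semi-discrete system and snapshot at ``t_eval``.

    The integration is restarted at every breakpoint of the ligand-input
    program so rate discontinuities are resolved exactly.  Default
    tolerances are rtol 1e-6 and atol 1e-9 nM with the stiff BDF stepper.
    """
    if program is None:
        program = LigandInputProgram.bolus(0.0)
    if t_eval is None:
        t_eval = np.linspace(0.0, 3600.0, 121)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.ndim != 1 or t_eval.size < 2 or np.any(np.diff(t_eval) <= 0):
        raise ValueError("t_eval must be a 1-D strictly increasing array")
    if t_eval[0] < 0:
        raise ValueError("t_eval must start at t >= 0")

    problem = SpatialProblem(params, diffusion, geometry,
                             mesh=mesh, program=program, resolution=resolution)
    y0 = problem.initial_state(initial)
    t0, t_end = 0.0, float(t_eval[-1])  # initial conditions live at t = 0
    edges = program.breakpoints()
    stops = np.unique(np.concatenate(
        ([t0, t_end], edges[(edges > t0) & (edges < t_end)])))

    sparsity = problem.jac_sparsity()
    states = np.empty((t_eval.size, problem.n_state))
    filled = np.zeros(t_eval.size, dtype=bool)
    if t_eval[0] == t0:
        states[0] = y0
        filled[0] = True
    n_steps = 0
    y = y0
    for a, b in zip(stops[:-1], stops[1:]):
        inner = t_eval[(t_eval > a) & (t_eval < b)]
        seg_eval = np.unique(np.concatenate((inner, [b])))
        problem.rate_override = input_rate(program, 0.5 * (a + b))
        sol = solve_ivp(
            problem.rhs, (a, b), y, method=method, t_eval=seg_eval,
            rtol=rtol, atol=atol, jac_sparsity=sparsity,
        )
        if not sol.success:
            raise RuntimeError(
                f"integrator failed on [{a:g}, {b:g}] s: {sol.message}; "
                f"last good time {sol.t[-1] if sol.t.size else a:g} s"
            )
        n_steps += sol.t.size
        for j, tj in enumerate(sol.t):
            hits = np.nonzero(np.isclose(t_eval, tj, rtol=0, atol=1e-9))[0]
            for h in hits:
                states[h] = sol.y[:, j]
                filled[h] = True
        y = sol.y[:, -1]
    problem.rate_override = None
    if not np.all(filled):
        raise RuntimeError("internal error: some snapshot times were not produced")

    fields = {name: states[:, problem.slices[name]] for name in SPECIES}
    led0 = problem.ledger_slice.start
    ledger = {name: states[:, led0 + i] for i, name in enumerate(LEDGER)}
    result = SimulationResult(
        times=t_eval, fields=fields, ledger=ledger, mesh=problem.mesh,
        params=params, diffusion=diffusion, geometry=geometry,
        initial=initial, program=program,
        diagnostics={"method": method, "rtol": rtol, "atol": atol,
                     "n_accepted_points": n_steps},
    )
    report = mass_balance(result)
    result.diagnostics["mass_balance_max_rel"] = report.max_relative_residual
    return result


@dataclass(frozen=True)
class MassBalanceReport:
    """Ledger residuals: conserved totals minus their initial values."""

    times: np.ndarray
    ligand_residual: np.ndarray    # nM·µm³
    receptor_residual: np.ndarray  # nM·µm³
    ligand_relative: np.ndarray
    receptor_relative: np.ndarray

    @property
    def max_relative_residual(self) -> float:
        vals = np.concatenate(
            (np.abs(self.ligand_relative), np.abs(self.receptor_relative)))
        return float(np.max(vals))


def mass_balance(result: SimulationResult) -> MassBalanceReport:
    """Check the ligand and receptor mass ledgers of a spatial run.

    Total ligand = L + LS + LRS + LRI amounts + degraded − injected;
    total receptor = RS + LRS + RI + LRI amounts + degraded − synthesized.
    Both should stay at their initial values to integrator accuracy.
    """
    m = result.mesh
    vc, vs, ve = m.cell.volumes, m.shell.volumes, m.ext.volumes

    def amount(species: str, vols: np.ndarray) -> np.ndarray:
        return result.fields[species] @ vols

    ligand = (amount("L", ve) + amount("LS", vs) + amount("LRS", vs)
              + amount("LRI", vc)
              + result.ledger["degraded_ligand"] - result.ledger["injected_ligand"])
    receptor = (amount("RS", vs) + amount("LRS", vs) + amount("RI", vc)
                + amount("LRI", vc)
                + result.ledger["degraded_receptor"]
                - result.ledger["synthesized_receptor"])
    lig_res = ligand - ligand[0]
    rec_res = receptor - receptor[0]
    total_v = m.total_volume
    lig_scale = max(abs(ligand[0]), result.ledger["injected_ligand"][-1],
                    1e-12 * total_v)
    rec_scale = max(abs(receptor[0]), 1e-12 * total_v)
    return MassBalanceReport(
        times=result.times,
        ligand_residual=lig_res,
        receptor_residual=rec_res,
        ligand_relative=lig_res / lig_scale,
        receptor_relative=rec_res / rec_scale,
    )


def steady_dirichlet_profile(
    domain: DomainMesh, d_coef: float, c_inner: float, c_outer: float
) -> np.ndarray:
    """Steady pure-diffusion profile with fixed concentrations at both faces.

    Solves the finite-volume Laplace problem on one spherical domain with
    Dirichlet values imposed at the inner/outer boundary faces through
    second-order one-sided flux closures.  The continuum solution is
    ``c(r) = A + B/r``; this is the discrete analogue used for convergence
    checks.
    """
    n = domain.n
    if n < 3:
        raise ValueError("need at least 3 control volumes")
    rows = sparse.lil_matrix((n, n))
    rhs = np.zeros(n)
    g = d_coef * domain.areas[1:-1] / np.diff(domain.centers)
    for j in range(n):
        if j > 0:
            rows[j, j - 1] += g[j - 1]
            rows[j, j] -= g[j - 1]
        if j < n - 1:
            rows[j, j + 1] += g[j]
            rows[j, j] -= g[j]
    # boundary faces: flux = -D A c'(face), c' from the one-sided quadratic
    # through the face value and the two nearest cell centers (2nd order)
    def face_gradient_weights(x1: float, x2: float) -> tuple[float, float, float]:
        # c'(0) = wb c_face + w1 c(x1) + w2 c(x2)
        wb = -(x1 + x2) / (x1 * x2)
        w1 = x2 / (x1 * (x2 - x1))
        w2 = -x1 / (x2 * (x2 - x1))
        return wb, w1, w2

    x1 = domain.centers[0] - domain.faces[0]
    x2 = domain.centers[1] - domain.faces[0]
    wb, w1, w2 = face_gradient_weights(x1, x2)
    a_in = d_coef * domain.areas[0]  # net inflow into cell 0 = -D A c'(face)
    rows[0, 0] += -a_in * w1
    rows[0, 1] += -a_in * w2
    rhs[0] += a_in * wb * c_inner
    x1 = domain.faces[-1] - domain.centers[-1]
    x2 = domain.faces[-1] - domain.centers[-2]
    wb, w1, w2 = face_gradient_weights(x1, x2)
    a_out = d_coef * domain.areas[-1]  # net inflow = +D A c'(face), outward x
    # measured inward from the face, the gradient flips sign
    rows[n - 1, n - 1] += -a_out * w1
    rows[n - 1, n - 2] += -a_out * w2
    rhs[n - 1] += a_out * wb * c_outer
    return spsolve(rows.tocsr(), rhs)
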