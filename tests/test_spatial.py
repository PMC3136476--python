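import math
from dataclasses import replace

import numpy as np
import pytest

import rdtraffic as rdt
from rdtraffic.mesh import build_mesh
from rdtraffic.spatial import (
    SpatialProblem,
    apply_diffusion,
    mass_balance,
    steady_dirichlet_profile,
)

from conftest import COARSE, MEDIUM, binding_equilibrium_amounts


def make_problem(params, diffusion, geometry, program=None, resolution=COARSE):
    return SpatialProblem(params, diffusion, geometry, program=program,
                          resolution=resolution)


class TestRhs:
    def test_all_rates_zero_uniform_fields_static(self, inert_params,
                                                  default_diffusion,
                                                  default_geometry):
        prob = make_problem(inert_params, default_diffusion, default_geometry)
        y = prob.initial_state(rdt.InitialConditions(
            l0=3.0, rs0=650.0, ri0=450.0, lrs0=5.0, lri0=7.0))
        y[prob.slices["LS"]] = 3.0  # match ligand across the R2 interface
        dy = prob.rhs(0.0, y)
        np.testing.assert_allclose(dy, 0.0, atol=1e-12)

    def test_mass_action_at_every_shell_node(self, binding_free_params,
                                             default_diffusion,
                                             default_geometry):
        p = replace(binding_free_params, k_off=0.0)
        prob = make_problem(p, default_diffusion, default_geometry)
        y = np.zeros(prob.n_state)
        y[prob.slices["LS"]] = 1.0
        y[prob.slices["RS"]] = 1.0
        dy = prob.rhs(0.0, y)
        np.testing.assert_allclose(
            dy[prob.slices["LRS"]], p.k_on * 1.0 * 1.0, rtol=1e-12)
        # LS also exchanges with L at R2, so only check its interior nodes
        np.testing.assert_allclose(
            dy[prob.slices["RS"]][:-1][:-1], -p.k_on, rtol=1e-12)

    def test_nonfinite_state_aborts(self, default_params, default_diffusion,
                                    default_geometry):
        prob = make_problem(default_params, default_diffusion,
                            default_geometry)
        y = np.zeros(prob.n_state)
        y[0] = np.nan
        with pytest.raises(FloatingPointError):
            prob.rhs(0.0, y)


class TestDiffusionOperator:
    """The 1/r steady solution is the analytic oracle for spherical
    diffusion between two fixed-concentration faces."""

    @staticmethod
    def analytic(dom, c_in, c_out):
        r_in, r_out = dom.faces[0], dom.faces[-1]
        b = (c_in - c_out) / (1.0 / r_in - 1.0 / r_out)
        a = c_out - b / r_out
        return a + b / dom.centers

    def solved_error(self, n):
        g = rdt.Geometry(r_outer=100.0)
        dom = build_mesh(g, (4, 4, n), grade_ext=False).ext
        c = steady_dirichlet_profile(dom, 100.0, 5.0, 1.0)
        exact = self.analytic(dom, 5.0, 1.0)
        return float(np.max(np.abs(c - exact) / np.abs(exact)))

    def test_steady_profile_matches_analytic(self):
        assert self.solved_error(120) < 1e-3

    def test_convergence_order_at_least_1_9(self):
        e1, e2 = self.solved_error(40), self.solved_error(80)
        assert math.log2(e1 / e2) >= 1.9

    def test_rhs_residual_shrinks_under_refinement(self):
        g = rdt.Geometry(r_outer=100.0)

        def resid(n):
            dom = build_mesh(g, (4, 4, n), grade_ext=False).ext
            r_in, r_out = dom.faces[0], dom.faces[-1]
            b = 4.0 / (1.0 / r_in - 1.0 / r_out)
            c = 1.0 - b / r_out + b / dom.centers
            flux = 4.0 * math.pi * 100.0 * b  # exact area-integrated flux
            res = apply_diffusion(dom, 100.0, c, flux_inner=flux,
                                  flux_outer=flux)
            return float(np.max(np.abs(res[1:-1])))

        r1, r2 = resid(160), resid(320)
        assert r2 < r1 / 2.5


class TestSimulate:
    def test_everything_off_stays_constant(self, inert_params,
                                           default_diffusion,
                                           default_geometry):
        ic = rdt.InitialConditions(l0=2.0, rs0=650.0, ri0=450.0)
        res = rdt.simulate(inert_params, default_diffusion, default_geometry,
                          ic, t_eval=np.linspace(0, 600, 5),
                          resolution=COARSE)
        # ligand partitions into the initially empty shell (LS); receptors
        # do not move at all
        for sp, v0 in (("RS", 650.0), ("RI", 450.0), ("LRS", 0.0),
                       ("LRI", 0.0)):
            np.testing.assert_allclose(res.fields[sp], v0, atol=1e-7)

    def test_binding_equilibrium_matches_quadratic(self, binding_free_params,
                                                   default_diffusion):
        g = rdt.Geometry(r_outer=20.0)
        ic = rdt.InitialConditions(rs0=650.0, ri0=0.0)
        prog = rdt.LigandInputProgram.bolus(100.0)
        res = rdt.simulate(binding_free_params, default_diffusion, g, ic,
                          prog, np.linspace(0, 20000, 21), resolution=COARSE)
        ls = res.fields["LS"][-1].mean()
        rs = res.fields["RS"][-1].mean()
        lrs = res.fields["LRS"][-1].mean()
        kd = binding_free_params.k_off / binding_free_params.k_on
        assert ls * rs / lrs == pytest.approx(kd, rel=5e-3)
        l_eq, rs_eq, lrs_eq = binding_equilibrium_amounts(
            100.0 * g.v_ext, 650.0 * g.v_shell, g.v_ext + g.v_shell, g.v_shell,
            kd)
        assert res.fields["L"][-1].mean() == pytest.approx(l_eq, rel=1e-3)
        assert lrs == pytest.approx(lrs_eq, rel=1e-3)

    def test_saturating_bolus_internalization_plateaus(self, default_geometry,
                                                       default_diffusion):
        """With recycling/degradation/synthesis off, every surface receptor
        ends up internalized: LRI -> 26.3 nM, RI+LRI -> 476.3 nM."""
        p = rdt.KineticParameters(
            q_syn=0.0, k_int_free=0.0, k_int_bound=1e-3, k_rec_free=0.0,
            k_rec_bound=0.0, k_deg_free=0.0, k_deg_bound=0.0)
        prog = rdt.LigandInputProgram.bolus(1e4)
        res = rdt.simulate(p, default_diffusion, default_geometry,
                          rdt.InitialConditions(), prog,
                          np.linspace(0, 36000, 11), resolution=COARSE)
        lri = float(np.mean(res.fields["LRI"][-1]))
        ri = float(np.mean(res.fields["RI"][-1]))
        assert lri == pytest.approx(
            rdt.shell_to_cell_concentration(650.0, default_geometry), rel=0.01)
        assert lri == pytest.approx(26.3, rel=0.01)
        assert ri + lri == pytest.approx(476.3, rel=0.01)

    def test_positivity(self, default_params, default_diffusion,
                        default_geometry):
        res = rdt.simulate(default_params, default_diffusion,
                          default_geometry, rdt.InitialConditions(),
                          rdt.LigandInputProgram.bolus(1.0),
                          np.linspace(0, 36000, 61), resolution=COARSE)
        min_c = min(res.fields[s].min() for s in res.fields)
        assert min_c >= -1e-9

    def test_invalid_t_eval(self, default_params, default_diffusion,
                            default_geometry):
        with pytest.raises(ValueError):
            rdt.simulate(default_params, default_diffusion, default_geometry,
                        rdt.InitialConditions(), t_eval=np.array([0.0, 0.0]))


class TestMassBalance:
    def test_closed_system_conserves(self, binding_free_params,
                                     default_diffusion, default_geometry):
        p = replace(binding_free_params, k_int_free=1e-3, k_int_bound=1e-3,
                    k_rec_free=2.5e-3, k_rec_bound=2.5e-3)
        res = rdt.simulate(p, default_diffusion, default_geometry,
                          rdt.InitialConditions(),
                          rdt.LigandInputProgram.bolus(10.0),
                          np.linspace(0, 36000, 37), resolution=COARSE)
        assert mass_balance(res).max_relative_residual < 1e-6

    def test_synthesis_only_linear_growth(self, inert_params,
                                          default_diffusion,
                                          default_geometry):
        p = replace(inert_params, q_syn=0.01)
        t_end = 5000.0
        res = rdt.simulate(p, default_diffusion, default_geometry,
                          rdt.InitialConditions(l0=0, rs0=0, ri0=0),
                          t_eval=np.linspace(0, t_end, 6), resolution=COARSE)
        m = res.mesh
        total = (res.fields["RS"][-1] @ m.shell.volumes
                 + res.fields["RI"][-1] @ m.cell.volumes)
        expected = p.q_syn * default_geometry.a_cell * t_end
        assert total == pytest.approx(expected, rel=1e-6)
        assert res.ledger["synthesized_receptor"][-1] == pytest.approx(
            expected, rel=1e-9)

    def test_pulse_ledger_matches_cumulative_input(self, inert_params,
                                                   default_diffusion,
                                                   default_geometry):
        prog = rdt.LigandInputProgram.pulse_train(
            1.0, [(0.0, 10.0), (50.0, 10.0)])
        res = rdt.simulate(inert_params, default_diffusion, default_geometry,
                          rdt.InitialConditions(rs0=0, ri0=0), prog,
                          np.linspace(0, 100, 11), resolution=COARSE)
        v_ext = res.mesh.ext.volumes.sum()
        expected = rdt.cumulative_input(prog, 100.0) * v_ext
        assert res.ledger["injected_ligand"][-1] == pytest.approx(
            expected, rel=1e-9)

    def test_degradation_routes_to_ledger(self, default_params,
                                          default_diffusion,
                                          default_geometry):
        res = rdt.simulate(default_params, default_diffusion,
                          default_geometry, rdt.InitialConditions(),
                          rdt.LigandInputProgram.bolus(10.0),
                          np.linspace(0, 7200, 13), resolution=COARSE)
        for name in ("degraded_receptor", "degraded_ligand"):
            assert np.all(np.diff(res.ledger[name]) >= -1e-12)
        assert res.ledger["degraded_receptor"][-1] > 0
        assert mass_balance(res).max_relative_residual < 1e-6


class TestWellMixedLimit:
    def test_fast_diffusion_matches_ode(self, default_params, default_initial,
                                        default_geometry):
        """Multiplying all diffusion coefficients by 1e3 collapses spatial
        gradients; volume-averaged trajectories then match the well-mixed
        comparator with converted parameters within 2% sup-norm."""
        base = rdt.DiffusionCoefficients()
        d_fast = rdt.DiffusionCoefficients(
            **{k: getattr(base, k) * 1e3 for k in (
                "d_ligand_ext", "d_free_surface", "d_complex_surface",
                "d_free_cell", "d_complex_cell")})
        prog = rdt.LigandInputProgram.bolus(100.0)
        t_eval = np.linspace(0.0, 7200.0, 81)
        g = default_geometry
        res = rdt.simulate(default_params, d_fast, g, default_initial, prog,
                          t_eval, resolution=MEDIUM)
        wm = rdt.simulate_wellmixed(
            rdt.spatial_to_wellmixed_params(default_params, g),
            rdt.wellmixed_initial_from_spatial(default_initial, g),
            prog, t_eval)
        scale = g.v_cell / g.v_shell
        for sp, fac in (("L", 1.0), ("RS", 1.0), ("LRS", 1.0),
                        ("RI", scale), ("LRI", scale)):
            avg = rdt.volume_average(res, sp) * fac
            ref = wm.series[sp]
            err = np.max(np.abs(avg - ref)) / max(np.max(np.abs(ref)), 1e-30)
            assert err < 0.02, f"{sp}: {err:.3%}"
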