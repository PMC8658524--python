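"""Projection solver: grids, divergence, stability, duct verification, transients."""

import numpy as np
import pytest

import pvlsim as pv
from pvlsim.grid import build_grid, make_box_domain
from pvlsim.oracles import slit_poiseuille
from pvlsim.solver import (
    BoundarySet,
    MassFluxInlet,
    PressureBoundary,
    SolverConfig,
    courant_number,
    divergence,
    solve_steady,
    step_transient,
    transient_systole_run,
)

PROPS = pv.FluidProperties()


def _poiseuille_setup(n, h=1e-3, L=8e-3, u_mean=0.0325, mode="planar"):
    ny = max(8, int(n * L / h / 4))
    dom = make_box_domain(n, ny, h, L, mode=mode)
    if mode == "axisymmetric":
        mdot = PROPS.rho * u_mean * np.pi * h**2
    else:
        mdot = PROPS.rho * u_mean * h
    bcs = BoundarySet(inlet=MassFluxInlet(mdot), la_outlet=PressureBoundary(0.0))
    cfg = SolverConfig(turbulence="laminar", tol=1e-6, max_iters=60000, ramp_steps=30)
    return dom, bcs, cfg


class TestGrid:
    def test_unit_square_cells(self):
        g = build_grid(make_box_domain(10, 10, 1.0, 1.0))
        assert g.vol.shape == (10, 10)
        assert np.allclose(g.vol, 0.01)

    def test_axisymmetric_volumes_scale_with_radius(self):
        g = build_grid(make_box_domain(8, 4, 1.0, 1.0, mode="axisymmetric"))
        ratio = g.vol[:, 0] / g.xc
        assert np.allclose(ratio, ratio[0])

    def test_degenerate_domain_rejected(self):
        with pytest.raises(ValueError):
            make_box_domain(0, 4, 1.0, 1.0)
        dom = make_box_domain(4, 4, 1.0, 1.0)
        dom.fluid[:] = False
        with pytest.raises(ValueError):
            build_grid(dom)


class TestDivergence:
    def _field(self, fu, fv, n=12):
        g = build_grid(make_box_domain(n, n, 1.0, 1.0))
        f = g.zero_field()
        XF, YC = np.meshgrid(g.xf, g.yc, indexing="ij")
        f.u = fu(XF, YC)
        yf = g.dy * np.arange(n + 1)
        XC, YF = np.meshgrid(g.xc, yf, indexing="ij")
        f.v = fv(XC, YF)
        return f

    def test_uniform_flow_is_solenoidal(self):
        f = self._field(lambda x, y: 1.0 + 0 * x, lambda x, y: 2.0 + 0 * x)
        assert np.allclose(divergence(f), 0.0, atol=1e-12)

    def test_shear_free_saddle_is_solenoidal(self):
        f = self._field(lambda x, y: x, lambda x, y: -y)
        assert np.allclose(divergence(f), 0.0, atol=1e-10)

    def test_linear_expansion_has_divergence_two(self):
        f = self._field(lambda x, y: x, lambda x, y: y)
        assert np.allclose(divergence(f), 2.0, rtol=1e-10)


class TestCourant:
    def test_definition(self):
        g = build_grid(make_box_domain(10, 10, 0.01, 0.01))  # dx = 1 mm
        f = g.zero_field()
        f.u[:] = 1.0
        assert courant_number(f, 1e-3) == pytest.approx(1.0)
        assert courant_number(f, 2e-3) == pytest.approx(2.0)
        assert courant_number(g.zero_field(), 1e-3) == 0.0


class TestStepTransient:
    def test_zero_flow_is_a_fixed_point(self):
        dom = make_box_domain(8, 8, 1e-3, 1e-3)
        g = build_grid(dom)
        bcs = BoundarySet(inlet=MassFluxInlet(0.0), la_outlet=PressureBoundary(0.0))
        cfg = SolverConfig(turbulence="laminar")
        f = g.zero_field()
        out = step_transient(f, bcs, cfg, PROPS, dt=1e-5)
        assert np.allclose(out.u, 0.0) and np.allclose(out.v, 0.0)

    def test_projection_makes_field_divergence_free(self):
        dom = make_box_domain(12, 20, 1e-3, 3e-3)
        g = build_grid(dom)
        bcs = BoundarySet(inlet=MassFluxInlet(1e-4), la_outlet=PressureBoundary(0.0))
        cfg = SolverConfig(turbulence="laminar")
        f = g.zero_field()
        for _ in range(5):
            f = step_transient(f, bcs, cfg, PROPS, dt=2e-5)
        u_scale = max(np.max(np.abs(f.v)), 1e-12)
        scaled_div = np.max(np.abs(divergence(f))) * g.dy / u_scale
        assert scaled_div < 1e-8


class TestPoiseuille:
    def test_plane_profile_and_wall_shear(self):
        u_mean, h = 0.0325, 1e-3
        dom, bcs, cfg = _poiseuille_setup(32)
        f, info = solve_steady(dom, bcs, cfg, PROPS)
        assert info.converged
        g = f.grid
        vc = 0.5 * (f.v[:, :-1] + f.v[:, 1:])
        ana = slit_poiseuille(u_mean, h, PROPS.mu)
        exact = ana.profile(g.xc - h / 2)
        assert np.max(np.abs(vc[:, g.ny // 2] - exact)) / ana.u_center < 0.01
        ws = pv.wall_shear_stress(f, PROPS)
        mid = np.abs(ws.y - 4e-3) < dom.dy
        assert ws.tau[mid] == pytest.approx(ana.tau_wall, rel=0.01)

    def test_axisymmetric_pipe_centerline_ratio(self):
        u_mean = 0.032
        dom, bcs, cfg = _poiseuille_setup(32, h=0.5e-3, L=8e-3, u_mean=u_mean,
                                          mode="axisymmetric")
        f, info = solve_steady(dom, bcs, cfg, PROPS)
        assert info.converged
        g = f.grid
        vc = 0.5 * (f.v[:, :-1] + f.v[:, 1:])
        prof = vc[:, g.ny // 2]
        u_cl = prof[0] + 0.25 * (prof[0] - prof[1])  # parabolic extrapolation to r=0
        assert u_cl / u_mean == pytest.approx(2.0, rel=0.01)

    def test_global_mass_conservation(self):
        dom, bcs, cfg = _poiseuille_setup(16)
        f, info = solve_steady(dom, bcs, cfg, PROPS)
        g = f.grid
        inflow = float(np.sum(g.Ay[:, 0] * f.v[:, 0]))
        outflow = float(np.sum(g.Ay[:, -1] * f.v[:, -1]))
        assert abs(inflow - outflow) / inflow < 1e-10
        assert inflow == pytest.approx(bcs.inlet.mdot / PROPS.rho, rel=1e-12)

    def test_second_order_spatial_convergence(self):
        errs = []
        for n in (8, 16, 32):
            dom, bcs, cfg = _poiseuille_setup(n, L=6e-3)
            cfg.tol = 1e-7
            f, info = solve_steady(dom, bcs, cfg, PROPS)
            g = f.grid
            vc = 0.5 * (f.v[:, :-1] + f.v[:, 1:])
            ana = slit_poiseuille(0.0325, 1e-3, PROPS.mu)
            exact = ana.profile(g.xc - 1e-3 / 2)
            errs.append(
                np.sqrt(np.mean((vc[:, 2 * g.ny // 3] - exact) ** 2)) / ana.u_center
            )
        order = np.log2(errs[0] / errs[2]) / 2
        assert 1.7 < order < 2.3

    def test_steady_solve_is_deterministic(self):
        dom, bcs, cfg = _poiseuille_setup(8)
        f1, _ = solve_steady(dom, bcs, cfg, PROPS, seed=3)
        f2, _ = solve_steady(dom, bcs, cfg, PROPS, seed=3)
        assert np.array_equal(f1.u, f2.u)
        assert np.array_equal(f1.v, f2.v)
        assert np.array_equal(f1.p, f2.p)


class TestTransientSystole:
    @pytest.fixture(scope="class")
    def run(self):
        spec = pv.pvl_preset("PVL I")
        dom = pv.rasterize_channel_domain(spec, resolution=0.25)
        cfg = SolverConfig(turbulence="laminar", dt=1e-3)
        profile = pv.FlowProfile()
        return transient_systole_run(dom, profile, cfg=cfg, props=PROPS), profile

    def test_seven_snapshots_at_reference_times(self, run):
        res, _ = run
        assert len(res.snapshots) == 7
        assert [s.t for s in res.snapshots] == pytest.approx(
            [0.71, 0.73, 0.75, 0.78, 0.84, 0.88, 0.92]
        )

    def test_injected_mass_matches_profile_quadrature(self, run):
        res, profile = run
        from pvlsim.cardiac import solve_flow_split

        t = np.linspace(0.68, 0.98, 3001)
        mdot = np.array(
            [
                solve_flow_split(profile.flow_rate(ti) * 1e-6, pv.pvl_preset("PVL I")).q_pvl
                * PROPS.rho
                for ti in t
            ]
        )
        expected = np.trapezoid(mdot, t)
        assert res.mass_in_total == pytest.approx(expected, rel=5e-3)

    def test_acceleration_stress_exceeds_deceleration_at_matched_flow(self, run):
        res, _ = run
        by_t = {round(s.t, 2): s for s in res.snapshots}
        tau_acc = pv.wall_shear_stress(by_t[0.71].field, PROPS).max()
        tau_dec = pv.wall_shear_stress(by_t[0.92].field, PROPS).max()
        assert tau_acc >= 0.98 * tau_dec
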