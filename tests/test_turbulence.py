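"""SST closure: limiter evaluations, strain kinematics, transport, wall distance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pvlsim as pv
from pvlsim import turbulence as turb
from pvlsim.grid import build_grid, make_box_domain


def _uniform_field(nx=8, ny=8, lx=1.0, ly=1.0, mode="planar"):
    grid = build_grid(make_box_domain(nx, ny, lx, ly, mode=mode))
    return grid.zero_field()


def _field_from_functions(fu, fv, nx=16, ny=16, lx=1.0, ly=1.0):
    grid = build_grid(make_box_domain(nx, ny, lx, ly))
    f = grid.zero_field()
    XF, YC = np.meshgrid(grid.xf, grid.yc, indexing="ij")
    f.u = fu(XF, YC)
    XC, YF = np.meshgrid(grid.xc, np.r_[0.0, grid.yc + grid.dy / 2][: ny + 1], indexing="ij")
    yf = grid.dy * np.arange(ny + 1)
    XC, YF = np.meshgrid(grid.xc, yf, indexing="ij")
    f.v = fv(XC, YF)
    return f


class TestStrainRate:
    def test_rigid_rotation_has_zero_strain(self):
        f = _field_from_functions(lambda x, y: -y, lambda x, y: x)
        S = turb.strain_rate(f).magnitude
        interior = S[2:-2, 2:-2]
        assert np.allclose(interior, 0.0, atol=1e-10)

    def test_simple_shear_recovers_gamma(self):
        gamma = 7.5
        f = _field_from_functions(lambda x, y: gamma * y, lambda x, y: 0.0 * x)
        S = turb.strain_rate(f).magnitude
        assert np.allclose(S[2:-2, 2:-2], gamma, rtol=1e-9)

    def test_planar_stretch(self):
        f = _field_from_functions(lambda x, y: x, lambda x, y: -y)
        S = turb.strain_rate(f).magnitude
        assert np.allclose(S[2:-2, 2:-2], 2.0, rtol=1e-9)


class TestPhi:
    def test_hand_computed_maximum(self):
        val = turb.phi(1.0, 100.0, 0.01, 3.2547e-6)
        assert float(val) == pytest.approx(22.222, abs=1e-3)
        # second term alone: 500*nu/(y^2*omega)
        assert float(turb.phi(0.0, 100.0, 0.01, 3.2547e-6)) == pytest.approx(
            500 * 3.2547e-6 / (1e-4 * 100), rel=1e-9
        )

    def test_term_crossover_in_wall_distance(self):
        # first term ~ 1/y dominates until the 1/y^2 viscous term takes over
        k, om, nu = 1.0, 100.0, 3.2547e-6
        y_cross = 500 * nu / (om * 0.01) * (0.09 * om) / (2 * np.sqrt(k)) * (1 / 1)
        big_y = float(turb.phi(k, om, 1.0, nu))
        assert big_y == pytest.approx(2 * np.sqrt(k) / (0.09 * om * 1.0), rel=1e-9)
        tiny = float(turb.phi(k, om, 1e-7, nu))
        assert tiny == pytest.approx(500 * nu / (1e-14 * om), rel=1e-6)

    def test_wall_limit_is_infinite(self):
        assert np.isinf(float(turb.phi(1.0, 100.0, 0.0, 3.2547e-6)))


class TestEddyViscosity:
    def test_hand_computed_branches(self):
        props = pv.FluidProperties()
        # tanh(phi^2) ~ 1 at these arguments; limiter picks k/omega
        mu_t = turb.eddy_viscosity(0.1, 1000.0, 100.0, 0.01, props)
        assert float(mu_t) == pytest.approx(1060 * 1e-4, rel=1e-3)

    def test_vanishing_k(self):
        assert float(turb.eddy_viscosity(0.0, 100.0, 10.0, 0.01)) == 0.0

    def test_weak_strain_disables_limiter(self):
        props = pv.FluidProperties()
        mu_t = turb.eddy_viscosity(0.05, 500.0, 1e-12, 0.01, props)
        assert float(mu_t) == pytest.approx(props.rho * 0.05 / 500.0, rel=1e-9)

    @given(
        st.floats(1e-10, 10.0),
        st.floats(1e-3, 1e5),
        st.floats(0.0, 1e5),
        st.floats(1e-6, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_limiter_never_exceeds_k_over_omega(self, k, om, S, y):
        props = pv.FluidProperties()
        mu_t = float(turb.eddy_viscosity(k, om, S, y, props))
        assert mu_t <= props.rho * k / om * (1 + 1e-12)
        assert mu_t >= 0.0


class TestTransport:
    def test_homogeneous_decay_matches_ode_closed_form(self):
        """dk/dt = -beta* k w, dw/dt = -beta2 w^2 for a uniform wall-free state."""
        props = pv.FluidProperties()
        f = _uniform_field(6, 6, 1.0, 1.0)
        k0, w0 = 2.0, 100.0
        y = np.full((6, 6), 1e3)  # far from any wall: outer (k-eps) branch
        state = turb.TurbulenceState(k=np.full((6, 6), k0), omega=np.full((6, 6), w0), y=y)
        n, dt = 100, 3.6e-4
        for _ in range(n):
            state = turb.transport_step(state, f, dt, props)
        t = n * dt
        beta2 = turb.SET2[2]
        w_exact = w0 / (1 + beta2 * w0 * t)
        k_exact = k0 * (1 + beta2 * w0 * t) ** (-turb.BETA_STAR / beta2)
        assert state.omega[3, 3] == pytest.approx(w_exact, rel=5e-3)
        assert state.k[3, 3] == pytest.approx(k_exact, rel=5e-3)

    def test_zero_dt_is_identity(self):
        f = _uniform_field()
        state = turb.TurbulenceState(
            k=np.full((8, 8), 0.3), omega=np.full((8, 8), 50.0), y=np.full((8, 8), 1.0)
        )
        out = turb.transport_step(state, f, 0.0)
        assert np.array_equal(out.k, state.k)
        assert np.array_equal(out.omega, state.omega)

    def test_positivity_floors_hold_under_large_steps(self):
        f = _uniform_field()
        state = turb.TurbulenceState(
            k=np.full((8, 8), 1e-9), omega=np.full((8, 8), 1e4), y=np.full((8, 8), 1e-4)
        )
        for _ in range(5):
            state = turb.transport_step(state, f, 10.0)
        assert np.all(state.k >= turb.K_FLOOR)
        assert np.all(state.omega >= turb.OMEGA_FLOOR)


class TestWallDistance:
    def test_channel_midpoint_and_wall_adjacent(self):
        h, n = 1e-3, 16
        dom = make_box_domain(n, 8, h, 4e-3)  # lateral walls at x=0, x=h
        y = turb.wall_distance(dom)
        assert y[0, 4] == pytest.approx(dom.dx / 2, rel=1e-9)
        mid = n // 2
        assert y[mid, 4] == pytest.approx(h / 2, rel=0.1)
        assert abs(y[mid - 1, 4] - (h / 2 - dom.dx / 2)) < 1e-9

    def test_discrete_eikonal_bound(self):
        dom = pv.rasterize_channel_domain(pv.pvl_preset("PVL IV"))
        y = turb.wall_distance(dom)
        gx = np.abs(np.diff(y, axis=0)) / dom.dx
        gy = np.abs(np.diff(y, axis=1)) / dom.dy
        assert gx.max() <= 1.0 + 1e-6
        assert gy.max() <= 1.0 + 1e-6

    def test_no_walls_is_an_error(self):
        dom = make_box_domain(
            4, 4, 1.0, 1.0,
            edge_tags={"xmin": "inlet", "xmax": "inlet", "ymin": "inlet", "ymax": "inlet"},
        )
        with pytest.raises(ValueError):
            turb.wall_distance(dom)
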