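"""Hemolysis metrics: shear fields, exceedance, residence time, velocity stats."""

import dataclasses

import numpy as np
import pytest

import pvlsim as pv
from pvlsim.grid import build_grid, make_box_domain
from pvlsim.metrics import channel_mass_flow

PROPS = pv.FluidProperties()


def _shear_field(gamma, n=12):
    """Laminar simple shear u = gamma*y on an open box."""
    dom = make_box_domain(n, n, 1e-3, 1e-3)
    g = build_grid(dom)
    f = g.zero_field()
    XF, YC = np.meshgrid(g.xf, g.yc, indexing="ij")
    f.u = gamma * YC
    return dom, f


class TestShearStressField:
    def test_critical_shear_rate_hits_300_pa(self):
        # gamma = 300 Pa / mu: the threshold-critical laminar shear rate
        gamma = 300.0 / PROPS.mu
        dom, f = _shear_field(gamma)
        sf = pv.shear_stress_field(f, props=PROPS)
        assert np.allclose(sf.tau[2:-2, 2:-2], 300.0, rtol=1e-9)

    def test_zero_velocity_zero_stress(self):
        dom, f = _shear_field(0.0)
        assert pv.shear_stress_field(f, props=PROPS).max() == 0.0

    def test_effective_viscosity_linearity(self):
        dom, f = _shear_field(100.0)
        base = pv.shear_stress_field(f, props=PROPS)
        mu_t = np.full((dom.nx, dom.ny), PROPS.mu)  # doubles mu_eff
        doubled = pv.shear_stress_field(f, mu_t=mu_t, props=PROPS)
        assert np.allclose(doubled.tau, 2 * base.tau)


class TestWallShear:
    def _parabolic_channel(self, u_mean, h=1e-3, n=16):
        dom = make_box_domain(n, 12, h, 3e-3)  # lateral walls
        g = build_grid(dom)
        f = g.zero_field()
        from pvlsim.oracles import slit_poiseuille

        ana = slit_poiseuille(u_mean, h, PROPS.mu)
        yf = g.dy * np.arange(13)
        XC, YF = np.meshgrid(g.xc, yf, indexing="ij")
        f.v = ana.profile(XC - h / 2)
        return dom, f, ana

    def test_plane_poiseuille_wall_shear_exact(self):
        dom, f, ana = self._parabolic_channel(3.0)
        ws = pv.wall_shear_stress(f, PROPS)
        assert ana.tau_wall == pytest.approx(62.1, rel=1e-6)
        assert np.allclose(ws.tau, ana.tau_wall, rtol=1e-9)

    def test_hagen_poiseuille_pipe_wall_shear(self):
        a, u_mean = 0.5e-3, 2.0
        dom = make_box_domain(16, 12, a, 3e-3, mode="axisymmetric")
        g = build_grid(dom)
        f = g.zero_field()
        yf = g.dy * np.arange(13)
        XC, YF = np.meshgrid(g.xc, yf, indexing="ij")
        f.v = 2 * u_mean * (1 - (XC / a) ** 2)
        ws = pv.wall_shear_stress(f, PROPS)
        assert np.allclose(ws.tau, 8 * PROPS.mu * u_mean / (2 * a), rtol=1e-9)

    def test_stationary_fluid(self):
        dom, f, _ = self._parabolic_channel(0.0)
        assert pv.wall_shear_stress(f, PROPS).max() == 0.0


class TestExceedance:
    @pytest.fixture()
    def lumen_setup(self):
        spec = pv.pvl_preset("PVL I")
        dom = pv.rasterize_channel_domain(spec, resolution=0.2)
        g = build_grid(dom)
        f = g.zero_field()
        return spec, dom, f

    def test_uniform_above_threshold_counts_whole_lumen(self, lumen_setup):
        spec, dom, f = lumen_setup
        sf = pv.shear_stress_field(f, props=PROPS)
        sf.tau = np.full_like(sf.tau, 400.0)
        assert pv.exceedance_volume(sf, dom) == pytest.approx(dom.lumen_volume())

    def test_uniform_below_threshold_counts_nothing(self, lumen_setup):
        spec, dom, f = lumen_setup
        sf = pv.shear_stress_field(f, props=PROPS)
        sf.tau = np.full_like(sf.tau, 100.0)
        assert pv.exceedance_volume(sf, dom) == 0.0

    def test_half_lumen_by_construction(self, lumen_setup):
        spec, dom, f = lumen_setup
        sf = pv.shear_stress_field(f, props=PROPS)
        sf.tau = np.zeros_like(sf.tau)
        # mark the lower half of the channel band
        y_mid = 0.5 * (dom.y_channel0 + dom.y_channel1)
        YC = np.broadcast_to(dom.yc, (dom.nx, dom.ny))
        lower = dom.lumen & (YC < y_mid)
        sf.tau[lower] = 500.0
        vols = dom.cell_volumes()
        expected = float(np.sum(vols[lower]))
        assert pv.exceedance_volume(sf, dom) == pytest.approx(expected)

    def test_threshold_sweep_monotone(self, lumen_setup):
        spec, dom, f = lumen_setup
        rng = np.random.default_rng(0)
        sf = pv.shear_stress_field(f, props=PROPS)
        sf.tau = rng.uniform(0, 1000, sf.tau.shape)
        vols = [pv.exceedance_volume(sf, dom, th) for th in (150, 300, 400, 600, 800)]
        assert all(a >= b for a, b in zip(vols, vols[1:]))


class TestFractionAndResidence:
    def test_fraction_arithmetic(self):
        spec = pv.PVLChannelSpec(family="oval", csa_mm2=7.9, fillet_mm=0.0, aspect=3.0)
        assert pv.exceedance_fraction(11.85e-9, spec) == pytest.approx(0.5, rel=1e-9)
        assert pv.exceedance_fraction(0.0, spec) == 0.0
        vpvl = pv.channel_volume(spec) * 1e-9
        assert pv.exceedance_fraction(vpvl, spec) == pytest.approx(1.0)
        assert pv.exceedance_fraction(2 * vpvl, spec) == 1.0  # clipped

    def test_residence_time_identity(self):
        assert pv.residence_time(1e-8, PROPS, 0.1) == pytest.approx(1.06e-4, rel=1e-12)
        assert pv.residence_time(0.0, PROPS, 0.1) == 0.0
        assert pv.residence_time(1e-8, PROPS, 0.05) == pytest.approx(2 * 1.06e-4, rel=1e-12)
        with pytest.raises(ValueError):
            pv.residence_time(1e-8, PROPS, 0.0)

    def test_backflow_ratio(self):
        assert pv.backflow_ratio(0.05, 0.439) == pytest.approx(0.05 / 0.439)
        assert pv.backflow_ratio(0.0, 0.1) == 0.0
        assert pv.backflow_ratio(0.2, 0.2) == 1.0
        with pytest.raises(ValueError):
            pv.backflow_ratio(0.3, 0.2)


class TestVelocityStats:
    def test_plug_flow(self):
        spec = pv.pvl_preset("PVL I")
        dom = pv.rasterize_channel_domain(spec, resolution=0.2)
        g = build_grid(dom)
        f = g.zero_field()
        f.v[:, :] = 2.5
        u_cp, u_avg = pv.channel_velocity_stats(f, dom)
        assert u_cp == pytest.approx(2.5, rel=1e-9)
        assert u_avg == pytest.approx(2.5, rel=1e-9)
        assert channel_mass_flow(f, dom, PROPS) > 0

    def test_zero_flow(self):
        spec = pv.pvl_preset("PVL IV")
        dom = pv.rasterize_channel_domain(spec, resolution=0.1)
        f = build_grid(dom).zero_field()
        assert pv.channel_velocity_stats(f, dom) == (0.0, 0.0)

    def test_slit_centerline_to_average_ratio(self):
        # fully developed laminar slit: centre = 1.5 x mean (2D volume average)
        from pvlsim.oracles import slit_poiseuille

        spec = pv.PVLChannelSpec(family="slit", csa_mm2=2.0, aspect=8.0, fillet_mm=0.0)
        dom = pv.rasterize_channel_domain(spec, resolution=0.02)
        g = build_grid(dom)
        f = g.zero_field()
        gap = spec.cross_section().gap_mm * 1e-3
        ana = slit_poiseuille(1.0, gap, PROPS.mu)
        yf = g.dy * np.arange(g.ny + 1)
        XC, YF = np.meshgrid(g.xc, yf, indexing="ij")
        prof = np.where(np.abs(XC) < gap / 2, ana.profile(XC), 0.0)
        f.v = prof
        u_cp, u_avg = pv.channel_velocity_stats(f, dom)
        assert u_cp == pytest.approx(1.5, rel=5e-3)  # centre sampled half a cell off-axis
        assert u_cp / u_avg == pytest.approx(1.5, rel=2e-2)


class TestRiskReport:
    def test_identity_and_sweep(self):
        spec = pv.pvl_preset("PVL II")
        dom = pv.rasterize_channel_domain(spec, resolution=0.05)
        g = build_grid(dom)
        f = g.zero_field()
        f.v[:, :] = 3.0  # plug flow through everything
        rep = pv.risk_report(
            label="synthetic", spec=spec, domain=dom, field=f, props=PROPS,
            mdot_in=0.09, sweep=(150, 300, 600),
        )
        if rep.mdot_pvl > 0 and rep.v300 > 0:
            assert rep.t300 == pytest.approx(rep.v300 * PROPS.rho / rep.mdot_pvl, rel=1e-12)
        vols = [rep.sweep[th][0] for th in (150, 300, 600)]
        assert all(a >= b for a, b in zip(vols, vols[1:]))
        assert 0.0 <= rep.bfr <= 1.0
        assert 0.0 <= rep.v300_fraction <= 1.0
        d = rep.to_dict()
        assert d["label"] == "synthetic"
        assert "v150_mm3" in d
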