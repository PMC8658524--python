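"""Hemolysis-risk post-processing of channel flow fields.

Shear drives mechanical damage to erythrocytes; the indicators computed here
are the interior shear-stress magnitude tau = mu_eff * sqrt(2 Sij Sij), the
wall shear stress from the resolved near-wall gradient, the super-threshold
volume V300 (lumen volume where tau exceeds the 300 Pa critical level), the
mean residence time in that region t300 = V300*rho/mdot_PVL, the backflow
ratio, and centre-point / mass-weighted-average channel velocities.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .cardiac import FluidProperties
from .geometry import ChannelDomain, PVLChannelSpec, channel_volume
from .grid import FlowField
from .turbulence import strain_rate

DEFAULT_THRESHOLD_PA = 300.0
#: critical-stress literature range swept by reports, Pa
THRESHOLD_SWEEP_PA = (150.0, 300.0, 400.0, 600.0, 800.0)


@dataclass
class WallShear:
    """Wall shear stress per wall facet (one-sided quadratic near-wall gradient)."""

    tau: np.ndarray  # Pa, one entry per facet
    x: np.ndarray  # facet centre positions, m
    y: np.ndarray

    def max(self) -> float:
        return float(np.max(self.tau)) if self.tau.size else 0.0

    def argmax_position(self) -> tuple[float, float]:
        i = int(np.argmax(self.tau))
        return float(self.x[i]), float(self.y[i])


@dataclass
class ShearField:
    """Interior shear-stress magnitude and the effective viscosity it used."""

    tau: np.ndarray  # (nx, ny) Pa
    mu_eff: np.ndarray  # (nx, ny) Pa s
    wall: WallShear | None = None

    def max(self) -> float:
        return float(np.max(self.tau))


def shear_stress_field(field: FlowField, mu_t=None,
                       props: FluidProperties | None = None) -> ShearField:
    """tau = (mu + mu_t) * sqrt(2 Sij Sij) per cell; exactly mu*gamma in
    laminar simple shear."""
    props = props or FluidProperties()
    S = strain_rate(field).magnitude
    mu_eff = np.full_like(S, props.mu)
    if mu_t is not None:
        mu_eff = mu_eff + mu_t
    tau = np.where(field.grid.fluid, mu_eff * S, 0.0)
    return ShearField(tau=tau, mu_eff=mu_eff)


def wall_shear_stress(field: FlowField, props: FluidProperties | None = None) -> WallShear:
    """mu * d(u_t)/dn at each wall facet from the two nearest cell centers.

    The quadratic one-sided fit (zero at the wall face) is exact for a
    parabolic sublayer profile, consistent with near-wall-resolved grids.
    """
    props = props or FluidProperties()
    g = field.grid
    fl = g.fluid
    mu = props.mu
    uc, vc = field.cell_velocity()
    taus, xs, ys = [], [], []

    flp = np.pad(fl, 1, mode="constant", constant_values=False)
    tags = g.domain.edge_tags
    if tags.get("xmin") == "axis":
        flp[0, 1:-1] = fl[0, :]
    if g.ymin_open:
        flp[1:-1, 0] = fl[:, 0]
    if g.ymax_open:
        flp[1:-1, -1] = fl[:, -1]

    def collect(tangential, axis, side):
        # side=-1: wall on the low-index side of the fluid cell
        d = g.dx if axis == 0 else g.dy
        nb = np.roll(flp, -side, axis=axis)[1:-1, 1:-1]
        wall_cells = fl & ~nb  # fluid cell with wall on that side
        if not wall_cells.any():
            return
        ii, jj = np.nonzero(wall_cells)
        # first and second cell centers moving away from the wall
        i2 = ii - side if axis == 0 else ii
        j2 = jj - side if axis == 1 else jj
        t1 = tangential[ii, jj]
        ok2 = (
            (i2 >= 0) & (i2 < g.nx) & (j2 >= 0) & (j2 < g.ny)
        )
        t2 = np.zeros_like(t1)
        t2[ok2] = tangential[i2[ok2], j2[ok2]]
        fluid2 = np.zeros_like(ok2)
        fluid2[ok2] = fl[i2[ok2], j2[ok2]]
        tau = np.where(
            fluid2,
            mu * np.abs(9.0 * t1 - t2) / (3.0 * d),
            mu * np.abs(t1) / (0.5 * d),
        )
        if axis == 0:
            xw = g.xf[ii] if side == -1 else g.xf[ii + 1]
            yw = g.yc[jj]
        else:
            xw = g.xc[ii]
            yw = (g.dy * jj) if side == -1 else (g.dy * (jj + 1))
        taus.append(tau)
        xs.append(np.asarray(xw, dtype=float))
        ys.append(np.asarray(yw, dtype=float))

    collect(vc, 0, -1)
    collect(vc, 0, +1)
    collect(uc, 1, -1)
    collect(uc, 1, +1)
    if taus:
        return WallShear(tau=np.concatenate(taus), x=np.concatenate(xs),
                         y=np.concatenate(ys))
    return WallShear(tau=np.zeros(0), x=np.zeros(0), y=np.zeros(0))


def exceedance_volume(shear: ShearField, domain: ChannelDomain,
                      threshold: float = DEFAULT_THRESHOLD_PA,
                      region: str = "lumen") -> float:
    """Volume (m^3) where tau exceeds the threshold, by default in the lumen
    (channel band incl. the entrance fillet); ``region="downstream"`` reports
    the jet exceedance in the atrial plenum separately, ``"all"`` everything."""
    if region == "lumen":
        mask = domain.lumen
    elif region == "downstream":
        mask = domain.la_plenum
    elif region == "all":
        mask = domain.fluid
    else:
        raise ValueError("region must be lumen|downstream|all")
    vols = domain.cell_volumes()
    hot = mask & (shear.tau > threshold)
    return float(np.sum(vols[hot]))


def exceedance_fraction(v300: float, spec: PVLChannelSpec) -> float:
    """V300 / V_PVL; clipped at 1 (exceedance beyond the lumen is reported
    separately by :func:`exceedance_volume`)."""
    if v300 < 0:
        raise ValueError("v300 must be non-negative")
    vpvl = channel_volume(spec) * 1e-9
    if vpvl <= 0:
        raise ValueError("channel volume is zero")
    return min(v300 / vpvl, 1.0)


def residence_time(v300: float, props: FluidProperties, mdot_pvl: float) -> float:
    """Mean residence time in the super-threshold region, t = V*rho/mdot."""
    if mdot_pvl <= 0:
        raise ValueError("mdot_pvl must be positive")
    return v300 * props.rho / mdot_pvl


def backflow_ratio(mdot_mitral: float, mdot_inlet: float) -> float:
    """Mitral (leak) outflow as a fraction of the ventricular inflow."""
    if mdot_mitral < 0 or mdot_inlet < 0:
        raise ValueError("mass flows must be non-negative")
    if mdot_mitral > mdot_inlet * (1.0 + 1e-12):
        raise ValueError("mitral outflow exceeds inflow: mass balance violated")
    if mdot_inlet == 0:
        return 0.0
    return min(mdot_mitral / mdot_inlet, 1.0)


def channel_mass_flow(field: FlowField, domain: ChannelDomain,
                      props: FluidProperties | None = None) -> float:
    """Mass flow through the channel at mid-height, kg/s (3D-equivalent:
    planar sections carry the realized out-of-plane width)."""
    props = props or FluidProperties()
    g = field.grid
    j_mid = int(round(0.5 * (domain.y_channel0 + domain.y_channel1) / g.dy))
    j_mid = min(max(j_mid, 0), g.ny)
    return props.rho * float(np.sum(g.Ay[:, j_mid] * field.v[:, j_mid]))


def axis_peak_velocity(field: FlowField, domain: ChannelDomain) -> float:
    """Maximum velocity magnitude along the channel axis (the x = 0 line), m/s.

    The jet accelerates sharply past the entrance and peaks on the axis just
    inside or beyond the channel; this is the duct-flow profile maximum."""
    g = field.grid
    sp = field.speed()
    if g.axisym:
        axis_speed = sp[0, :]
    else:
        i = int(np.clip(np.searchsorted(g.xc, 0.0) - 1, 0, g.nx - 2))
        fx = (0.0 - g.xc[i]) / g.dx
        axis_speed = sp[i, :] * (1 - fx) + sp[i + 1, :] * fx
    return float(np.max(axis_speed))


def channel_velocity_stats(field: FlowField, domain: ChannelDomain) -> tuple[float, float]:
    """(u_cp, u_avg): speed at the lumen centre point at mid-height, and the
    mass-weighted average speed over the lumen (constant density cancels)."""
    g = field.grid
    sp = field.speed()
    y_mid = 0.5 * (domain.y_channel0 + domain.y_channel1)
    x_cp = 0.0  # gap centre (planar) / axis (axisymmetric)
    xc, yc = g.xc, g.yc
    x_q = min(max(x_cp, xc[0]), xc[-1])  # axis symmetry: clamp to first column
    y_q = min(max(y_mid, yc[0]), yc[-1])
    i = int(np.clip(np.searchsorted(xc, x_q) - 1, 0, g.nx - 2))
    j = int(np.clip(np.searchsorted(yc, y_q) - 1, 0, g.ny - 2))
    fx = (x_q - xc[i]) / g.dx
    fy = (y_q - yc[j]) / g.dy
    patch = domain.fluid[i : i + 2, j : j + 2]
    if not patch.all():
        raise ValueError("channel centre point is not inside the fluid")
    u_cp = float(
        sp[i, j] * (1 - fx) * (1 - fy)
        + sp[i + 1, j] * fx * (1 - fy)
        + sp[i, j + 1] * (1 - fx) * fy
        + sp[i + 1, j + 1] * fx * fy
    )
    vols = domain.cell_volumes()
    lum = domain.lumen
    u_avg = float(np.sum(sp[lum] * vols[lum]) / np.sum(vols[lum]))
    return u_cp, u_avg


@dataclass
class HemolysisReport:
    """Per-case record of the hemolysis-risk indicators."""

    label: str
    mdot_in: float  # ventricular inflow at the case flow point, kg/s
    mdot_pvl: float  # simulated leak mass flow, kg/s
    tau_max: float  # Pa, cell max of the interior shear magnitude
    tau_wall_max: float  # Pa, facet max
    v300: float  # m^3
    v300_fraction: float
    t300: float  # s
    bfr: float
    u_cp: float  # m/s
    u_avg: float  # m/s
    u_axis_max: float = 0.0  # m/s, peak speed along the channel axis
    threshold: float = DEFAULT_THRESHOLD_PA
    t_s: float | None = None
    phase: str | None = None
    converged: bool = True
    v_downstream: float = 0.0  # jet exceedance beyond the lumen, m^3
    sweep: dict = dfield(default_factory=dict)  # threshold -> (volume, fraction)

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "t_s": self.t_s,
            "phase": self.phase,
            "mdot_kgps": self.mdot_in,
            "mdot_pvl_kgps": self.mdot_pvl,
            "tau_max_pa": self.tau_max,
            "tauw_max_pa": self.tau_wall_max,
            "v300_mm3": self.v300 * 1e9,
            "v300_frac": self.v300_fraction,
            "t300_s": self.t300,
            "bfr": self.bfr,
            "ucp_mps": self.u_cp,
            "uavg_mps": self.u_avg,
            "uaxismax_mps": self.u_axis_max,
            "threshold_pa": self.threshold,
            "converged": self.converged,
            "v_downstream_mm3": self.v_downstream * 1e9,
        }
        for th, (vol, frac) in self.sweep.items():
            d[f"v{int(th)}_mm3"] = vol * 1e9
            d[f"v{int(th)}_frac"] = frac
        return d


def risk_report(
    label: str,
    spec: PVLChannelSpec,
    domain: ChannelDomain,
    field: FlowField,
    props: FluidProperties,
    mdot_in: float,
    mu_t=None,
    bfr: float | None = None,
    t_s: float | None = None,
    phase: str | None = None,
    threshold: float = DEFAULT_THRESHOLD_PA,
    sweep=(),
    converged: bool = True,
) -> HemolysisReport:
    """Aggregate all indicators for one (geometry, flow point) case.

    ``bfr`` may come from the lumped flow split; when omitted it is the
    simulated leak flow over the inflow.  The residence-time identity
    t300 = V300*rho/mdot_PVL holds exactly by construction.
    """
    shear = shear_stress_field(field, mu_t=mu_t, props=props)
    wall = wall_shear_stress(field, props)
    shear.wall = wall
    v300 = exceedance_volume(shear, domain, threshold)
    v_down = exceedance_volume(shear, domain, threshold, region="downstream")
    mdot_pvl = channel_mass_flow(field, domain, props)
    u_cp, u_avg = channel_velocity_stats(field, domain)
    u_axis = axis_peak_velocity(field, domain)
    t300 = residence_time(v300, props, mdot_pvl) if mdot_pvl > 0 else 0.0
    if bfr is None:
        bfr = backflow_ratio(min(max(mdot_pvl, 0.0), mdot_in), mdot_in)
    sweep_d = {
        th: (exceedance_volume(shear, domain, th),
             exceedance_fraction(exceedance_volume(shear, domain, th), spec))
        for th in sweep
    }
    return HemolysisReport(
        label=label,
        mdot_in=mdot_in,
        mdot_pvl=mdot_pvl,
        tau_max=shear.max(),
        tau_wall_max=wall.max(),
        v300=v300,
        v300_fraction=exceedance_fraction(v300, spec),
        t300=t300,
        bfr=bfr,
        u_cp=u_cp,
        u_avg=u_avg,
        u_axis_max=u_axis,
        threshold=threshold,
        t_s=t_s,
        phase=phase,
        converged=converged,
        v_downstream=v_down,
        sweep=sweep_d,
    )
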