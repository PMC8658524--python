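"""Menter k-omega SST eddy-viscosity closure.

The eddy viscosity carries the shear-stress-transport limiter

    mu_t = rho * min(k/omega, a*k / (S * tanh(phi^2)))
    phi  = max(2*sqrt(k)/(0.09*omega*y), 500*nu/(y^2*omega))

with a = a1 = 0.31, S the strain-rate magnitude and y the wall distance;
tanh(phi^2) is Menter's F2 blending function.  The k and omega transport
equations use the standard SST-2003 coefficient sets blended by F1
(beta* = 0.09; inner set sigma_k 0.85 / sigma_w 0.5 / beta 0.075 /
alpha 5/9; outer set 1.0 / 0.856 / 0.0828 / 0.44), with the production
limiter P_k <= 10 beta* rho k omega.  Near-wall boundary values follow
viscous-sublayer practice: k = 0 at walls and omega = 60 nu/(beta1 y^2)
in wall-adjacent cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cardiac import FluidProperties
from .grid import FlowField, Grid, compute_wall_distance

A1 = 0.31
BETA_STAR = 0.09
#: (sigma_k, sigma_w, beta, alpha) inner (k-omega) and outer (k-eps) sets
SET1 = (0.85, 0.5, 0.075, 5.0 / 9.0)
SET2 = (1.0, 0.856, 0.0828, 0.44)

K_FLOOR = 1e-12
OMEGA_FLOOR = 1e-6


@dataclass
class TurbulenceState:
    """k, omega and derived closure fields on a grid."""

    k: np.ndarray
    omega: np.ndarray
    y: np.ndarray  # wall distance, m
    mu_t: np.ndarray | None = None
    S: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.k < 0):
            raise ValueError("k must be non-negative")
        if np.any(self.omega <= 0):
            raise ValueError("omega must be strictly positive")


@dataclass
class StrainRate:
    s11: np.ndarray
    s22: np.ndarray
    s12: np.ndarray
    s33: np.ndarray  # hoop component u_r/r in axisymmetric mode, else 0
    magnitude: np.ndarray  # sqrt(2 Sij Sij)


def wall_distance(domain) -> np.ndarray:
    """Minimum distance from each cell center to any wall facet, m."""
    return compute_wall_distance(domain)


def strain_rate(field: FlowField) -> StrainRate:
    """Strain-rate tensor at cell centers and its magnitude sqrt(2 Sij Sij)."""
    g = field.grid
    u, v = field.u, field.v
    fluid = g.fluid
    dudx = (u[1:, :] - u[:-1, :]) / g.dx
    dvdy = (v[:, 1:] - v[:, :-1]) / g.dy
    uc, vc = field.cell_velocity()
    dudy = _tangential_center_gradient(uc, g.dy, 1, fluid, g)
    dvdx = _tangential_center_gradient(vc, g.dx, 0, fluid, g)
    s12 = 0.5 * (dudy + dvdx)
    if g.axisym:
        r = np.where(np.abs(g.xc) < 1e-30, 1.0, g.xc)[:, None]
        s33 = uc / r
    else:
        s33 = np.zeros_like(uc)
    mag = np.sqrt(2.0 * (dudx**2 + dvdy**2 + s33**2 + 2.0 * s12**2))
    mag = np.where(fluid, mag, 0.0)
    return StrainRate(s11=dudx, s22=dvdy, s12=s12, s33=s33, magnitude=mag)


def _tangential_center_gradient(qc, d, axis, fluid, g: Grid) -> np.ndarray:
    """Central derivative of a cell-centered velocity component with a no-slip
    (zero at the face) closure where the neighbour cell is solid or a wall
    edge, and one-sided differences at open domain edges."""
    qp = np.pad(qc, 1, mode="edge")
    flp = np.pad(fluid, 1, mode="edge")
    # open edges behave like fluid (zero-gradient); wall edges like solid
    tags = g.domain.edge_tags
    if tags.get("xmin") in ("inlet", "la_outlet", "axis"):
        flp[0, 1:-1] = fluid[0, :]
    if tags.get("xmax") in ("inlet", "la_outlet"):
        flp[-1, 1:-1] = fluid[-1, :]
    if tags.get("ymin") in ("inlet", "la_outlet"):
        flp[1:-1, 0] = fluid[:, 0]
    if tags.get("ymax") in ("inlet", "la_outlet"):
        flp[1:-1, -1] = fluid[:, -1]
    sl = [slice(1, -1), slice(1, -1)]
    sl_p = list(sl)
    sl_m = list(sl)
    sl_p[axis] = slice(2, None)
    sl_m[axis] = slice(0, -2)
    q_p, q_m = qp[tuple(sl_p)], qp[tuple(sl_m)]
    f_p, f_m = flp[tuple(sl_p)], flp[tuple(sl_m)]
    grad = (q_p - q_m) / (2.0 * d)
    # wall half a cell away on one side: one-sided toward the zero face value
    wall_p = ~f_p & f_m
    wall_m = f_p & ~f_m
    grad = np.where(wall_p, (0.0 - qc) / (0.5 * d), grad)
    grad = np.where(wall_m, (qc - 0.0) / (0.5 * d), grad)
    # at open-but-replicated edges the padded value equals qc -> one-sided
    return grad


def phi(k, omega, y, nu) -> np.ndarray:
    """Blending argument max(2 sqrt(k)/(0.09 omega y), 500 nu/(y^2 omega))."""
    k = np.asarray(k, dtype=float)
    omega = np.asarray(omega, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    y_safe = np.where(y <= 0, np.inf, y) if np.any(y <= 0) else y
    with np.errstate(divide="ignore"):
        t1 = 2.0 * np.sqrt(k) / (0.09 * omega * y_safe)
        t2 = 500.0 * nu / (y_safe**2 * omega)
    out = np.maximum(t1, t2)
    if np.any(np.asarray(y) <= 0):
        out = np.where(np.asarray(y) <= 0, np.inf, out)
    return out


def eddy_viscosity(k, omega, S, y, props: FluidProperties | None = None) -> np.ndarray:
    """SST-limited eddy viscosity rho*min(k/omega, a*k/(S tanh(phi^2)))."""
    props = props or FluidProperties()
    k = np.asarray(k, dtype=float)
    omega = np.asarray(omega, dtype=float)
    S = np.asarray(S, dtype=float)
    ph = np.minimum(phi(k, omega, y, props.nu), 100.0)
    f2 = np.tanh(ph**2)
    denom = S * f2
    ratio = np.where(denom > 1e-300, A1 * k / np.maximum(denom, 1e-300), np.inf)
    mu_t = props.rho * np.minimum(k / omega, ratio)
    return np.maximum(mu_t, 0.0)


def _upwind_face_advection(qc, u, v, grid: Grid) -> np.ndarray:
    """Conservative first-order upwind advection divergence for a scalar, per
    unit volume; inactive faces carry no flux."""
    g = grid
    qp_x = np.pad(qc, ((1, 1), (0, 0)), mode="edge")
    q_face_x = np.where(u >= 0, qp_x[:-1, :], qp_x[1:, :])
    fx = g.Ax * u * q_face_x
    fx[~g.u_active] = 0.0
    qp_y = np.pad(qc, ((0, 0), (1, 1)), mode="edge")
    q_face_y = np.where(v >= 0, qp_y[:, :-1], qp_y[:, 1:])
    fy = g.Ay * v * q_face_y
    open_y = g.v_active.copy()
    fy[~open_y] = 0.0
    div = (fx[1:, :] - fx[:-1, :] + fy[:, 1:] - fy[:, :-1]) / g.vol
    return np.where(g.fluid, div, 0.0)


def _face_diffusion(qc, gamma_c, grid: Grid, dirichlet_zero_walls: bool) -> np.ndarray:
    """Explicit diffusion div(gamma grad q) per unit volume; optional zero-value
    Dirichlet at wall faces (used for k), otherwise zero-flux walls."""
    g = grid
    gp = np.pad(gamma_c, 1, mode="edge")
    gx = 0.5 * (gp[:-1, 1:-1] + gp[1:, 1:-1])  # (nx+1, ny)
    gy = 0.5 * (gp[1:-1, :-1] + gp[1:-1, 1:])  # (nx, ny+1)
    qp_x = np.pad(qc, ((1, 1), (0, 0)), mode="edge")
    dq_x = (qp_x[1:, :] - qp_x[:-1, :]) / g.dx
    fx = g.Ax * gx * dq_x
    fx[~g.u_active] = 0.0
    qp_y = np.pad(qc, ((0, 0), (1, 1)), mode="edge")
    dq_y = (qp_y[:, 1:] - qp_y[:, :-1]) / g.dy
    fy = g.Ay * gy * dq_y
    fy[~g.v_active] = 0.0
    if dirichlet_zero_walls:
        # wall faces: value 0 at the face, half spacing
        flp = np.pad(g.fluid, 1, mode="constant", constant_values=False)
        wall_x = flp[:-1, 1:-1] ^ flp[1:, 1:-1]  # (nx+1, ny) fluid-solid faces
        # flux into the fluid cell adjacent to the wall
        qxL = qp_x[:-1, :]
        qxR = qp_x[1:, :]
        fx = np.where(wall_x & flp[:-1, 1:-1], g.Ax * gx * (0.0 - qxL) / (0.5 * g.dx), fx)
        fx = np.where(wall_x & flp[1:, 1:-1], g.Ax * gx * (qxR - 0.0) / (0.5 * g.dx), fx)
        wall_y = flp[1:-1, :-1] ^ flp[1:-1, 1:]
        qyL = qp_y[:, :-1]
        qyR = qp_y[:, 1:]
        fy = np.where(wall_y & flp[1:-1, :-1], g.Ay * gy * (0.0 - qyL) / (0.5 * g.dy), fy)
        fy = np.where(wall_y & flp[1:-1, 1:], g.Ay * gy * (qyR - 0.0) / (0.5 * g.dy), fy)
    div = (fx[1:, :] - fx[:-1, :] + fy[:, 1:] - fy[:, :-1]) / g.vol
    return np.where(g.fluid, div, 0.0)


def transport_step(state: TurbulenceState, field: FlowField, dt: float,
                   props: FluidProperties | None = None,
                   update_mu_t: bool = True) -> TurbulenceState:
    """Advance k and omega by one explicit step (semi-implicit destruction).

    Production, beta*-destruction, blended diffusion and the cross-diffusion
    term are all included; positivity is preserved by the implicit treatment
    of the destruction terms plus floors.
    """
    props = props or FluidProperties()
    if dt == 0:
        return TurbulenceState(k=state.k.copy(), omega=state.omega.copy(),
                               y=state.y, mu_t=state.mu_t, S=state.S)
    g = field.grid
    nu = props.nu
    k = state.k
    om = state.omega
    y = state.y

    sr = strain_rate(field)
    S = sr.magnitude
    mu_t = eddy_viscosity(k, om, S, y, props)
    nu_t = mu_t / props.rho

    # F1 blending (plain central gradients suffice for the blend argument)
    dkdx, dkdy = np.gradient(k, g.dx, g.dy)
    dwdx, dwdy = np.gradient(om, g.dx, g.dy)
    grad_kw = dkdx * dwdx + dkdy * dwdy
    cd_kw = np.maximum(2.0 * props.rho * SET2[1] / om * grad_kw, 1e-10)
    y_safe = np.maximum(y, 1e-12)
    arg1 = np.minimum(
        np.maximum(np.sqrt(np.maximum(k, 0.0)) / (BETA_STAR * om * y_safe),
                   500.0 * nu / (y_safe**2 * om)),
        4.0 * props.rho * SET2[1] * np.maximum(k, 0.0) / (cd_kw * y_safe**2),
    )
    f1 = np.tanh(np.minimum(arg1, 50.0) ** 4)

    def blend(c1, c2):
        return f1 * c1 + (1.0 - f1) * c2

    sigma_k = blend(SET1[0], SET2[0])
    sigma_w = blend(SET1[1], SET2[1])
    beta = blend(SET1[2], SET2[2])
    alpha = blend(SET1[3], SET2[3])

    p_k = np.minimum(nu_t * S**2, 10.0 * BETA_STAR * k * om)

    adv_k = _upwind_face_advection(k, field.u, field.v, g)
    adv_w = _upwind_face_advection(om, field.u, field.v, g)
    diff_k = _face_diffusion(k, nu + sigma_k * nu_t, g, dirichlet_zero_walls=True)
    diff_w = _face_diffusion(om, nu + sigma_w * nu_t, g, dirichlet_zero_walls=False)
    cross = 2.0 * (1.0 - f1) * SET2[1] / om * grad_kw

    k_new = (k + dt * (p_k + diff_k - adv_k)) / (1.0 + dt * BETA_STAR * om)
    w_rhs = alpha * S**2 + np.maximum(cross, 0.0) + diff_w - adv_w
    w_new = (om + dt * w_rhs) / (1.0 + dt * beta * om + dt * np.maximum(-cross, 0.0) / om)

    k_new = np.maximum(k_new, K_FLOOR)
    w_new = np.maximum(w_new, OMEGA_FLOOR)
    mu_t_new = eddy_viscosity(k_new, w_new, S, y, props) if update_mu_t else None
    return TurbulenceState(k=k_new, omega=w_new, y=y, mu_t=mu_t_new, S=S)


class SSTClosure:
    """Grid-bound SST closure used by the flow solver loop."""

    def __init__(self, grid: Grid, props: FluidProperties, cfg, u_ref: float):
        self.grid = grid
        self.props = props
        self.y = grid.wall_distance
        self.ti = getattr(cfg, "inlet_turbulence_intensity", 0.05)
        lf = getattr(cfg, "inlet_length_scale_factor", 0.1)
        # turbulent length scale ~ 10% of the lumen hydraulic width
        dom = grid.domain
        j_mid = min(max(int(round(0.5 * (dom.y_channel0 + dom.y_channel1) / grid.dy)), 0),
                    grid.ny - 1)
        n_lumen = int(np.count_nonzero(dom.lumen[:, j_mid])) or 1
        gap = n_lumen * grid.dx * (2.0 if grid.axisym else 1.0)
        self.length_scale = max(lf * gap, grid.dx)
        # wall-adjacent cells: any face neighbour solid or wall edge
        fl = grid.fluid
        flp = np.pad(fl, 1, mode="constant", constant_values=False)
        if grid.domain.edge_tags.get("xmin") == "axis":
            flp[0, 1:-1] = fl[0, :]
        if grid.ymin_open:
            flp[1:-1, 0] = fl[:, 0]
        if grid.ymax_open:
            flp[1:-1, -1] = fl[:, -1]
        nb_solid = (
            ~flp[:-2, 1:-1] | ~flp[2:, 1:-1] | ~flp[1:-1, :-2] | ~flp[1:-1, 2:]
        )
        self.wall_adjacent = fl & nb_solid

    def omega_wall(self) -> np.ndarray:
        beta1 = SET1[2]
        y = np.maximum(self.grid.wall_distance, 1e-12)
        return 60.0 * self.props.nu / (beta1 * y**2)

    def inflow_levels(self, field: FlowField) -> tuple[float, float]:
        """(k, omega) at the inlet from the intensity and length-scale rules,
        based on the current local inlet velocity (the plenum inflow is slow;
        jet turbulence is generated by the resolved shear layers)."""
        g = self.grid
        sel = g.inlet_faces
        if not sel.any():
            return K_FLOOR, OMEGA_FLOOR
        a = g.Ay[:, 0][sel]
        u_in = float(np.sum(a * np.abs(field.v[:, 0][sel])) / max(np.sum(a), 1e-300))
        k_in = 1.5 * (self.ti * u_in) ** 2 + K_FLOOR
        om_in = max(np.sqrt(k_in) / (BETA_STAR**0.25 * self.length_scale), OMEGA_FLOOR)
        return k_in, om_in

    def advance(self, field: FlowField, dt: float) -> np.ndarray:
        """Advance k/omega in place and return the updated eddy viscosity."""
        state = TurbulenceState(k=field.k, omega=field.omega, y=self.y)
        new = transport_step(state, field, dt, self.props, update_mu_t=False)
        k, om = new.k, new.omega
        # near-wall sublayer omega (k -> 0 at walls enters via the diffusion flux)
        om = np.where(self.wall_adjacent, np.maximum(self.omega_wall(), om), om)
        # inlet rows carry the inflow turbulence level
        if self.grid.ymin_open and self.grid.inlet_faces.any():
            k_in, om_in = self.inflow_levels(field)
            k[self.grid.inlet_faces, 0] = k_in
            om[self.grid.inlet_faces, 0] = om_in
        field.k = np.maximum(k, K_FLOOR)
        field.omega = np.maximum(om, OMEGA_FLOOR)
        mu = eddy_viscosity(field.k, field.omega, new.S, self.y, self.props)
        return np.where(self.grid.fluid, mu, 0.0)

    def mu_t_from(self, field: FlowField, S: np.ndarray) -> np.ndarray:
        mu = eddy_viscosity(field.k, field.omega, S, self.y, self.props)
        return np.where(self.grid.fluid, mu, 0.0)

    def mu_t(self, field: FlowField) -> np.ndarray:
        S = strain_rate(field).magnitude
        mu = eddy_viscosity(field.k, field.omega, S, self.y, self.props)
        return np.where(self.grid.fluid, mu, 0.0)
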