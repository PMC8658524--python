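"""Structured staggered (MAC) solver grids built from rasterized channel domains.

Velocity components live on cell faces (u on x-faces, v on y-faces), pressure
and turbulence scalars at cell centers.  Planar grids carry an out-of-plane
width in all areas and volumes; axisymmetric grids carry the 2*pi*r metric,
which also makes the axis (r = 0) a natural zero-area boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import distance_transform_edt
from scipy.sparse.linalg import splu

from .geometry import ChannelDomain


def make_box_domain(
    nx: int,
    ny: int,
    lx: float,
    ly: float,
    mode: str = "planar",
    width: float = 1.0,
    edge_tags: dict | None = None,
    x0: float | None = None,
) -> ChannelDomain:
    """An all-fluid rectangular domain (verification ducts, unit tests).

    Default tags mimic a duct run along +y: lateral walls (or the axis at
    x = 0 in axisymmetric mode), inlet at the bottom, outlet at the top.
    """
    if nx <= 0 or ny <= 0 or lx <= 0 or ly <= 0:
        raise ValueError("degenerate box")
    if edge_tags is None:
        edge_tags = {
            "xmin": "axis" if mode == "axisymmetric" else "wall",
            "xmax": "wall",
            "ymin": "inlet",
            "ymax": "la_outlet",
        }
    if x0 is None:
        x0 = 0.0
    fluid = np.ones((nx, ny), dtype=bool)
    return ChannelDomain(
        mode=mode,
        dx=lx / nx,
        dy=ly / ny,
        x0=x0,
        nx=nx,
        ny=ny,
        fluid=fluid,
        lumen=fluid.copy(),
        lv_plenum=np.zeros_like(fluid),
        la_plenum=np.zeros_like(fluid),
        edge_tags=edge_tags,
        width=width if mode == "planar" else 1.0,
        y_channel0=0.0,
        y_channel1=ly,
        spec=None,
    )


def compute_wall_distance(domain: ChannelDomain) -> np.ndarray:
    """Minimum distance from each cell center to the nearest wall facet, m.

    Wall facets are faces between fluid and solid cells plus lateral domain
    edges tagged as walls; open (inlet/outlet) and axis edges are not walls.
    Computed as an exact Euclidean distance transform on a half-spacing
    lattice whose feature points are the wall-face centers.
    """
    nx, ny = domain.nx, domain.ny
    fl = domain.fluid
    feat = np.zeros((2 * nx + 1, 2 * ny + 1), dtype=bool)
    # interior x-faces between fluid and solid
    wx = fl[:-1, :] ^ fl[1:, :]
    feat[2 : 2 * nx : 2, 1::2] = wx
    # interior y-faces
    wy = fl[:, :-1] ^ fl[:, 1:]
    feat[1::2, 2 : 2 * ny : 2] = wy
    if domain.edge_tags.get("xmin") == "wall":
        feat[0, 1::2] = fl[0, :]
    if domain.edge_tags.get("xmax") == "wall":
        feat[2 * nx, 1::2] = fl[-1, :]
    if domain.edge_tags.get("ymin") == "wall":
        feat[1::2, 0] = fl[:, 0]
    if domain.edge_tags.get("ymax") == "wall":
        feat[1::2, 2 * ny] = fl[:, ny]
    if not feat.any():
        raise ValueError("domain has no walls; wall distance undefined")
    edt = distance_transform_edt(~feat, sampling=(domain.dx / 2.0, domain.dy / 2.0))
    return np.ascontiguousarray(edt[1::2, 1::2])


@dataclass
class FlowField:
    """Staggered velocity/pressure/turbulence state on a :class:`Grid`."""

    grid: "Grid"
    u: np.ndarray  # (nx+1, ny) x-face normal velocity, m/s
    v: np.ndarray  # (nx, ny+1) y-face normal velocity, m/s
    p: np.ndarray  # (nx, ny) pressure, Pa
    k: np.ndarray  # (nx, ny) turbulent kinetic energy, m^2/s^2
    omega: np.ndarray  # (nx, ny) specific dissipation, 1/s
    time: float = 0.0

    def copy(self) -> "FlowField":
        return FlowField(
            self.grid, self.u.copy(), self.v.copy(), self.p.copy(),
            self.k.copy(), self.omega.copy(), self.time,
        )

    def cell_velocity(self) -> tuple[np.ndarray, np.ndarray]:
        """(uc, vc) velocity components averaged to cell centers."""
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        return uc, vc

    def speed(self) -> np.ndarray:
        uc, vc = self.cell_velocity()
        return np.sqrt(uc**2 + vc**2)


class Grid:
    """Metric terms, face activity masks and cached Poisson factorizations."""

    def __init__(self, domain: ChannelDomain):
        if not domain.fluid.any():
            raise ValueError("domain has no fluid cells")
        if domain.dx <= 0 or domain.dy <= 0:
            raise ValueError("degenerate cell size")
        self.domain = domain
        self.mode = domain.mode
        self.axisym = domain.mode == "axisymmetric"
        self.nx, self.ny = domain.nx, domain.ny
        self.dx, self.dy = domain.dx, domain.dy
        self.xc = domain.xc
        self.yc = domain.yc
        self.xf = domain.xf
        self.fluid = domain.fluid
        w = domain.width
        if self.axisym:
            if np.any(self.xf < -1e-15):
                raise ValueError("axisymmetric grids require x >= 0")
            self.Ax = 2.0 * np.pi * np.abs(self.xf)[:, None] * self.dy * np.ones((1, self.ny))
            self.Ay = 2.0 * np.pi * self.xc[:, None] * self.dx * np.ones((1, self.ny + 1))
            self.vol = 2.0 * np.pi * self.xc[:, None] * self.dx * self.dy * np.ones((1, self.ny))
        else:
            self.Ax = np.full((self.nx + 1, self.ny), w * self.dy)
            self.Ay = np.full((self.nx, self.ny + 1), w * self.dx)
            self.vol = np.full((self.nx, self.ny), w * self.dx * self.dy)

        fl = self.fluid
        # face activity: a face is active when it can carry a momentum unknown
        self.u_active = np.zeros((self.nx + 1, self.ny), dtype=bool)
        self.u_active[1:-1, :] = fl[:-1, :] & fl[1:, :]
        self.v_active = np.zeros((self.nx, self.ny + 1), dtype=bool)
        self.v_active[:, 1:-1] = fl[:, :-1] & fl[:, 1:]
        self.ymin_open = domain.edge_tags.get("ymin") in ("inlet", "la_outlet")
        self.ymax_open = domain.edge_tags.get("ymax") in ("inlet", "la_outlet")
        self.inlet_faces = fl[:, 0] & self.ymin_open
        self.outlet_faces = fl[:, -1] & self.ymax_open
        self.v_active[:, 0] = self.inlet_faces
        self.v_active[:, -1] = self.outlet_faces

        # fluid-neighbour availability (open domain edges count as fluid)
        flp = np.pad(fl, 1, mode="constant", constant_values=False)
        if self.ymin_open:
            flp[1:-1, 0] = fl[:, 0]
        if self.ymax_open:
            flp[1:-1, -1] = fl[:, -1]
        if domain.edge_tags.get("xmin") == "axis":
            flp[0, 1:-1] = fl[0, :]
        self._flp = flp

        # tangential-wall masks for the quadratic no-slip ghosts
        # u faces: is the row above/below fluid for both adjacent cells?
        self.u_up_ok = flp[:-1, 2:] & flp[1:, 2:]  # (nx+1, ny)
        self.u_dn_ok = flp[:-1, :-2] & flp[1:, :-2]
        # v faces: columns to the left/right fluid for both adjacent cells?
        self.v_lf_ok = flp[:-2, :-1] & flp[:-2, 1:]  # (nx, ny+1)
        self.v_rt_ok = flp[2:, :-1] & flp[2:, 1:]

        self.wall_distance = compute_wall_distance(domain)

        self._poisson_cache: dict = {}

    # -- pressure projection ------------------------------------------------

    def _poisson(self, inlet_dirichlet: bool):
        """Sparse factorization of the FV Laplacian over fluid cells.

        Dirichlet pressure faces sit on the open ymin edge (if the inlet is a
        pressure boundary) and on the open ymax edge; all other boundaries are
        Neumann.  Solves for phi with  sum_f A_f (phi_nb - phi_c)/delta =
        net outward volume flux;  p = rho*phi/dt.
        """
        key = bool(inlet_dirichlet)
        if key in self._poisson_cache:
            return self._poisson_cache[key]
        nx, ny = self.nx, self.ny
        fl = self.fluid
        idx = -np.ones((nx, ny), dtype=np.int64)
        nf = int(fl.sum())
        idx[fl] = np.arange(nf)

        rows, cols, vals = [], [], []
        diag = np.zeros(nf)

        def add_pairs(mask, ca, cb, coeff):
            ia, ib = idx[ca][mask], idx[cb][mask]
            c = coeff[mask]
            rows.extend([ia, ib])
            cols.extend([ib, ia])
            vals.extend([c, c])
            np.add.at(diag, ia, -c)
            np.add.at(diag, ib, -c)

        # interior x faces i=1..nx-1 between cells (i-1,j),(i,j)
        both = fl[:-1, :] & fl[1:, :]
        coeff = self.Ax[1:-1, :] / self.dx
        add_pairs(both, np.s_[:-1, :], np.s_[1:, :], coeff)
        # interior y faces
        both_y = fl[:, :-1] & fl[:, 1:]
        coeff_y = self.Ay[:, 1:-1] / self.dy
        add_pairs(both_y, np.s_[:, :-1], np.s_[:, 1:], coeff_y)

        # Dirichlet faces (half-cell distance)
        dir_lo = self.inlet_faces if inlet_dirichlet else np.zeros(nx, dtype=bool)
        dir_hi = self.outlet_faces
        c_lo = np.where(dir_lo, 2.0 * self.Ay[:, 0] / self.dy, 0.0)
        c_hi = np.where(dir_hi, 2.0 * self.Ay[:, -1] / self.dy, 0.0)
        np.add.at(diag, idx[:, 0][dir_lo], -c_lo[dir_lo])
        np.add.at(diag, idx[:, -1][dir_hi], -c_hi[dir_hi])

        if not dir_lo.any() and not dir_hi.any():
            # all-Neumann: pin the first fluid cell
            diag[0] -= 1.0

        rows.append(np.arange(nf))
        cols.append(np.arange(nf))
        vals.append(diag)
        rows = np.concatenate([np.atleast_1d(r) for r in rows])
        cols = np.concatenate([np.atleast_1d(c) for c in cols])
        vals = np.concatenate([np.atleast_1d(v) for v in vals])
        mat = sp.csc_matrix((vals, (rows, cols)), shape=(nf, nf))
        lu = splu(mat, permc_spec="MMD_AT_PLUS_A")
        entry = {"lu": lu, "idx": idx, "c_lo": c_lo, "c_hi": c_hi,
                 "dir_lo": dir_lo, "dir_hi": dir_hi}
        self._poisson_cache[key] = entry
        return entry

    def project(self, u, v, inlet_dirichlet, phi_lo=0.0, phi_hi=0.0):
        """Make (u, v) discretely divergence free; returns (u, v, phi).

        ``phi_lo``/``phi_hi`` are Dirichlet values of phi = p*dt/rho on the
        open bottom/top edges.
        """
        ps = self._poisson(inlet_dirichlet)
        idx, lu = ps["idx"], ps["lu"]
        fl = self.fluid
        outflux = (
            self.Ax[1:, :] * u[1:, :] - self.Ax[:-1, :] * u[:-1, :]
            + self.Ay[:, 1:] * v[:, 1:] - self.Ay[:, :-1] * v[:, :-1]
        )
        rhs = outflux[fl]
        if ps["dir_lo"].any():
            contrib = np.zeros_like(outflux)
            contrib[:, 0] = ps["c_lo"] * phi_lo
            rhs = rhs - contrib[fl]
        if ps["dir_hi"].any():
            contrib = np.zeros_like(outflux)
            contrib[:, -1] = ps["c_hi"] * phi_hi
            rhs = rhs - contrib[fl]
        phi_flat = lu.solve(rhs)
        phi = np.zeros((self.nx, self.ny))
        phi[fl] = phi_flat

        u = u.copy()
        v = v.copy()
        gx = (phi[1:, :] - phi[:-1, :]) / self.dx
        u[1:-1, :] = np.where(self.u_active[1:-1, :], u[1:-1, :] - gx, u[1:-1, :])
        gy = (phi[:, 1:] - phi[:, :-1]) / self.dy
        v[:, 1:-1] = np.where(self.v_active[:, 1:-1], v[:, 1:-1] - gy, v[:, 1:-1])
        if ps["dir_lo"].any():
            g0 = (phi[:, 0] - phi_lo) / (0.5 * self.dy)
            v[:, 0] = np.where(ps["dir_lo"], v[:, 0] - g0, v[:, 0])
        if ps["dir_hi"].any():
            g1 = (phi_hi - phi[:, -1]) / (0.5 * self.dy)
            v[:, -1] = np.where(ps["dir_hi"], v[:, -1] - g1, v[:, -1])
        return u, v, phi

    # -- diagnostics --------------------------------------------------------

    def divergence(self, u, v) -> np.ndarray:
        """Net outward volume flux per cell volume, 1/s (zero in solid)."""
        outflux = (
            self.Ax[1:, :] * u[1:, :] - self.Ax[:-1, :] * u[:-1, :]
            + self.Ay[:, 1:] * v[:, 1:] - self.Ay[:, :-1] * v[:, :-1]
        )
        div = np.zeros_like(outflux)
        div[self.fluid] = outflux[self.fluid] / self.vol[self.fluid]
        return div

    def zero_field(self) -> FlowField:
        return FlowField(
            grid=self,
            u=np.zeros((self.nx + 1, self.ny)),
            v=np.zeros((self.nx, self.ny + 1)),
            p=np.zeros((self.nx, self.ny)),
            k=np.full((self.nx, self.ny), 1e-12),
            omega=np.full((self.nx, self.ny), 1.0),
            time=0.0,
        )


def build_grid(domain: ChannelDomain) -> Grid:
    """Attach metric terms, face masks and the wall-distance field to a domain."""
    return Grid(domain)
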