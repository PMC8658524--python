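"""Parametric LV and PVL-channel geometry, and rasterization onto solver grids.

The leak channels are straight ducts of height 3 mm piercing the wall between
the left ventricle and the left atrium, with a rounded (fillet radius 0.3 mm)
entrance corner on the ventricular side.  Clinically reported cross-section
families — round, oval, slit-like and crescent — are represented by parametric
shapes whose realized area matches the requested cross-sectional area (CSA)
exactly.  For solving, each channel is reduced to a meridional/plane section:
round and oval sections map to an equivalent-area axisymmetric duct, slit and
crescent sections to a planar gap carrying the section's width per unit depth.

Lengths in the public specs are millimetres; rasterized domains are SI (m).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

FAMILIES = ("round", "oval", "slit", "crescent")

#: default width-to-gap aspect ratio when a spec does not give one
_DEFAULT_ASPECT = {"round": 1.0, "oval": 3.0, "slit": 6.0, "crescent": 6.0}

#: angular span of the crescent (annular-sector) family
_CRESCENT_ANGLE = 2.0 * math.pi / 3.0


# ---------------------------------------------------------------------------
# LV geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LVGeometry:
    """Simplified left ventricle as a body of revolution.

    Diameters (mm): d_M1/d_M2 mitral major/minor, d_A aortic, d_LV1 upper LV,
    d_LV2 maximal LV.  ``axial_length`` (mm) is solved so the chamber volume
    matches ``target_volume`` (mL).
    """

    d_M1: float = 24.0
    d_M2: float = 20.0
    d_A: float = 20.0
    d_LV1: float = 45.0
    d_LV2: float = 76.5
    target_volume: float = 87.0
    axial_length: float = 0.0  # solved

    def __post_init__(self) -> None:
        for name in ("d_M1", "d_M2", "d_A", "d_LV1", "d_LV2", "target_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_LV2 < self.d_LV1:
            raise ValueError("d_LV2 must be >= d_LV1")

    def radius_profile(self, z: np.ndarray) -> np.ndarray:
        """Chamber radius (mm) at axial positions z in [0, axial_length]."""
        L = self.axial_length
        zm = 0.35 * L
        r1, r2 = self.d_LV1 / 2.0, self.d_LV2 / 2.0
        z = np.asarray(z, dtype=float)
        r = np.empty_like(z)
        up = z <= zm
        # smooth widening from the basal diameter to the maximal diameter
        r[up] = r1 + (r2 - r1) * np.sin(0.5 * np.pi * z[up] / zm)
        # elliptic taper to the apex
        frac = np.clip((z[~up] - zm) / (L - zm), 0.0, 1.0)
        r[~up] = r2 * np.sqrt(np.clip(1.0 - frac**2, 0.0, None))
        return r

    @property
    def volume_ml(self) -> float:
        """Body-of-revolution volume, mL (numeric quadrature of the profile)."""
        z = np.linspace(0.0, self.axial_length, 2001)
        r = self.radius_profile(z)
        vol_mm3 = np.pi * np.trapezoid(r**2, z)
        return vol_mm3 / 1000.0


def make_lv_geometry(**overrides) -> LVGeometry:
    """Build the simplified LV, solving the axial length for the target volume."""
    geo = LVGeometry(**overrides)

    def vol_err(L: float) -> float:
        return replace(geo, axial_length=L).volume_ml - geo.target_volume

    # volume grows linearly with L at fixed diameters; bracket generously
    scale = geo.target_volume * 1000.0 / geo.d_LV2**2
    L = brentq(vol_err, 1e-3 * scale, 1e4 * scale, xtol=1e-10, rtol=1e-14)
    return replace(geo, axial_length=L)


# ---------------------------------------------------------------------------
# PVL channel cross-sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossSection:
    """Realized cross-section (mm units): exact area, perimeter and the
    narrow-dimension gap used by the planar/axisymmetric reduction."""

    area_mm2: float
    perimeter_mm: float
    gap_mm: float
    width_mm: float

    @property
    def equiv_radius_mm(self) -> float:
        """Radius of the equal-area circle."""
        return math.sqrt(self.area_mm2 / math.pi)


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan's approximation (error < 1e-5 for the aspects used here)
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


@dataclass(frozen=True)
class PVLChannelSpec:
    """A straight PVL channel: cross-section family, CSA, height and entrance fillet."""

    family: str
    csa_mm2: float
    height_mm: float = 3.0
    fillet_mm: float = 0.3
    aspect: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.csa_mm2 <= 0:
            raise ValueError("csa must be positive")
        if self.height_mm < 0:
            raise ValueError("height must be non-negative")
        if not (0 <= self.fillet_mm) or (self.height_mm > 0 and self.fillet_mm >= self.height_mm / 2):
            raise ValueError("fillet radius must satisfy 0 <= r < height/2")
        if self.aspect is not None and self.aspect < 1.0:
            raise ValueError("aspect (width/gap) must be >= 1")

    @property
    def aspect_ratio(self) -> float:
        return self.aspect if self.aspect is not None else _DEFAULT_ASPECT[self.family]

    def cross_section(self) -> CrossSection:
        """Realized cross-section; its area equals the requested CSA exactly."""
        A = self.csa_mm2
        t = self.aspect_ratio
        if self.family == "round":
            r = math.sqrt(A / math.pi)
            return CrossSection(A, 2 * math.pi * r, 2 * r, 2 * r)
        if self.family == "oval":
            b = math.sqrt(A / (math.pi * t))
            a = t * b
            return CrossSection(A, _ellipse_perimeter(a, b), 2 * b, 2 * a)
        # slit: rectangle width w x gap g; crescent: annular sector of the same
        # gap and arc width (area R*theta*g is exact; perimeter ~ two arcs + ends)
        g = math.sqrt(A / t)
        w = A / g
        if self.family == "crescent" and (w / _CRESCENT_ANGLE) <= g / 2:
            raise ValueError("crescent aspect too small for a valid annular sector")
        return CrossSection(A, 2 * (w + g), g, w)

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.family,
                "csa_mm2": self.csa_mm2,
                "height_mm": self.height_mm,
                "fillet_mm": self.fillet_mm,
                "aspect": self.aspect,
                "label": self.label,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PVLChannelSpec":
        return cls(**json.loads(text))


#: the four study presets: wide untreated leaks (I, III) and narrow residual
#: leaks after incomplete percutaneous closure (II, IV)
_PRESETS = {
    "PVL I": dict(family="oval", csa_mm2=7.9, aspect=3.0),
    "PVL II": dict(family="slit", csa_mm2=1.5, aspect=8.0),
    "PVL III": dict(family="crescent", csa_mm2=18.5, aspect=6.0),
    "PVL IV": dict(family="slit", csa_mm2=5.0, aspect=5.0),
}

PRESET_LABELS = tuple(_PRESETS)


def pvl_preset(label: str) -> PVLChannelSpec:
    """One of the four study channels (PVL I–IV)."""
    if label not in _PRESETS:
        raise KeyError(f"unknown preset {label!r}; expected one of {PRESET_LABELS}")
    return PVLChannelSpec(label=label, height_mm=3.0, fillet_mm=0.3, **_PRESETS[label])


def channel_volume(spec: PVLChannelSpec) -> float:
    """Total channel volume V_PVL, mm^3: prism CSA*height plus the fluid opened
    by the entrance fillet (corner area r^2(1-pi/4) swept along the perimeter)."""
    cs = spec.cross_section()
    prism = spec.csa_mm2 * spec.height_mm
    fillet = cs.perimeter_mm * spec.fillet_mm**2 * (1.0 - math.pi / 4.0)
    return prism + fillet


def hydraulic_diameter(spec: PVLChannelSpec) -> float:
    """4*area/perimeter of the realized cross-section, mm."""
    cs = spec.cross_section()
    return 4.0 * cs.area_mm2 / cs.perimeter_mm


# ---------------------------------------------------------------------------
# Rasterized channel domain
# ---------------------------------------------------------------------------

@dataclass
class ChannelDomain:
    """Uniform structured grid for a channel + plena sandwich (SI units).

    The domain stacks an upstream LV plenum, the channel lumen and a downstream
    LA plenum along +y.  ``mode`` is "planar" (x is a transverse coordinate,
    cells carry the section width per unit depth) or "axisymmetric" (x is the
    radius; cell volumes carry the 2*pi*r weight).  Edge tags assign the
    boundary-condition kinds: the LV-side bottom edge is the inlet, the top
    edge the LA outlet, lateral edges walls (or the axis at r = 0).
    """

    mode: str
    dx: float
    dy: float
    x0: float  # coordinate of the first x face, m
    nx: int
    ny: int
    fluid: np.ndarray  # (nx, ny) bool
    lumen: np.ndarray  # (nx, ny) bool, channel band only
    lv_plenum: np.ndarray
    la_plenum: np.ndarray
    edge_tags: dict
    width: float  # planar out-of-plane width, m (1.0 for axisymmetric)
    y_channel0: float  # channel entrance height, m
    y_channel1: float  # channel exit height, m
    spec: PVLChannelSpec | None = None
    #: open fraction of boundary (fillet) cells for volume accounting; the
    #: solver itself sees the binary fluid mask
    cell_fraction: np.ndarray | None = None

    @property
    def solid(self) -> np.ndarray:
        return ~self.fluid

    @property
    def xf(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.nx + 1)

    @property
    def xc(self) -> np.ndarray:
        return self.x0 + self.dx * (np.arange(self.nx) + 0.5)

    @property
    def yc(self) -> np.ndarray:
        return self.dy * (np.arange(self.ny) + 0.5)

    def cell_volumes(self) -> np.ndarray:
        """(nx, ny) cell volumes, m^3, honoring the mode (2*pi*r or width weight)."""
        if self.mode == "axisymmetric":
            ring = 2.0 * np.pi * self.xc * self.dx * self.dy
        else:
            ring = np.full(self.nx, self.width * self.dx * self.dy)
        vols = np.repeat(ring[:, None], self.ny, axis=1)
        if self.cell_fraction is not None:
            vols = vols * self.cell_fraction
        return vols

    def lumen_volume(self) -> float:
        """Summed lumen cell volume, m^3."""
        return float(np.sum(self.cell_volumes()[self.lumen]))


def rasterize_channel_domain(
    spec: PVLChannelSpec,
    mode: str | None = None,
    resolution: float | None = None,
    plenum_factor: float = 3.0,
    resolution_axial: float | None = None,
) -> ChannelDomain:
    """Rasterize a channel spec onto a uniform structured solver grid.

    Parameters
    ----------
    mode : "planar" or "axisymmetric".  Defaults to axisymmetric for
        round/oval sections and planar for slit/crescent sections.
    resolution : requested in-lumen cell size, mm (<= 0.25).  Defaults to
        gap/16 capped at 0.25 mm.  The transverse spacing is snapped so channel
        walls coincide with cell faces; the axial spacing is twice as coarse.
    plenum_factor : upstream/downstream plena depth and lateral margin in
        channel widths (>= 3).
    """
    cs = spec.cross_section()
    if mode is None:
        mode = "axisymmetric" if spec.family in ("round", "oval") else "planar"
    if mode not in ("planar", "axisymmetric"):
        raise ValueError("mode must be 'planar' or 'axisymmetric'")
    if plenum_factor < 3.0:
        raise ValueError("plenum_factor must be >= 3 (plena of at least 3 channel widths)")
    if spec.height_mm <= 0:
        raise ValueError("cannot rasterize a zero-height channel")

    if mode == "axisymmetric":
        half_gap = cs.equiv_radius_mm * 1e-3
        channel_width = 2.0 * half_gap
    else:
        half_gap = 0.5 * cs.gap_mm * 1e-3
        channel_width = 2.0 * half_gap
    if resolution is None:
        resolution = min(0.25, 1e3 * half_gap / 12.0)
    if resolution > 0.25:
        raise ValueError("resolution must be <= 0.25 mm inside the lumen")
    res = resolution * 1e-3

    height = spec.height_mm * 1e-3
    fillet = spec.fillet_mm * 1e-3

    # snap the transverse spacing so the channel wall lies on a face
    n_half = max(4, math.ceil(half_gap / res - 1e-12))
    dx = half_gap / n_half
    # axial spacing: twice the transverse target by default, but fine enough
    # for the entrance fillet; snapped to the channel height
    res_y = resolution_axial * 1e-3 if resolution_axial is not None else 2.0 * res
    if fillet > 0:
        res_y = min(res_y, 0.75 * fillet)
    n_ch = max(4, math.ceil(height / res_y - 1e-12))
    dy = height / n_ch

    drop_fillet = False
    if fillet > 0 and (dx > fillet or dy > fillet):
        warnings.warn(
            "grid too coarse to resolve the entrance fillet; fillet dropped",
            RuntimeWarning,
            stacklevel=2,
        )
        drop_fillet = True
        fillet = 0.0

    plenum_depth = plenum_factor * channel_width
    n_p = max(3, math.ceil(plenum_depth / dy - 1e-12))
    lateral = half_gap + plenum_factor * channel_width
    n_lat = math.ceil(lateral / dx - 1e-12)

    if mode == "axisymmetric":
        nx = n_lat
        x0 = 0.0
        wall_x = half_gap  # channel wall radius
        edge_tags = {"xmin": "axis", "xmax": "wall", "ymin": "inlet", "ymax": "la_outlet"}
    else:
        nx = 2 * n_lat
        x0 = -n_lat * dx
        wall_x = half_gap
        edge_tags = {"xmin": "wall", "xmax": "wall", "ymin": "inlet", "ymax": "la_outlet"}
    ny = n_p + n_ch + n_p
    y_ch0 = n_p * dy
    y_ch1 = y_ch0 + height

    xc = x0 + dx * (np.arange(nx) + 0.5)
    yc = dy * (np.arange(ny) + 0.5)
    X, Y = np.meshgrid(xc, yc, indexing="ij")

    in_lv = Y < y_ch0
    in_la = Y >= y_ch1
    in_band = ~in_lv & ~in_la
    r_abs = np.abs(X)
    in_gap = r_abs < wall_x - 1e-15

    fluid = in_lv | in_la | (in_band & in_gap)
    cell_fraction = np.ones_like(X)

    if fillet > 0:
        # entrance corner (LV side): arc centre at (wall_x + r, y_ch0 + r);
        # fluid gains the corner-square points outside the arc.  A cell joins
        # the fluid when the majority of a 4x4 subsample lies outside the arc,
        # which centres the voxelization error on the curved boundary.
        cxr = wall_x + fillet
        cy = y_ch0 + fillet
        corner = (
            in_band
            & (r_abs >= wall_x - 1e-15)
            & (r_abs < wall_x + fillet)
            & (Y < y_ch0 + fillet)
        )
        frac = np.zeros_like(X)
        offs = (np.arange(4) + 0.5) / 4.0 - 0.5
        for ox in offs:
            for oy in offs:
                xs = np.abs(X + ox * dx)
                ys = Y + oy * dy
                sub_fluid = (
                    ((xs - cxr) ** 2 + (ys - cy) ** 2 >= fillet**2)
                    | (xs < wall_x)
                    | (ys < y_ch0)
                )
                frac += sub_fluid
        fluid |= corner & (frac >= 8.0)
        # boundary cells carry their resolved open fraction, rescaled so the
        # included cells conserve the sampled corner area (excluded slivers
        # are lumped into their neighbours)
        included = corner & (frac >= 8.0)
        if included.any():
            total = float(np.sum(frac[corner])) / 16.0
            kept = float(np.sum(frac[included])) / 16.0
            scale = total / kept if kept > 0 else 1.0
            cell_fraction[included] = np.clip(frac[included] / 16.0 * scale, 0.0, 1.0)

    lumen = fluid & in_band
    if not lumen.any():
        raise ValueError("rasterization produced no lumen cells")

    dom = ChannelDomain(
        mode=mode,
        dx=dx,
        dy=dy,
        x0=x0,
        nx=nx,
        ny=ny,
        fluid=fluid,
        lumen=lumen,
        lv_plenum=fluid & in_lv,
        la_plenum=fluid & in_la,
        edge_tags=edge_tags,
        width=1.0 if mode == "axisymmetric" else cs.width_mm * 1e-3,
        y_channel0=y_ch0,
        y_channel1=y_ch1,
        spec=spec if not drop_fillet else replace(spec, fillet_mm=0.0),
        cell_fraction=cell_fraction,
    )
    return dom
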