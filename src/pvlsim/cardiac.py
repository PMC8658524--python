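"""Systolic flow profile, pressures, unit conversions and the lumped LV flow split.

During systole the mitral valve is closed, so ventricular inflow (the
contraction-induced mass flux) leaves either through the aorta or backward
through the paravalvular leak (PVL) channel into the left atrium.  This module
holds the blood properties, the tabulated systolic flow-rate profile, the
boundary pressures, and a small lumped-parameter model that splits the
ventricular inflow between the aortic outlet and the PVL orifice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

#: mmHg -> Pa factor; self-consistent with the printed pressure pairs
#: (23 mmHg = 3066.4 Pa, 102 mmHg = 13598.8 Pa) after one-decimal rounding.
MMHG_TO_PA = 133.322

#: Seven reference points on the systolic flow-rate profile:
#: (cycle time s, volume flow mL/s).  Peak at 0.78 s.
REFERENCE_FLOW_POINTS = (
    (0.71, 85.3),
    (0.73, 207.0),
    (0.75, 328.7),
    (0.78, 414.0),
    (0.84, 328.7),
    (0.88, 207.0),
    (0.92, 85.3),
)

SYSTOLE_START_S = 0.68
SYSTOLE_END_S = 0.98
CYCLE_PERIOD_S = 1.0


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood constants.

    mu : dynamic viscosity, Pa s
    rho : density, kg/m^3
    """

    mu: float = 3.45e-3
    rho: float = 1060.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("viscosity and density must be strictly positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity, m^2/s."""
        return self.mu / self.rho


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert a pressure in mmHg to Pa (factor 133.322)."""
    if not np.isfinite(p_mmhg):
        raise ValueError("pressure must be finite")
    return float(p_mmhg) * MMHG_TO_PA


@dataclass(frozen=True)
class PressureSet:
    """Constant boundary pressures, Pa (systolic scenario: aortic > atrial)."""

    p_aortic_outlet: float = 102 * MMHG_TO_PA
    p_mitral_outlet: float = 23 * MMHG_TO_PA

    @classmethod
    def from_mmhg(cls, p_ao_mmhg: float = 102.0, p_la_mmhg: float = 23.0) -> "PressureSet":
        return cls(mmhg_to_pa(p_ao_mmhg), mmhg_to_pa(p_la_mmhg))

    @property
    def dp(self) -> float:
        """Aortic-side minus atrial-side pressure, Pa."""
        return self.p_aortic_outlet - self.p_mitral_outlet


@dataclass(frozen=True)
class FlowProfile:
    """Systolic volume-flow profile q(t), mL/s, zero outside the systole window.

    The profile interpolates the seven tabulated reference points plus zero
    anchors at the start and end of systole with a monotone shape-preserving
    piecewise cubic (PCHIP): it is continuous, non-negative, and exact at every
    anchor.
    """

    anchors: tuple = REFERENCE_FLOW_POINTS
    systole_start: float = SYSTOLE_START_S
    systole_end: float = SYSTOLE_END_S
    period: float = CYCLE_PERIOD_S
    _interp: PchipInterpolator = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        t = [self.systole_start] + [a[0] for a in self.anchors] + [self.systole_end]
        q = [0.0] + [a[1] for a in self.anchors] + [0.0]
        ta = np.asarray(t, dtype=float)
        qa = np.asarray(q, dtype=float)
        if np.any(np.diff(ta) <= 0):
            raise ValueError("anchor times must be strictly increasing")
        if np.any(qa < 0):
            raise ValueError("flow anchors must be non-negative")
        object.__setattr__(self, "_interp", PchipInterpolator(ta, qa))

    def flow_rate(self, t: float) -> float:
        """Volume flow rate at cycle time ``t`` (wrapped modulo the period), mL/s."""
        tm = float(t) % self.period
        if tm <= self.systole_start or tm >= self.systole_end:
            return 0.0
        return max(float(self._interp(tm)), 0.0)


def systolic_flow_rate(t: float, profile: FlowProfile | None = None) -> float:
    """Systolic volume flow rate at cycle time ``t``, mL/s."""
    profile = profile or FlowProfile()
    return profile.flow_rate(t)


def volume_to_mass_flow(q_ml_s: float, props: FluidProperties | None = None) -> float:
    """Convert a volume flow (mL/s) to a mass flow (kg/s); unrounded.

    Tabulated mass flows are displayed rounded to 3 decimals.
    """
    if q_ml_s < 0:
        raise ValueError("volume flow must be non-negative")
    props = props or FluidProperties()
    return q_ml_s * 1e-6 * props.rho


def reference_points(props: FluidProperties | None = None) -> pd.DataFrame:
    """The seven reference systolic flow points as a table.

    Columns: t_s, q_ml_s, mdot_kg_s (display-rounded to 3 decimals), phase
    (acceleration / peak / deceleration relative to the 0.78 s peak).
    """
    props = props or FluidProperties()
    rows = []
    for t, q in REFERENCE_FLOW_POINTS:
        phase = "peak" if t == 0.78 else ("acceleration" if t < 0.78 else "deceleration")
        rows.append(
            {
                "t_s": t,
                "q_ml_s": q,
                "mdot_kg_s": round(volume_to_mass_flow(q, props), 3),
                "phase": phase,
            }
        )
    return pd.DataFrame(rows)


def lv_reference_volume(edv_ml: float, esv_ml: float) -> float:
    """Reference chamber volume: arithmetic mean of end-diastolic and end-systolic volumes."""
    if esv_ml < 0 or edv_ml < esv_ml:
        raise ValueError("need edv >= esv >= 0")
    return 0.5 * (edv_ml + esv_ml)


@dataclass(frozen=True)
class FlowSplit:
    """Ventricular inflow split between the aortic outlet and the PVL orifice (SI)."""

    q_in: float
    q_aortic: float
    q_pvl: float
    p_lv: float
    bfr: float


def solve_flow_split(
    q_in: float,
    pvl,
    cd: float = 0.80,
    r_a: float = 7.5e5,
    pressures: PressureSet | None = None,
    props: FluidProperties | None = None,
) -> FlowSplit:
    """Lumped-parameter split of the ventricular inflow between aorta and PVL.

    Solves for the chamber pressure ``p_lv`` such that

        q_aortic(p_lv) + q_pvl(p_lv) = q_in

    with a linear aortic branch ``q_aortic = (p_lv - p_ao) / r_a`` and an
    orifice law for the leak ``q_pvl = cd * A * sqrt(2 max(p_lv - p_la, 0)/rho)``.
    With ``r_a = 0`` the chamber pressure is pinned to the aortic pressure and
    the aorta takes whatever flow the orifice does not.

    Parameters
    ----------
    q_in : ventricular inflow, m^3/s.
    pvl : PVLChannelSpec (or any object with ``csa_mm2``); ``None`` or zero area
        means no leak.
    cd : orifice discharge coefficient, in (0, 1].
    r_a : aortic flow resistance, Pa s/m^3.
    """
    if q_in < 0:
        raise ValueError("q_in must be non-negative")
    if not (0 < cd <= 1):
        raise ValueError("cd must be in (0, 1]")
    if r_a < 0:
        raise ValueError("r_a must be non-negative")
    pressures = pressures or PressureSet()
    props = props or FluidProperties()
    area = 0.0 if pvl is None else float(pvl.csa_mm2) * 1e-6
    p_ao, p_la = pressures.p_aortic_outlet, pressures.p_mitral_outlet

    def q_orifice(p_lv: float) -> float:
        return cd * area * np.sqrt(2.0 * max(p_lv - p_la, 0.0) / props.rho)

    if r_a == 0.0:
        # chamber pinned to aortic pressure; the aortic branch takes the residual
        p_lv = p_ao
        q_pvl = q_orifice(p_lv)
        q_a = q_in - q_pvl
    elif area == 0.0:
        q_pvl = 0.0
        q_a = q_in
        p_lv = p_ao + r_a * q_a
    else:

        def resid(p_lv: float) -> float:
            return (p_lv - p_ao) / r_a + q_orifice(p_lv) - q_in

        lo = min(p_la, p_ao) - 1.0
        hi = p_ao + r_a * q_in + 1.0
        if resid(lo) > 0 or resid(hi) < 0:
            raise RuntimeError(
                f"flow-split root not bracketed: resid({lo:.6g})={resid(lo):.6g}, "
                f"resid({hi:.6g})={resid(hi):.6g}"
            )
        p_lv = brentq(resid, lo, hi, xtol=1e-10, rtol=1e-14)
        q_pvl = q_orifice(p_lv)
        q_a = q_in - q_pvl
    bfr = 0.0 if q_in < 1e-300 else min(max(q_pvl / q_in, 0.0), 1.0)
    return FlowSplit(q_in=q_in, q_aortic=q_a, q_pvl=q_pvl, p_lv=p_lv, bfr=bfr)
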