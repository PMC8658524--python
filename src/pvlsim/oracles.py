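"""Closed-form flow references used to verify the solver and screen cases.

These are deliberately kept independent of the solver discretization so they
constitute genuine cross-checks: an inviscid (Torricelli/Bernoulli) jet limit,
the orifice discharge law, fully developed laminar slit flow, and a Reynolds
number diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class OracleResult:
    name: str
    value: float
    units: str
    inputs: dict = field(default_factory=dict)
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "value": self.value,
            "units": self.units,
            "inputs": self.inputs,
            "note": self.note,
        }


def bernoulli_jet_velocity(dp: float, rho: float = 1060.0) -> OracleResult:
    """Inviscid jet velocity sqrt(2*dp/rho) for a pressure-driven orifice."""
    if dp < 0:
        raise ValueError("dp must be non-negative")
    v = math.sqrt(2.0 * dp / rho)
    return OracleResult(
        "bernoulli_jet_velocity", v, "m/s", {"dp_pa": dp, "rho": rho},
        "inviscid limit; real jets fall short of this by viscous/entrance losses",
    )


def orifice_flow(cd: float, area: float, dp: float, rho: float = 1060.0) -> OracleResult:
    """Orifice discharge q = cd * A * sqrt(2*dp/rho), m^3/s."""
    if not (0 < cd <= 1):
        raise ValueError("cd must be in (0, 1]")
    if area < 0:
        raise ValueError("area must be non-negative")
    q = cd * area * bernoulli_jet_velocity(dp, rho).value
    return OracleResult(
        "orifice_flow", q, "m^3/s", {"cd": cd, "area_m2": area, "dp_pa": dp, "rho": rho},
        "sharp-edged orifice law; cd lumps contraction and friction",
    )


@dataclass(frozen=True)
class SlitPoiseuille:
    """Fully developed laminar flow between parallel plates spaced ``gap`` apart."""

    u_mean: float
    gap: float
    mu: float

    @property
    def u_center(self) -> float:
        return 1.5 * self.u_mean

    @property
    def tau_wall(self) -> float:
        return 6.0 * self.mu * self.u_mean / self.gap

    @property
    def dpdx(self) -> float:
        return -12.0 * self.mu * self.u_mean / self.gap**2

    def profile(self, x) -> float:
        """Velocity at transverse position x measured from the gap centre."""
        return self.u_center * (1.0 - (2.0 * x / self.gap) ** 2)


def slit_poiseuille(u_mean: float, gap: float, mu: float) -> SlitPoiseuille:
    """Laminar plane-Poiseuille solution: parabolic profile, tau_w = 6*mu*U/h."""
    if gap <= 0 or mu <= 0:
        raise ValueError("gap and mu must be positive")
    return SlitPoiseuille(u_mean=u_mean, gap=gap, mu=mu)


def reynolds_number(rho: float, u: float, d_h: float, mu: float) -> OracleResult:
    """Reynolds number rho*u*d_h/mu based on a hydraulic diameter."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    re = rho * u * d_h / mu
    return OracleResult(
        "reynolds_number", re, "-", {"rho": rho, "u": u, "d_h": d_h, "mu": mu},
        "duct transition is gradual; ~2300 is the usual pipe threshold",
    )
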