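"""Lumped-parameter single-lymphangion hemodynamics.

Passive tube law, sigmoidal valve resistances, Poiseuille body resistance,
conservation of mass for the diameter, and the circumferential wall-force
balance that closes the loop with the muscle-cell force.  All quantities
in CGS units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .params import CellMechParams, TubeLawParams, ValveParams, VesselParams

__all__ = ["LymphangionState", "passive_tube_law", "valve_resistance",
           "body_half_resistance", "flows", "diameter_rate", "wall_pressure",
           "cell_length_from_diameter", "ejection_fraction",
           "fluid_energy_rates"]


@dataclass
class LymphangionState:
    """Diameter, mid pressure, valve flows, and valve resistances."""

    D: float          # cm
    p_m: float = 0.0  # dyne/cm²
    Q1: float = 0.0   # inlet flow, cm³/s
    Q2: float = 0.0   # outlet flow, cm³/s
    R_V1: float = 0.0 # dyne·s/cm⁵
    R_V2: float = 0.0


def passive_tube_law(D, tl: TubeLawParams):
    """Passive transmural pressure f_pas(D) (dyne/cm²), monotone in D.

    f_pas(D) = P_d·[exp(s_d·(D/D_d − 1)) − c_collapse·(D_d/D)³]
    """
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ValueError("diameter must be > 0")
    out = tl.P_d * (np.exp(tl.s_d * (D / tl.D_d - 1.0))
                    - tl.c_collapse * (tl.D_d / D) ** 3)
    return float(out) if out.ndim == 0 else out


def valve_resistance(dp, vp: ValveParams):
    """Valve resistance R_V(dp) = R_Vn + R_Vx/(1 + exp(s_o·(dp − dp_o))).

    Monotone decreasing in the pressure drop dp: low resistance for a
    favorable (positive) drop, high — but finite, so the valve never fully
    seals — for an adverse one.
    """
    dp = np.asarray(dp, dtype=float)
    out = vp.R_Vn + vp.R_Vx * expit(-vp.s_o * (dp - vp.dp_o))
    return float(out) if out.ndim == 0 else out


def body_half_resistance(D: float, vessel: VesselParams) -> float:
    """Poiseuille resistance of half the lymphangion body (dyne·s/cm⁵)."""
    return 64.0 * vessel.mu_lymph * vessel.L_v / (math.pi * D ** 4)


def _valve_local_drop(dp_tot: float, Rh: float, vp: ValveParams) -> float:
    """Pressure drop across the valve itself when the segment drop is
    ``dp_tot`` and the body half-resistance is ``Rh``.

    Solves dp = dp_tot·R_V(dp)/(R_V(dp) + Rh); the residual is strictly
    increasing in dp, so the root is unique and bracketed by [0, dp_tot].
    """
    if dp_tot == 0.0:
        return 0.0

    def res(dp: float) -> float:
        R = valve_resistance(dp, vp)
        return dp - dp_tot * R / (R + Rh)

    lo, hi = (0.0, dp_tot) if dp_tot > 0 else (dp_tot, 0.0)
    return float(brentq(res, lo, hi, xtol=1e-12 * max(1.0, abs(dp_tot)),
                        rtol=8.9e-16, maxiter=200))


def flows(p_a: float, p_m: float, p_b: float, D: float,
          vessel: VesselParams) -> tuple[float, float, float, float]:
    """(Q1, Q2, R_V1, R_V2) from the axial momentum balance.

    Each valve's resistance is evaluated at the local pressure drop across
    the valve itself (Q·R_V), obtained from the enclosed scalar root solve.
    """
    Rh = body_half_resistance(D, vessel)
    dp1 = _valve_local_drop(p_a - p_m, Rh, vessel.valve1)
    R_V1 = float(valve_resistance(dp1, vessel.valve1))
    Q1 = (p_a - p_m) / (R_V1 + Rh)
    dp2 = _valve_local_drop(p_m - p_b, Rh, vessel.valve2)
    R_V2 = float(valve_resistance(dp2, vessel.valve2))
    Q2 = (p_m - p_b) / (R_V2 + Rh)
    return Q1, Q2, R_V1, R_V2


def diameter_rate(Q1: float, Q2: float, D: float, vessel: VesselParams) -> float:
    """dD/dt = 2(Q1 − Q2)/(π·D·L_v) for a cylinder of fixed axial length."""
    if D <= 0:
        raise ValueError("diameter must be > 0")
    return 2.0 * (Q1 - Q2) / (math.pi * D * vessel.L_v)


def wall_pressure(D: float, F: float, tl: TubeLawParams,
                  vessel: VesselParams) -> float:
    """Mid-lymphangion pressure from the circumferential wall-force balance.

    p_m = p_ext + f_pas(D) + 2F/(D·L_v): a Laplace-type closure in which the
    circumferential cells in series all carry tension F.  With zero CE
    force the remaining F is the cell viscoelastic contribution, recovering
    the zero-intrinsic-force balance.
    """
    if D <= 0:
        raise ValueError("diameter must be > 0")
    return vessel.p_ext + passive_tube_law(D, tl) + 2.0 * F / (D * vessel.L_v)


def cell_length_from_diameter(D: float, N_Cell: int) -> float:
    """Circumferential length balance L_Cell = π·D/N_Cell."""
    if D <= 0:
        raise ValueError("diameter must be > 0")
    return math.pi * D / N_Cell


def ejection_fraction(Dmax: float, Dmin: float) -> float:
    """EF = 100·(Dmax² − Dmin²)/Dmax² (%)."""
    if Dmin <= 0 or Dmax < Dmin:
        raise ValueError("need Dmax >= Dmin > 0")
    return 100.0 * (Dmax ** 2 - Dmin ** 2) / Dmax ** 2


def fluid_energy_rates(Q1: float, Q2: float, D: float, vessel: VesselParams,
                       cp: CellMechParams | None = None) -> dict[str, float]:
    """Useful fluid work rate and lymph viscous loss rate (erg/s).

    dE_fluid/dt = Q2·(p_b − p_a);
    dE_lymph/dt = 64·μ·L_v/(π·D³)·(Q1² + Q2²) — the D³ denominator of the reference
    formulation is kept even though the flow resistance itself scales with D⁴.
    """
    dE_fluid = Q2 * (vessel.p_b - vessel.p_a)
    dE_lymph = (64.0 * vessel.mu_lymph * vessel.L_v / (math.pi * D ** 3)
                * (Q1 ** 2 + Q2 ** 2))
    return {"dE_fluid": dE_fluid, "dE_lymph": dE_lymph}
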