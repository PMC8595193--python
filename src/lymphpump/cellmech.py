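"""Cell-scale force network.

Each of the ``N_Rows`` parallel rows holds ``N_P`` phasic and ``N_T`` tonic
contractile elements (CEs) in series, with a strain-stiffening spring in
parallel with the phasic CEs and a Newtonian dashpot in parallel with the
tonic CEs.  The cell adds a Kelvin–Voigt viscoelastic element in parallel
with the rows.  Velocities are positive in shortening.

The series force balance
``F_Row = F_P + E_P·(N_P·Y_P − N_P·Y_P,ref) = F_T + μ_T·N_T·dY_T/dt``
is solved for dY_T/dt; the tonic shortening velocity is therefore
``v_T = −dY_T/dt = (F_T − F_P − spring)/(μ_T·N_T)``.  (Solving the velocity
equation with the opposite sign, as sometimes written, is inconsistent
with the force balance itself; the balance is authoritative —
with it, both expressions for F_Row agree identically and the spring acts
as a restoring element.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .params import CEGeometry, CellMechParams

__all__ = ["CellState", "phasic_spring_stiffness", "spring_force",
           "row_velocities", "row_force", "cell_force", "loss_rates"]


@dataclass
class CellState:
    """Lengths, velocities, and force decomposition of one muscle cell."""

    Y_P: float              # phasic CE length, cm
    Y_T: float              # tonic CE length, cm
    L_Cell: float           # cell length, cm
    dLdt: float = 0.0       # cell length rate, cm/s
    v_P: float = 0.0        # phasic shortening velocity, cm/s
    v_T: float = 0.0        # tonic shortening velocity, cm/s
    F_P: float = 0.0        # per-CE phasic force, dyne
    F_T: float = 0.0        # per-CE tonic force, dyne
    F_Row: float = 0.0      # row force, dyne
    F: float = 0.0          # total cell force, dyne

    def length_closure_residual(self, geom: CEGeometry) -> float:
        """Relative residual of N_P·Y_P + N_T·Y_T = L_Cell."""
        return abs(geom.N_P * self.Y_P + geom.N_T * self.Y_T - self.L_Cell) \
            / self.L_Cell

    def validate(self, geom: CEGeometry, tol: float = 1e-12) -> None:
        if self.Y_P <= 0 or self.Y_T <= 0 or self.L_Cell <= 0:
            raise ValueError("lengths must be positive")
        if self.length_closure_residual(geom) > tol:
            raise ValueError("series length closure violated")


def phasic_spring_stiffness(Y_P: float, cp: CellMechParams, N_P: int) -> float:
    """Strain-stiffening spring E_P = a·exp(b·N_P·Y_P) (dyne/cm)."""
    if Y_P <= 0:
        raise ValueError("Y_P must be > 0")
    return cp.a * math.exp(cp.b * N_P * Y_P)


def spring_force(Y_P: float, cp: CellMechParams, N_P: int) -> float:
    """Phasic parallel-spring force E_P·(N_P·Y_P − N_P·Y_P,ref) (dyne)."""
    if cp.YP_ref is None:
        raise ValueError("reference lengths not initialized")
    E_P = phasic_spring_stiffness(Y_P, cp, N_P)
    return E_P * (N_P * Y_P - N_P * cp.YP_ref)


def row_velocities(F_P: float, F_T: float, Y_P: float, dLdt: float,
                   cp: CellMechParams, geom: CEGeometry) -> tuple[float, float]:
    """(v_T, v_P), both positive in shortening.

    v_T comes from the row force balance; v_P from differentiating the
    series length closure, so that N_P·Y_P + N_T·Y_T tracks L_Cell exactly.
    """
    spr = spring_force(Y_P, cp, geom.N_P)
    v_T = (F_T - F_P - spr) / (cp.mu_T * geom.N_T)
    dYT_dt = -v_T
    dYP_dt = (dLdt - geom.N_T * dYT_dt) / geom.N_P
    v_P = -dYP_dt
    return v_T, v_P


def row_force(F_P: float, F_T: float, Y_P: float, dYT_dt: float,
              cp: CellMechParams, geom: CEGeometry,
              rtol: float = 1e-8) -> float:
    """Row force via the phasic side, checked against the tonic side.

    A residual beyond ``rtol`` (relative) signals an integration fault.
    """
    phasic_side = F_P + spring_force(Y_P, cp, geom.N_P)
    tonic_side = F_T + cp.mu_T * geom.N_T * dYT_dt
    scale = max(abs(phasic_side), abs(tonic_side), 1e-30)
    if abs(phasic_side - tonic_side) > rtol * scale:
        raise ValueError(
            f"row force balance violated: phasic side {phasic_side:.6e} vs "
            f"tonic side {tonic_side:.6e}")
    return phasic_side


def cell_force(F_Row: float, L_Cell: float, dLdt: float,
               cp: CellMechParams) -> float:
    """Total cell force F = N_Rows·F_Row + E_Cell·(L−L_ref) + μ_Cell·dL/dt."""
    if cp.LCell_ref is None:
        raise ValueError("reference lengths not initialized")
    return (cp.N_Rows * F_Row + cp.E_Cell * (L_Cell - cp.LCell_ref)
            + cp.mu_Cell * dLdt)


def loss_rates(dYT_dt: float, dLdt: float, F: float,
               cp: CellMechParams, geom: CEGeometry) -> dict[str, float]:
    """Viscous loss rates and the muscle work rate (erg/s), lymphangion
    totals over all cells.

    dW/dt = −dL/dt·N_Cell·F is positive when the cell shortens against a
    positive (contractile) force.
    """
    return {
        "dE_TDloss": cp.N_Rows * cp.N_Cell * cp.mu_T * (geom.N_T * dYT_dt) ** 2,
        "dE_CSloss": cp.N_Cell * cp.mu_Cell * dLdt ** 2,
        "dW": -dLdt * cp.N_Cell * F,
    }
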