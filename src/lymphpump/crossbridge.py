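"""Displacement-dependent transition rates, bound-state bookkeeping, force
integrals, and energy-liberation integrands for both myosin isoforms.

Sign convention: positive displacement ``x`` produces contractile force;
shortening velocity ``v > 0`` convects the bound-head distribution toward
smaller ``x``.

The piecewise-linear rate branches are joined across windows of half-width
``dx_trans`` centred on the rate-transition points.  The default
``mode="smooth"`` uses a half-cosine blend that exactly matches the branch
values at both window endpoints (C0 continuity everywhere);
``mode="literal"`` evaluates the part-sine expressions of the reference
formulation verbatim,
which do not meet the adjacent branches at the endpoints and is provided
for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CEGeometry, CellMechParams, PhasicRateParams, TonicRateParams
from .transport import DisplacementGrid, moment

__all__ = [
    "PhasicState", "TonicState", "RateField",
    "phasic_attach_rate", "phasic_detach_rate",
    "tonic_attach_rate", "tonic_phos_detach_rate", "tonic_latch_detach_rate",
    "tonic_rate_matrix", "build_rate_field",
    "phasic_force", "tonic_force", "energy_liberation_rates",
]


@dataclass
class PhasicState:
    """Bound fraction of phasic heads per displacement bin."""

    n: np.ndarray

    def validate(self, tol: float = 1e-8) -> None:
        if np.any(self.n < -tol) or np.any(self.n > 1.0 + tol):
            raise ValueError("phasic bound fractions must lie in [0, 1]")


@dataclass
class TonicState:
    """Four-state fractions (M, Mp, AMp, AM) per displacement bin."""

    M: np.ndarray
    Mp: np.ndarray
    AMp: np.ndarray
    AM: np.ndarray

    def stack(self) -> np.ndarray:
        return np.stack([self.M, self.Mp, self.AMp, self.AM])

    def validate(self, tol: float = 1e-8, sum_tol: float = 1e-10) -> None:
        y = self.stack()
        if np.any(y < -tol):
            raise ValueError("tonic state fractions must be >= 0")
        total = y.sum(axis=0)
        if np.any(np.abs(total - 1.0) > sum_tol):
            raise ValueError("tonic per-bin state fractions must sum to 1")


def _blend(x, lo, hi, v_lo, v_hi):
    """Half-cosine interpolation matching ``v_lo`` at ``lo`` and ``v_hi`` at ``hi``."""
    w = 0.5 * (1.0 - np.cos(np.pi * (x - lo) / (hi - lo)))
    return (1.0 - w) * v_lo + w * v_hi


def phasic_attach_rate(x, S_Trop: float, pr: PhasicRateParams,
                       mode: str = "smooth"):
    """Attachment rate f(x) of phasic heads (1/s)."""
    h, dx = pr.h, pr.dx_trans
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    lin = (x >= 0.0) & (x < h - dx)
    out[lin] = pr.f1 * x[lin] / h
    win = (x >= h - dx) & (x <= h + dx)
    if mode == "smooth":
        out[win] = _blend(x[win], h - dx, h + dx, pr.f1 * (h - dx) / h, 0.0)
    elif mode == "literal":
        out[win] = pr.f1 * 0.9 * (np.sin(2.0 * np.pi * x[win] / (0.4 * h)) / 2.0 + 0.5)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out *= S_Trop
    return float(out) if out.ndim == 0 else out


def phasic_detach_rate(x, pr: PhasicRateParams, mode: str = "smooth"):
    """Detachment rate g(x) of phasic heads (1/s)."""
    h, dx = pr.h, pr.dx_trans
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    out[x < -dx] = pr.g2
    win = (x >= -dx) & (x <= dx)
    if mode == "smooth":
        out[win] = _blend(x[win], -dx, dx, pr.g2, pr.g1 * dx / h)
    elif mode == "literal":
        out[win] = ((pr.g2 - 0.1 * pr.g1) *
                    (np.sin(2.0 * np.pi * x[win] / (0.4 * h) - np.pi) / 2.0 + 0.5)
                    + 0.1 * pr.g1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lin = (x > dx) & (x <= h)
    out[lin] = pr.g1 * x[lin] / h
    out[x > h] = pr.g1
    return float(out) if out.ndim == 0 else out


def _ramp_with_drop(x, slope_over_h: float, h: float, dx: float):
    """Ramp slope·x/h on [0, h−dx], half-cosine drop to zero across [h−dx, h+dx]."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    lin = (x >= 0.0) & (x < h - dx)
    out[lin] = slope_over_h * x[lin] / h
    win = (x >= h - dx) & (x <= h + dx)
    out[win] = _blend(x[win], h - dx, h + dx, slope_over_h * (h - dx) / h, 0.0)
    return out


def _detach_shape(x, k_neg: float, k_slope: float, k_slope_hi: float,
                  h: float, dx: float):
    """Plateau k_neg for x<−dx, ramp k_slope·x/h on (dx, h−dx), steeper ramp
    k_slope_hi·x/h beyond the powerstroke, half-cosine joins at both windows."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    out[x < -dx] = k_neg
    win0 = (x >= -dx) & (x <= dx)
    out[win0] = _blend(x[win0], -dx, dx, k_neg, k_slope * dx / h)
    lin = (x > dx) & (x < h - dx)
    out[lin] = k_slope * x[lin] / h
    winh = (x >= h - dx) & (x <= h + dx)
    out[winh] = _blend(x[winh], h - dx, h + dx,
                       k_slope * (h - dx) / h, k_slope_hi * (h + dx) / h)
    hi = x > h + dx
    out[hi] = k_slope_hi * x[hi] / h
    return out


def tonic_attach_rate(x, tr: TonicRateParams, h: float, dx: float):
    """Mp → AMp attachment rate k3(x) (1/s); zero outside [0, h+dx]."""
    out = _ramp_with_drop(x, tr.K3_1, h, dx)
    return float(out) if out.ndim == 0 else out


def tonic_phos_detach_rate(x, tr: TonicRateParams, h: float, dx: float):
    """AMp → Mp detachment rate k4(x): K4_2 plateau for x<0, K4_1 ramp on
    (0,h], enhanced K4_3 slope beyond the powerstroke."""
    out = _detach_shape(x, tr.K4_2, tr.K4_1, tr.K4_3, h, dx)
    return float(out) if out.ndim == 0 else out


def tonic_latch_detach_rate(x, tr: TonicRateParams, h: float, dx: float):
    """AM → M latch detachment rate k7(x); same shape as k4 with K7 constants."""
    out = _detach_shape(x, tr.K7_2, tr.K7_1, tr.K7_3, h, dx)
    return float(out) if out.ndim == 0 else out


def tonic_rate_matrix(x, S_CaM: float, tr: TonicRateParams,
                      h: float, dx: float) -> np.ndarray:
    """4-state generator at displacement(s) ``x``, state order (M, Mp, AMp, AM).

    Columns are source states and sum to zero (probability conservation).
    Returns shape (4, 4) for scalar ``x``, else (4, 4, len(x)).
    """
    if not (0.0 <= S_CaM <= 1.0):
        raise ValueError("S_CaM must lie in [0, 1]")
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    nbin = xs.shape[0]
    k1 = S_CaM * tr.K1
    k6 = S_CaM * tr.K6
    k3 = np.asarray(tonic_attach_rate(xs, tr, h, dx))
    k4 = np.asarray(tonic_phos_detach_rate(xs, tr, h, dx))
    k7 = np.asarray(tonic_latch_detach_rate(xs, tr, h, dx))
    A = np.zeros((4, 4, nbin))
    A[1, 0] = k1
    A[0, 1] = tr.K2
    A[2, 1] = k3
    A[1, 2] = k4
    A[3, 2] = tr.K5
    A[2, 3] = k6
    A[0, 3] = k7
    for j in range(4):
        A[j, j] = -A[:, j].sum(axis=0)
    if np.ndim(x) == 0:
        return A[:, :, 0]
    return A


@dataclass
class RateField:
    """Per-bin rate arrays plus the calcium-gated scalar rates for one step."""

    f: np.ndarray   # phasic attachment (already S_Trop-scaled)
    g: np.ndarray   # phasic detachment
    k3: np.ndarray  # Mp → AMp
    k4: np.ndarray  # AMp → Mp
    k7: np.ndarray  # AM → M
    k1: float       # M → Mp (S_CaM-scaled)
    k2: float
    k5: float
    k6: float       # AM → AMp (S_CaM-scaled)


def build_rate_field(grid: DisplacementGrid, S_Trop: float, S_CaM: float,
                     pr: PhasicRateParams, tr: TonicRateParams,
                     mode: str = "smooth") -> RateField:
    """Evaluate all displacement-dependent rates on the grid centers."""
    x = grid.centers
    return RateField(
        f=np.asarray(phasic_attach_rate(x, S_Trop, pr, mode)),
        g=np.asarray(phasic_detach_rate(x, pr, mode)),
        k3=np.asarray(tonic_attach_rate(x, tr, pr.h, pr.dx_trans)),
        k4=np.asarray(tonic_phos_detach_rate(x, tr, pr.h, pr.dx_trans)),
        k7=np.asarray(tonic_latch_detach_rate(x, tr, pr.h, pr.dx_trans)),
        k1=S_CaM * tr.K1, k2=tr.K2, k5=tr.K5, k6=S_CaM * tr.K6,
    )


def phasic_force(n: np.ndarray, grid: DisplacementGrid, geom: CEGeometry) -> float:
    """Force per phasic CE (dyne): rho·Num_P·K_P·∫ x·n dx."""
    return geom.rho * geom.Num_P * geom.K_P * moment(n, grid, weight="x")


def tonic_force(AMp: np.ndarray, AM: np.ndarray, grid: DisplacementGrid,
                geom: CEGeometry) -> float:
    """Force per tonic CE (dyne): rho·Num_T·K_T·(∫x·AMp dx + ∫x·AM dx)."""
    return geom.rho * geom.Num_T * geom.K_T * (
        moment(AMp, grid, weight="x") + moment(AM, grid, weight="x"))


def energy_liberation_rates(phasic: PhasicState | np.ndarray,
                            tonic: TonicState,
                            rates: RateField,
                            grid: DisplacementGrid,
                            geom: CEGeometry,
                            cellp: CellMechParams) -> dict[str, float]:
    """ATP energy liberation rates (erg/s) for the whole lymphangion.

    One ATP is hydrolysed per detachment and per phosphorylation event; the
    tonic total is by construction the sum of its four components.
    """
    n = phasic.n if isinstance(phasic, PhasicState) else phasic
    pre_P = (cellp.N_Cell * cellp.N_Rows * geom.rho * cellp.u *
             geom.Num_P * geom.N_P)
    pre_T = (cellp.N_Cell * geom.rho * cellp.u * cellp.N_Rows *
             geom.Num_T * geom.N_T)
    dE_P = pre_P * moment(rates.g * n, grid)
    phos_detach = pre_T * moment(rates.k4 * tonic.AMp, grid)
    unphos_detach = pre_T * moment(rates.k7 * tonic.AM, grid)
    detach_phos = pre_T * rates.k1 * moment(tonic.M, grid)
    attach_phos = pre_T * rates.k6 * moment(tonic.AM, grid)
    dE_T = phos_detach + unphos_detach + detach_phos + attach_phos
    return {
        "dEnergy_P": dE_P,
        "dEnergy_T_PhosDetach": phos_detach,
        "dEnergy_T_UnphosDetach": unphos_detach,
        "dEnergy_T_DetachPhos": detach_phos,
        "dEnergy_T_AttachPhos": attach_phos,
        "dEnergy_T": dE_T,
    }


def export_state_csv(path, grid: DisplacementGrid, n: np.ndarray,
                     tonic: TonicState) -> None:
    """Per-bin snapshot (x, n, M, Mp, AMp, AM) for distribution plots."""
    arr = np.column_stack([grid.centers, n, tonic.M, tonic.Mp, tonic.AMp,
                           tonic.AM])
    np.savetxt(path, arr, delimiter=",",
               header="x [cm],n [-],M [-],Mp [-],AMp [-],AM [-]", comments="")
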