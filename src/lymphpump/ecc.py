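"""Excitation–contraction coupling.

Prescribed periodic calcium transient, quasi-steady Hill saturations of
troponin-C and calmodulin, and the resulting scaling of the
attachment/phosphorylation rate constants.  Saturations are computed once
per time step and shared by all contractile elements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import CalciumParams, PhasicRateParams, RegulationParams, TonicRateParams


@dataclass
class CalciumTrace:
    """Point sample of the calcium drive: concentration and saturations."""

    t_p: float
    c: float        # µM
    S_Trop: float
    S_CaM: float


def calcium_transient(t_p, cp: CalciumParams):
    """Free calcium concentration (µM) at time ``t_p`` since cycle start.

    Pulse branch before ``t_Osc``; sinusoidal oscillation about the
    diastolic level afterwards.  ``t_p`` may be a scalar or array; the
    caller is responsible for wrapping absolute time into [0, cycletime).
    """
    t = np.asarray(t_p, dtype=float)
    if np.any(t < 0) or np.any(t >= cp.cycletime):
        raise ValueError("t_p must lie in [0, cycletime); wrap time before calling")
    t6 = t ** 6
    pulse = (cp.Ca_amp - cp.Ca_d) * cp.a2 / (cp.b2 - cp.a2) * (
        np.exp(-cp.a2 * t6) - np.exp(-cp.b2 * t6)) + cp.Ca_d
    osc = cp.Ca_d * (1.0 + cp.Osc_Amp *
                     np.sin(cp.omega_Osc * 2.0 * np.pi * (t - cp.t_Osc)))
    out = np.where(t < cp.t_Osc, pulse, osc)
    if np.ndim(t_p) == 0:
        return float(out)
    return out


def check_transient_continuity(cp: CalciumParams, tol_uM: float = 1.0e-3) -> float:
    """Gap |c(t_Osc⁻) − c(t_Osc⁺)| in µM; warns when it exceeds ``tol_uM``.

    The two branches of the transient only join continuously if the pulse
    has decayed back to the diastolic level by ``t_Osc``.
    """
    if cp.t_Osc <= 0.0 or cp.t_Osc >= cp.cycletime:
        return 0.0
    eps = 1e-9 * cp.cycletime
    gap = abs(calcium_transient(cp.t_Osc - eps, cp) -
              calcium_transient(cp.t_Osc, cp))
    if gap >= tol_uM:
        warnings.warn(
            f"calcium transient discontinuous at t_Osc: gap {gap*1e3:.3f} nM",
            stacklevel=2)
    return gap


def hill_saturation(c, c05: float, nm: float):
    """Hill saturation cⁿ/(cⁿ + c05ⁿ), monotone increasing, in [0, 1)."""
    if c05 <= 0 or nm <= 0:
        raise ValueError("c05 and nm must be > 0")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    r = (c / c05) ** nm
    out = r / (r + 1.0)
    return float(out) if out.ndim == 0 else out


def saturations(c, reg: RegulationParams):
    """(S_Trop, S_CaM) at concentration ``c`` (µM)."""
    return (hill_saturation(c, reg.c05_Trop, reg.nm_Trop),
            hill_saturation(c, reg.c05_CaM, reg.nm_CaM))


def trace(t_p: float, cp: CalciumParams, reg: RegulationParams) -> CalciumTrace:
    c = calcium_transient(t_p, cp)
    s_trop, s_cam = saturations(c, reg)
    return CalciumTrace(t_p=t_p, c=c, S_Trop=s_trop, S_CaM=s_cam)


@dataclass
class EffectiveRates:
    """Calcium-modulated scalar rates; displacement dependence lives in
    :mod:`lymphpump.crossbridge`."""

    k1: float       # M → Mp phosphorylation, S_CaM·K1
    k2: float       # Mp → M
    k5: float       # AMp → AM
    k6: float       # AM → AMp phosphorylation, S_CaM·K6
    f_scale: float  # S_Trop multiplier on the phasic attachment rate


def modulate_rates(S_Trop: float, S_CaM: float, pr: PhasicRateParams,
                   tr: TonicRateParams) -> EffectiveRates:
    """Scale the calcium-gated rates; detachment rates are unmodified."""
    if not (0.0 <= S_Trop <= 1.0 and 0.0 <= S_CaM <= 1.0):
        raise ValueError("saturations must lie in [0, 1]")
    return EffectiveRates(k1=S_CaM * tr.K1, k2=tr.K2, k5=tr.K5,
                          k6=S_CaM * tr.K6, f_scale=S_Trop)


def omega_from_per_diastole(n_osc: float, cp: CalciumParams) -> float:
    """Convert "oscillations per diastolic period" to omega_Osc in 1/s."""
    diastole = cp.cycletime - cp.t_Osc
    if diastole <= 0:
        raise ValueError("no diastolic period: t_Osc >= cycletime")
    return n_osc / diastole


def export_trace_csv(path, cp: CalciumParams, n: int = 1000) -> None:
    """Write a two-column time (s) / concentration (nM) CSV over one cycle."""
    t = np.linspace(0.0, cp.cycletime, n, endpoint=False)
    c_nM = np.asarray(calcium_transient(t, cp)) * 1.0e3
    arr = np.column_stack([t, c_nM])
    np.savetxt(path, arr, delimiter=",", header="t [s],c [nM]", comments="")
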