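"""Two-stage solution driver.

Stage 1 relaxes the passive (zero muscle force) lymphangion to its
equilibrium diameter with a stiff adaptive integrator.  Stage 2 runs the
fully coupled muscle–lymphangion system with the explicit fixed scheme
(CFL-limited Godunov transport, forward-Euler diameter update) until the
periodicity criteria hold on whole-cycle averages or the cycle cap is
reached.

Per time step the order of operations is: calcium saturations; Godunov
update of both head populations with the current CE velocities; force
integrals; algebraic pressure/flow solve; forward-Euler diameter update;
CE velocities for the next step.  The mid-lymphangion pressure, flows, and
the μ_Cell viscous force term (linear in dD/dt) are solved together
self-consistently, which is what keeps the explicit scheme stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import cellmech, ecc, lymphangion
from .crossbridge import (RateField, phasic_attach_rate, phasic_detach_rate,
                          tonic_attach_rate, tonic_latch_detach_rate,
                          tonic_phos_detach_rate)
from .params import CMH2O, ParameterBundle
from .transport import build_grid, cfl_dt, godunov_step

__all__ = ["CycleMetrics", "PeriodicityReport", "SimulationResult",
           "SimulationDiverged", "Simulation", "equilibrium_diameter",
           "run_to_periodicity"]

#: cm³/s → mL/hr
ML_PER_HR = 3600.0
#: cm³ → nL
NL = 1.0e6
#: cm → µm
UM = 1.0e4


class SimulationDiverged(RuntimeError):
    """Raised when the coupled solve produces a non-finite or collapsed
    state; carries whatever partial output exists."""

    def __init__(self, msg: str, partial=None):
        super().__init__(msg)
        self.partial = partial


@dataclass
class CycleMetrics:
    """Per-cycle summary in presentation units (µm, cmH2O, mL/hr, nL, dyne,
    erg); ``F_*`` traces are lymphangion totals (all rows, all cells)."""

    cycle: int
    EF: float
    Dmax_um: float
    Dmin_um: float
    stroke_volume_nL: float
    mean_Q1_mlhr: float
    mean_Q2_mlhr: float
    peak_Q2_mlhr: float
    peak_pm_cmh2o: float
    min_pm_cmh2o: float
    peak_F_P: float
    peak_F_T: float
    peak_F: float
    Energy_P: float
    Energy_T: float
    W: float
    E_fluid: float
    E_TDloss: float
    E_CSloss: float
    E_lymph: float
    efficiency_cycle: float
    transfer_fraction: float
    overall_efficiency: float
    tonic_force_range_over_mean: float
    mean_F_T: float
    mean_dYT_dt: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PeriodicityReport:
    """Per-cycle values of the three periodicity criteria."""

    flow_mismatch_pct: list[float] = field(default_factory=list)
    yt_drift_cm: list[float] = field(default_factory=list)
    ft_drift_pct: list[float] = field(default_factory=list)
    converged: bool = False
    cycles_run: int = 0
    converged_at: int | None = None

    def criteria_met(self, i: int, rc) -> bool:
        return (self.flow_mismatch_pct[i] < rc.tol_flow_pct
                and self.yt_drift_cm[i] < rc.tol_yt_cm
                and self.ft_drift_pct[i] < rc.tol_ft_pct)


@dataclass
class SimulationResult:
    timeseries: pd.DataFrame
    metrics: CycleMetrics
    report: PeriodicityReport
    cycles: list[CycleMetrics]
    D0: float
    params: ParameterBundle


def equilibrium_diameter(params: ParameterBundle, tol: float = 1e-9,
                         t_max: float = 2.0e4) -> float:
    """Resting (zero muscle force) equilibrium diameter D0 (cm).

    Relaxes dD/dt of the passive system from D_init with a stiff adaptive
    integrator until |dD/dt| < ``tol`` cm/s.
    """
    v = params.vessel

    def rhs(t, y):
        D = y[0]
        if D <= 0:
            return [0.0]
        p_m = lymphangion.wall_pressure(D, 0.0, v.tube_law, v)
        Q1, Q2, _, _ = lymphangion.flows(v.p_a, p_m, v.p_b, D, v)
        return [lymphangion.diameter_rate(Q1, Q2, D, v)]

    def settled(t, y):
        return abs(rhs(t, y)[0]) - tol
    settled.terminal = True

    if abs(rhs(0.0, [v.D_init])[0]) < tol:
        return v.D_init
    sol = solve_ivp(rhs, (0.0, t_max), [v.D_init], method="BDF",
                    events=settled, rtol=1e-10, atol=1e-14)
    if not sol.success:
        raise RuntimeError(f"equilibrium relaxation failed: {sol.message}")
    if sol.status != 1:
        raise RuntimeError("no passive equilibrium found within the time bracket")
    return float(sol.y[0, -1])


def _tube_law_scalar(D: float, tl) -> float:
    return tl.P_d * (math.exp(tl.s_d * (D / tl.D_d - 1.0))
                     - tl.c_collapse * (tl.D_d / D) ** 3)


def _rv_scalar(dp: float, vp) -> float:
    z = vp.s_o * (dp - vp.dp_o)
    if z > 700.0:
        return vp.R_Vn
    if z < -700.0:
        return vp.R_Vn + vp.R_Vx
    return vp.R_Vn + vp.R_Vx / (1.0 + math.exp(z))


def _valve_drop_scalar(dp_tot: float, Rh: float, vp, guess: float) -> float:
    """Local valve drop: root of g(dp) = dp·(R(dp)+Rh) − dp_tot·R(dp),
    strictly increasing on the bracket [0, dp_tot]; safeguarded Newton."""
    if dp_tot == 0.0:
        return 0.0
    lo, hi = (0.0, dp_tot) if dp_tot > 0 else (dp_tot, 0.0)
    dp = min(max(guess, lo), hi)
    tol = 1e-12 * max(1.0, abs(dp_tot))
    for _ in range(100):
        z = vp.s_o * (dp - vp.dp_o)
        if z > 700.0:
            sig = 0.0
        elif z < -700.0:
            sig = 1.0
        else:
            sig = 1.0 / (1.0 + math.exp(z))
        R = vp.R_Vn + vp.R_Vx * sig
        g = dp * (R + Rh) - dp_tot * R
        if g > 0:
            hi = dp
        else:
            lo = dp
        if abs(g) <= tol * (R + Rh) or hi - lo <= tol:
            return dp
        dR = -vp.s_o * vp.R_Vx * sig * (1.0 - sig)
        dg = R + Rh + (dp - dp_tot) * dR
        step_ok = dg > 0
        if step_ok:
            dp_new = dp - g / dg
            if not (lo < dp_new < hi):
                step_ok = False
        if not step_ok:
            dp_new = 0.5 * (lo + hi)
        dp = dp_new
    return dp


class _StepRejected(Exception):
    """Internal: a trial step changed the diameter too much; retry smaller."""

    def __init__(self, dDdt: float):
        self.dDdt = dDdt


class Simulation:
    """Coupled muscle–lymphangion simulation engine."""

    #: per-step relative diameter change allowed (stiff-start safeguard)
    MAX_REL_DD = 0.01
    #: target per-step relative diameter change used for the adaptive cap
    TARGET_REL_DD = 2.0e-3

    def __init__(self, params: ParameterBundle, rate_mode: str = "smooth"):
        params.validate()
        self.p = params
        self.rate_mode = rate_mode
        pr, tr = params.phasic, params.tonic
        self.grid = build_grid(params.run, pr.h)
        x = self.grid.centers
        # static per-bin rate shapes; saturations only scale f, k1, k6
        self.f_base = np.asarray(phasic_attach_rate(x, 1.0, pr, rate_mode))
        self.g_arr = np.asarray(phasic_detach_rate(x, pr, rate_mode))
        self.k3 = np.asarray(tonic_attach_rate(x, tr, pr.h, pr.dx_trans))
        self.k4 = np.asarray(tonic_phos_detach_rate(x, tr, pr.h, pr.dx_trans))
        self.k7 = np.asarray(tonic_latch_detach_rate(x, tr, pr.h, pr.dx_trans))
        geom, cell = params.geometry, params.cell
        self.pre_FP = geom.rho * geom.Num_P * geom.K_P
        self.pre_FT = geom.rho * geom.Num_T * geom.K_T
        self.pre_EP = cell.N_Cell * cell.N_Rows * geom.rho * cell.u \
            * geom.Num_P * geom.N_P
        self.pre_ET = cell.N_Cell * geom.rho * cell.u * cell.N_Rows \
            * geom.Num_T * geom.N_T
        self.total_rows = cell.N_Rows * cell.N_Cell
        # trapezoid weights on the non-uniform centers (matches np.trapezoid)
        wtrap = np.zeros_like(x)
        dxc = np.diff(x)
        wtrap[:-1] += 0.5 * dxc
        wtrap[1:] += 0.5 * dxc
        self.wtrap = wtrap
        self.wtrap_x = wtrap * x
        self.initialized = False

    # -- initialization ---------------------------------------------------
    def initialize(self, D0: float | None = None,
                   init_heads: str = "detached") -> None:
        """Set the stage-2 initial state from the passive equilibrium.

        Heads all detached (tonic all dephosphorylated), CEs at equal
        lengths, reference lengths as the configured fraction of the
        initial lengths.  ``init_heads="steady"`` instead starts both
        populations at their isometric steady state under diastolic
        calcium, which shortens the spin-up (used for calibration runs).
        """
        p = self.p
        if D0 is None:
            D0 = equilibrium_diameter(p)
        self.D0 = D0
        geom, cell = p.geometry, p.cell
        n = self.grid.n
        if init_heads == "detached":
            self.n_P = np.zeros(n)
            self.y_T = np.zeros((4, n))
            self.y_T[0] = 1.0  # all detached, dephosphorylated (state M)
        elif init_heads == "steady":
            c_d = ecc.calcium_transient(0.0, p.calcium)
            S_Trop, S_CaM = ecc.saturations(c_d, p.regulation)
            rf = self._rate_field(S_Trop, S_CaM)
            self.n_P = rf.f / (rf.f + rf.g)
            self.y_T = np.empty((4, n))
            for i in range(n):
                A = np.array([
                    [-rf.k1, rf.k2, 0.0, rf.k7[i]],
                    [rf.k1, -(rf.k2 + rf.k3[i]), rf.k4[i], 0.0],
                    [0.0, rf.k3[i], -(rf.k4[i] + rf.k5), rf.k6],
                    [1.0, 1.0, 1.0, 1.0]])
                self.y_T[:, i] = np.linalg.lstsq(
                    A, np.array([0.0, 0.0, 0.0, 1.0]), rcond=None)[0]
            np.clip(self.y_T, 0.0, 1.0, out=self.y_T)
            self.y_T /= self.y_T.sum(axis=0)
        else:
            raise ValueError(f"unknown init_heads {init_heads!r}")
        self.D = D0
        L0 = lymphangion.cell_length_from_diameter(D0, cell.N_Cell)
        self.L = L0
        Y0 = L0 / (geom.N_P + geom.N_T)
        self.Y_P = Y0
        self.Y_T = Y0
        if cell.YP_ref is None:
            cell.set_reference_lengths(cell.ref_fraction * Y0,
                                       cell.ref_fraction * L0)
        self.dLdt = 0.0
        self.v_P = 0.0
        self.v_T = 0.0
        self.t = 0.0
        self.p_m = lymphangion.wall_pressure(D0, 0.0, p.vessel.tube_law, p.vessel)
        self.R_V1 = float(lymphangion.valve_resistance(p.vessel.p_a - self.p_m,
                                                       p.vessel.valve1))
        self.R_V2 = float(lymphangion.valve_resistance(self.p_m - p.vessel.p_b,
                                                       p.vessel.valve2))
        self.F_P = 0.0
        self.F_T = 0.0
        self.F = 0.0
        self.dDdt_prev = 0.0
        self._dp1_local = p.vessel.p_a - self.p_m
        self._dp2_local = self.p_m - p.vessel.p_b
        self.initialized = True

    def _snapshot(self) -> dict:
        return {"n_P": self.n_P.copy(), "y_T": self.y_T.copy(),
                "D": self.D, "L": self.L, "Y_P": self.Y_P, "Y_T": self.Y_T,
                "dLdt": self.dLdt, "v_P": self.v_P, "v_T": self.v_T,
                "t": self.t, "p_m": self.p_m, "R_V1": self.R_V1,
                "R_V2": self.R_V2, "dDdt_prev": self.dDdt_prev}

    def _restore(self, snap: dict) -> None:
        for key, val in snap.items():
            setattr(self, key, val)

    # -- per-step physics -------------------------------------------------
    def _rate_field(self, S_Trop: float, S_CaM: float) -> RateField:
        tr = self.p.tonic
        return RateField(f=S_Trop * self.f_base, g=self.g_arr, k3=self.k3,
                         k4=self.k4, k7=self.k7, k1=S_CaM * tr.K1, k2=tr.K2,
                         k5=tr.K5, k6=S_CaM * tr.K6)

    def _pressure_flow(self, D: float, F0: float):
        """Self-consistent p_m, flows, valve resistances, and dD/dt.

        ``F0`` is the cell force without its μ_Cell·dL/dt term; that term
        is linear in dD/dt, so p_m = P0 + β·dD/dt with dD/dt set by the
        flow balance at p_m.  The residual is strictly increasing in p_m;
        the unique root is found by a warm-started, bracketed
        Newton–bisection (same physics as :func:`lymphangion.flows`, on a
        scalar fast path — the two are cross-checked in the test suite).
        """
        p = self.p
        v = p.vessel
        cell = p.cell
        P0 = v.p_ext + _tube_law_scalar(D, v.tube_law) \
            + 2.0 * F0 / (D * v.L_v)
        beta = 2.0 * cell.mu_Cell * math.pi / (cell.N_Cell * D * v.L_v)
        geo = 2.0 / (math.pi * D * v.L_v)
        Rh = 64.0 * v.mu_lymph * v.L_v / (math.pi * D ** 4)

        dp1_guess = self._dp1_local
        dp2_guess = self._dp2_local

        def parts(p_m: float):
            nonlocal dp1_guess, dp2_guess
            dp1_guess = _valve_drop_scalar(v.p_a - p_m, Rh, v.valve1,
                                           dp1_guess)
            R_V1 = _rv_scalar(dp1_guess, v.valve1)
            Q1 = (v.p_a - p_m) / (R_V1 + Rh)
            dp2_guess = _valve_drop_scalar(p_m - v.p_b, Rh, v.valve2,
                                           dp2_guess)
            R_V2 = _rv_scalar(dp2_guess, v.valve2)
            Q2 = (p_m - v.p_b) / (R_V2 + Rh)
            return Q1, Q2, R_V1, R_V2, geo * (Q1 - Q2)

        def res(p_m: float) -> float:
            *_, dDdt = parts(p_m)
            return p_m - (P0 + beta * dDdt)

        guess = self.p_m
        r0 = res(guess)
        tol = 1e-10 * max(1.0, abs(guess))
        if abs(r0) > tol:
            # expand a bracket around the previous pressure (res slope >= 1)
            step = max(1.0, abs(r0))
            lo, hi = guess, guess
            rlo = rhi = r0
            for _ in range(200):
                if r0 > 0:
                    hi, rhi = guess, r0
                    lo = lo - step
                    rlo = res(lo)
                    if rlo <= 0:
                        break
                else:
                    lo, rlo = guess, r0
                    hi = hi + step
                    rhi = res(hi)
                    if rhi >= 0:
                        break
                step *= 4.0
            else:
                raise RuntimeError("pressure bracket expansion failed")
            # Illinois false position on the monotone residual, with a
            # bisection step every other iteration (false position alone
            # creeps at the near-vertical valve-transition segment)
            side = 0
            for it in range(200):
                if it % 2:
                    mid = 0.5 * (lo + hi)
                else:
                    mid = (lo * rhi - hi * rlo) / (rhi - rlo)
                    if not (lo < mid < hi):
                        mid = 0.5 * (lo + hi)
                r = res(mid)
                if r > 0:
                    hi, rhi = mid, r
                    if side == 1:
                        rlo *= 0.5
                    side = 1
                else:
                    lo, rlo = mid, r
                    if side == -1:
                        rhi *= 0.5
                    side = -1
                guess, r0 = mid, r
                # tolerance must stay above the ulp of the bracket scale
                # (transients can push the balance to ~1e12 dyne/cm²)
                tol_eff = max(tol, 1e-12 * (abs(lo) + abs(hi)))
                if abs(r) <= tol_eff or hi - lo <= tol_eff:
                    break
            else:
                raise RuntimeError("pressure solve did not converge")
        p_m = guess
        Q1, Q2, R_V1, R_V2, dDdt = parts(p_m)
        self._dp1_local, self._dp2_local = dp1_guess, dp2_guess
        return p_m, Q1, Q2, R_V1, R_V2, dDdt

    def step(self, dt: float, t_p: float) -> dict:
        """Advance one explicit step of size ``dt``; returns the step record."""
        p = self.p
        geom, cell, v = p.geometry, p.cell, p.vessel
        # (1) excitation–contraction coupling (scalar fast path; identical
        # math to ecc.calcium_transient / ecc.saturations, cross-checked
        # in the test suite)
        cp, reg = p.calcium, p.regulation
        if t_p < cp.t_Osc:
            t6 = t_p ** 6
            c = (cp.Ca_amp - cp.Ca_d) * cp.a2 / (cp.b2 - cp.a2) * (
                math.exp(-cp.a2 * t6) - math.exp(-cp.b2 * t6)) + cp.Ca_d
        else:
            c = cp.Ca_d * (1.0 + cp.Osc_Amp * math.sin(
                cp.omega_Osc * 2.0 * math.pi * (t_p - cp.t_Osc)))
        rt = (c / reg.c05_Trop) ** reg.nm_Trop
        S_Trop = rt / (rt + 1.0)
        rcm = (c / reg.c05_CaM) ** reg.nm_CaM
        S_CaM = rcm / (rcm + 1.0)
        rf = self._rate_field(S_Trop, S_CaM)

        # (2) Godunov update of both populations with current velocities
        f_arr, g_arr = rf.f, rf.g
        k3, k4, k7 = rf.k3, rf.k4, rf.k7
        k1, k2, k5, k6 = rf.k1, rf.k2, rf.k5, rf.k6

        def react_phasic(u):
            return (1.0 - u) * f_arr - u * g_arr

        def react_tonic(y):
            M, Mp, AMp, AM = y
            out = np.empty_like(y)
            out[0] = -k1 * M + k2 * Mp + k7 * AM
            out[1] = k1 * M - (k2 + k3) * Mp + k4 * AMp
            out[2] = k3 * Mp - (k4 + k5) * AMp + k6 * AM
            out[3] = k5 * AMp - (k6 + k7) * AM
            return out

        self.n_P = godunov_step(self.n_P, self.v_P, dt, self.grid,
                                reaction=react_phasic, inflow=0.0, check=False)
        mfrac = k2 / (k1 + k2)
        self.y_T = godunov_step(self.y_T, self.v_T, dt, self.grid,
                                reaction=react_tonic,
                                inflow=np.array([mfrac, 1.0 - mfrac, 0.0, 0.0]),
                                check=False, normalize_sum=True)
        if not (np.isfinite(self.n_P[0]) and np.isfinite(self.y_T[0, 0])):
            raise SimulationDiverged("head populations became non-finite")

        # (3) forces from the updated populations
        F_P = self.pre_FP * float(np.dot(self.wtrap_x, self.n_P))
        F_T = self.pre_FT * float(np.dot(self.wtrap_x,
                                         self.y_T[2] + self.y_T[3]))
        spr = cellmech.spring_force(self.Y_P, cell, geom.N_P)
        F_Row = F_P + spr
        F0 = cell.N_Rows * F_Row + cell.E_Cell * (self.L - cell.LCell_ref)

        # (4) algebraic pressures/flows (μ_Cell term solved implicitly)
        p_m, Q1, Q2, R_V1, R_V2, dDdt = self._pressure_flow(self.D, F0)

        # (5) forward-Euler diameter update
        D_new = self.D + dt * dDdt
        if not math.isfinite(D_new) or D_new <= 0 \
                or abs(D_new - self.D) > self.MAX_REL_DD * self.D:
            raise _StepRejected(dDdt)
        self.dDdt_prev = dDdt
        L_new = lymphangion.cell_length_from_diameter(D_new, cell.N_Cell)
        dLdt = math.pi * dDdt / cell.N_Cell
        F = F0 + cell.mu_Cell * dLdt

        # (6) CE lengths advance with this step's velocities; new velocities
        # use the same spring state as this step's force balance, so the
        # recorded (F_P, F_T, spring, v_T) tuple satisfies the row force
        # balance identically
        dYT_dt_applied = -self.v_T
        Y_T_new = self.Y_T + dt * dYT_dt_applied
        Y_P_new = (L_new - geom.N_T * Y_T_new) / geom.N_P
        if Y_P_new <= 0 or Y_T_new <= 0:
            raise SimulationDiverged("contractile element length collapsed")
        v_T_new, v_P_new = cellmech.row_velocities(F_P, F_T, self.Y_P, dLdt,
                                                   cell, geom)

        # energy/work rates at this step's state
        energies = {
            "dEnergy_P": self.pre_EP * float(np.dot(self.wtrap,
                                                    g_arr * self.n_P)),
            "dEnergy_T": (self.pre_ET *
                          (float(np.dot(self.wtrap, k4 * self.y_T[2]))
                           + float(np.dot(self.wtrap, k7 * self.y_T[3]))
                           + k1 * float(np.dot(self.wtrap, self.y_T[0]))
                           + k6 * float(np.dot(self.wtrap, self.y_T[3])))),
        }
        losses = cellmech.loss_rates(dYT_dt_applied, dLdt, F, cell, geom)
        fluid = lymphangion.fluid_energy_rates(Q1, Q2, D_new, v)

        rec = {
            "t": self.t + dt, "c": c, "S_Trop": S_Trop, "S_CaM": S_CaM,
            "D": D_new, "p_m": p_m, "Q1": Q1, "Q2": Q2,
            "R_V1": R_V1, "R_V2": R_V2,
            "F_P": F_P, "F_T": F_T, "F_Row": F_Row, "F": F, "spring": spr,
            "v_P": v_P_new, "v_T": v_T_new, "dLdt": dLdt,
            "dYT_dt": dYT_dt_applied,
            **energies, **losses, **fluid,
        }

        self.D, self.L, self.dLdt = D_new, L_new, dLdt
        self.Y_P, self.Y_T = Y_P_new, Y_T_new
        self.v_P, self.v_T = v_P_new, v_T_new
        self.p_m, self.Q1, self.Q2 = p_m, Q1, Q2
        self.R_V1, self.R_V2 = R_V1, R_V2
        self.F_P, self.F_T, self.F = F_P, F_T, F
        self.t += dt
        return rec

    # -- cycle / periodicity loop ----------------------------------------
    def run_cycle(self, cycle_index: int, records: list | None = None) \
            -> CycleMetrics:
        p = self.p
        rc = p.run
        ct = p.calcium.cycletime
        t0 = self.t
        t_end = t0 + ct
        acc = {k: 0.0 for k in ("E_P", "E_T", "W", "E_fluid", "E_TD",
                                "E_CS", "E_lymph", "V1", "V2", "FT_int",
                                "dYT_int")}
        Dmin = Dmax = self.D
        peak = {"Q2": -np.inf, "pm": -np.inf, "pm_min": np.inf,
                "F_P": -np.inf, "F_T": -np.inf, "F": -np.inf}
        FT_min, FT_max = np.inf, -np.inf
        next_rec = t0
        while self.t < t_end - 1e-12:
            dt = cfl_dt(self.v_P, self.v_T, self.grid, rc)
            if self.dDdt_prev != 0.0:
                dt = min(dt, self.TARGET_REL_DD * self.D
                         / abs(self.dDdt_prev))
            dt = min(dt, t_end - self.t)
            t_p = min(self.t - t0, ct * (1.0 - 1e-15))
            snap = self._snapshot()
            for _ in range(60):
                try:
                    rec = self.step(dt, t_p)
                    break
                except _StepRejected:
                    self._restore(snap)
                    dt *= 0.2
            else:
                raise SimulationDiverged(
                    f"no stable step size found at t={self.t:.5f}s")
            acc["E_P"] += dt * rec["dEnergy_P"]
            acc["E_T"] += dt * rec["dEnergy_T"]
            acc["W"] += dt * rec["dW"]
            acc["E_fluid"] += dt * rec["dE_fluid"]
            acc["E_TD"] += dt * rec["dE_TDloss"]
            acc["E_CS"] += dt * rec["dE_CSloss"]
            acc["E_lymph"] += dt * rec["dE_lymph"]
            acc["V1"] += dt * rec["Q1"]
            acc["V2"] += dt * rec["Q2"]
            FT_tot = self.total_rows * rec["F_T"]
            acc["FT_int"] += dt * FT_tot
            acc["dYT_int"] += dt * rec["dYT_dt"]
            Dmin = min(Dmin, rec["D"])
            Dmax = max(Dmax, rec["D"])
            FT_min = min(FT_min, FT_tot)
            FT_max = max(FT_max, FT_tot)
            peak["Q2"] = max(peak["Q2"], rec["Q2"])
            peak["pm"] = max(peak["pm"], rec["p_m"])
            peak["pm_min"] = min(peak["pm_min"], rec["p_m"])
            peak["F_P"] = max(peak["F_P"], self.total_rows * rec["F_P"])
            peak["F_T"] = max(peak["F_T"], FT_tot)
            peak["F"] = max(peak["F"], rec["F"])
            if records is not None and self.t >= next_rec - 1e-12:
                records.append(rec)
                next_rec += rc.record_dt

        mean_FT = acc["FT_int"] / ct
        liberated = acc["E_P"] + acc["E_T"]
        return CycleMetrics(
            cycle=cycle_index,
            EF=lymphangion.ejection_fraction(Dmax, Dmin),
            Dmax_um=Dmax * UM, Dmin_um=Dmin * UM,
            stroke_volume_nL=(math.pi / 4.0) * (Dmax ** 2 - Dmin ** 2)
            * p.vessel.L_v * NL,
            mean_Q1_mlhr=acc["V1"] / ct * ML_PER_HR,
            mean_Q2_mlhr=acc["V2"] / ct * ML_PER_HR,
            peak_Q2_mlhr=peak["Q2"] * ML_PER_HR,
            peak_pm_cmh2o=peak["pm"] / CMH2O,
            min_pm_cmh2o=peak["pm_min"] / CMH2O,
            peak_F_P=peak["F_P"], peak_F_T=peak["F_T"], peak_F=peak["F"],
            Energy_P=acc["E_P"], Energy_T=acc["E_T"], W=acc["W"],
            E_fluid=acc["E_fluid"], E_TDloss=acc["E_TD"],
            E_CSloss=acc["E_CS"], E_lymph=acc["E_lymph"],
            efficiency_cycle=acc["W"] / liberated if liberated > 0 else math.nan,
            transfer_fraction=acc["E_fluid"] / acc["W"]
            if acc["W"] != 0 else math.nan,
            overall_efficiency=acc["E_fluid"] / liberated
            if liberated > 0 else math.nan,
            tonic_force_range_over_mean=(FT_max - FT_min) / mean_FT
            if mean_FT != 0 else math.nan,
            mean_F_T=mean_FT,
            mean_dYT_dt=acc["dYT_int"] / ct,
        )

    def run_to_periodicity(self, store_timeseries: bool = True) \
            -> SimulationResult:
        if not self.initialized:
            self.initialize()
        p = self.p
        rc = p.run
        report = PeriodicityReport()
        cycles: list[CycleMetrics] = []
        records: list[dict] | None = [] if store_timeseries else None
        prev_FT = None
        try:
            for i in range(rc.max_cycles):
                m = self.run_cycle(i, records)
                cycles.append(m)
                q2 = m.mean_Q2_mlhr
                flow_mis = 100.0 * abs((q2 - m.mean_Q1_mlhr) / q2) \
                    if q2 != 0 else math.inf
                yt_drift = abs(m.mean_dYT_dt) * p.calcium.cycletime
                ft_drift = (100.0 * abs((m.mean_F_T - prev_FT) / m.mean_F_T)
                            if prev_FT is not None and m.mean_F_T != 0
                            else math.inf)
                report.flow_mismatch_pct.append(flow_mis)
                report.yt_drift_cm.append(yt_drift)
                report.ft_drift_pct.append(ft_drift)
                report.cycles_run = i + 1
                prev_FT = m.mean_F_T
                if report.criteria_met(i, rc):
                    report.converged = True
                    report.converged_at = i + 1
                    break
        except SimulationDiverged as exc:
            exc.partial = SimulationResult(
                timeseries=pd.DataFrame(records or []),
                metrics=cycles[-1] if cycles else None,
                report=report, cycles=cycles, D0=self.D0, params=p)
            raise
        ts = pd.DataFrame(records) if records is not None else pd.DataFrame()
        return SimulationResult(timeseries=ts, metrics=cycles[-1],
                                report=report, cycles=cycles, D0=self.D0,
                                params=p)


def initialize(params: ParameterBundle, D0: float | None = None) -> Simulation:
    """Build a simulation and set its initial state (module-level surface)."""
    sim = Simulation(params)
    sim.initialize(D0)
    return sim


def run_to_periodicity(params: ParameterBundle,
                       store_timeseries: bool = True) -> SimulationResult:
    """Two-stage solve: passive equilibrium, then cycles to periodicity."""
    sim = Simulation(params)
    sim.initialize()
    return sim.run_to_periodicity(store_timeseries=store_timeseries)
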