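import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp
from scipy.linalg import expm, null_space

from lymphpump import crossbridge as cb
from lymphpump.transport import build_grid, godunov_step, moment


@pytest.fixture
def pr(defaults):
    return defaults.phasic


@pytest.fixture
def tr(defaults):
    return defaults.tonic


@pytest.fixture
def geom(defaults):
    return defaults.geometry


class TestPhasicRates:
    def test_attach_zero_for_negative_displacement(self, pr):
        assert cb.phasic_attach_rate(-pr.h / 4, 1.0, pr) == 0.0
        assert cb.phasic_attach_rate(-10 * pr.h, 0.5, pr) == 0.0

    def test_attach_linear_ramp_midpoint(self, pr):
        # midpoint of the ramp: f1/2 = 310 1/s at full saturation
        assert cb.phasic_attach_rate(pr.h / 2, 1.0, pr) == pytest.approx(310.0)

    def test_attach_zero_beyond_window(self, pr):
        assert cb.phasic_attach_rate(pr.h + 2 * pr.dx_trans, 1.0, pr) == 0.0

    def test_attach_scales_with_saturation(self, pr):
        full = cb.phasic_attach_rate(pr.h / 3, 1.0, pr)
        half = cb.phasic_attach_rate(pr.h / 3, 0.5, pr)
        assert half == pytest.approx(0.5 * full)

    def test_detach_negative_plateau(self, pr):
        assert cb.phasic_detach_rate(-pr.h, pr) == pytest.approx(210.0)

    def test_detach_ramp_midpoint(self, pr):
        assert cb.phasic_detach_rate(pr.h / 2, pr) == pytest.approx(25.0)

    def test_detach_positive_plateau(self, pr):
        assert cb.phasic_detach_rate(2 * pr.h, pr) == pytest.approx(50.0)

    @pytest.mark.parametrize("fn,smax", [
        (lambda x, pr: cb.phasic_attach_rate(x, 1.0, pr), 620.0),
        (cb.phasic_detach_rate, 210.0),
    ])
    def test_continuity_at_breakpoints(self, pr, fn, smax):
        # C0 continuity: evaluate both sides of every breakpoint
        eps = 1e-8 * pr.h
        dx = pr.dx_trans
        for b in (-dx, 0.0, dx, pr.h - dx, pr.h, pr.h + dx):
            jump = abs(fn(b - eps, pr) - fn(b + eps, pr))
            assert jump < 1e-6 * smax, f"jump {jump} at x={b}"

    def test_literal_mode_differs_in_window(self, pr):
        x = pr.h  # middle of the smoothing window
        smooth = cb.phasic_attach_rate(x, 1.0, pr, mode="smooth")
        literal = cb.phasic_attach_rate(x, 1.0, pr, mode="literal")
        assert smooth != literal
        # both modes agree outside the windows
        for xi in (0.3 * pr.h, -pr.h, 2 * pr.h):
            assert cb.phasic_attach_rate(xi, 1.0, pr, "smooth") == \
                cb.phasic_attach_rate(xi, 1.0, pr, "literal")


class TestTonicRates:
    def test_phos_detach_negative_plateau_follows_relation(self, pr, tr):
        # K4_2 = 4(K3_1 + K4_1) = 4.4 1/s
        v = cb.tonic_phos_detach_rate(-5 * pr.dx_trans, tr, pr.h, pr.dx_trans)
        assert v == pytest.approx(4.4)

    def test_latch_detach_shape(self, pr, tr):
        dx = pr.dx_trans
        assert cb.tonic_latch_detach_rate(-2 * dx, tr, pr.h, dx) == \
            pytest.approx(20 * 0.12)
        assert cb.tonic_latch_detach_rate(pr.h / 2, tr, pr.h, dx) == \
            pytest.approx(0.12 / 2)
        # enhanced slope beyond the powerstroke: K7_3·x/h
        assert cb.tonic_latch_detach_rate(2 * pr.h, tr, pr.h, dx) == \
            pytest.approx(3 * 0.12 * 2.0)

    def test_attach_ramp_and_cutoff(self, pr, tr):
        dx = pr.dx_trans
        assert cb.tonic_attach_rate(pr.h / 2, tr, pr.h, dx) == \
            pytest.approx(0.44)
        assert cb.tonic_attach_rate(-pr.h, tr, pr.h, dx) == 0.0
        assert cb.tonic_attach_rate(pr.h + 2 * dx, tr, pr.h, dx) == 0.0

    def test_continuity_at_breakpoints(self, pr, tr):
        eps = 1e-8 * pr.h
        dx = pr.dx_trans
        for fn, smax in ((cb.tonic_attach_rate, 0.88),
                         (cb.tonic_phos_detach_rate, 4.4),
                         (cb.tonic_latch_detach_rate, 2.4)):
            for b in (-dx, 0.0, dx, pr.h - dx, pr.h, pr.h + dx):
                jump = abs(fn(b - eps, tr, pr.h, dx)
                           - fn(b + eps, tr, pr.h, dx))
                assert jump < 1e-6 * smax

    def test_generator_columns_sum_to_zero(self, pr, tr, rng):
        xs = rng.uniform(-2 * pr.h, 2 * pr.h, size=50)
        A = cb.tonic_rate_matrix(xs, 0.7, tr, pr.h, pr.dx_trans)
        assert A.shape == (4, 4, 50)
        assert np.max(np.abs(A.sum(axis=0))) < 1e-12

    def test_generator_k6_at_full_saturation(self, pr, tr):
        A = cb.tonic_rate_matrix(pr.h / 2, 1.0, tr, pr.h, pr.dx_trans)
        assert A[2, 3] == pytest.approx(0.35)   # AM -> AMp, k6 = K6 = K1
        assert A[1, 0] == pytest.approx(0.35)   # M -> Mp, k1 = K1

    def test_generator_off_diagonals_nonnegative(self, pr, tr, rng):
        xs = rng.uniform(-3 * pr.h, 3 * pr.h, size=30)
        A = cb.tonic_rate_matrix(xs, 0.3, tr, pr.h, pr.dx_trans)
        off = A.copy()
        for j in range(4):
            off[j, j] = 0.0
        assert np.min(off) >= 0.0


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def relax_isometric_phasic(grid, pr, S_Trop, T=1.0, dt=2e-4):
    """Relax the phasic PDE at v = 0 to steady state."""
    f = np.asarray(cb.phasic_attach_rate(grid.centers, S_Trop, pr))
    g = np.asarray(cb.phasic_detach_rate(grid.centers, pr))
    n = np.zeros(grid.n)
    steps = int(round(T / dt))
    for _ in range(steps):
        n = godunov_step(n, 0.0, dt, grid,
                         reaction=lambda u: (1.0 - u) * f - u * g)
    return n, f, g


class TestPhasicForce:
    def test_zero_state_zero_force(self, grid, geom):
        assert cb.phasic_force(np.zeros(grid.n), grid, geom) == 0.0

    def test_symmetric_state_near_zero_force(self, grid, geom):
        n = np.exp(-(grid.centers / grid.h) ** 2)
        F = cb.phasic_force(n, grid, geom)
        scale = geom.rho * geom.Num_P * geom.K_P * grid.h ** 2
        assert abs(F) < 1e-3 * scale  # odd integrand on a near-symmetric grid

    def test_isometric_steady_state_matches_analytic_oracle(
            self, grid, pr, geom):
        n, f, g = relax_isometric_phasic(grid, pr, 1.0)
        # per-bin steady state is f/(f+g)
        expected = np.where(f + g > 0, f / np.where(f + g > 0, f + g, 1.0),
                            0.0)
        assert np.max(np.abs(n - expected)) < 1e-8

        # force against an independent quadrature oracle built from the
        # analytic steady state on a fine separate grid
        def n_star(x):
            fa = cb.phasic_attach_rate(x, 1.0, pr)
            ga = cb.phasic_detach_rate(x, pr)
            return fa / (fa + ga) if fa + ga > 0 else 0.0

        val, _ = quad(lambda x: x * n_star(x), 0.0, pr.h + pr.dx_trans,
                      limit=500,
                      points=[pr.dx_trans, pr.h - pr.dx_trans, pr.h])
        F_oracle = geom.rho * geom.Num_P * geom.K_P * val
        F = cb.phasic_force(n, grid, geom)
        assert F == pytest.approx(F_oracle, rel=1e-3)
        # closed form on the linear branches: n* = f1/(f1+g1), constant
        assert n[(grid.centers > 2 * pr.dx_trans)
                 & (grid.centers < pr.h - 2 * pr.dx_trans)] == \
            pytest.approx(620.0 / 670.0, rel=1e-9)


class TestTonicForce:
    def test_zero_attached_zero_force(self, grid, geom):
        z = np.zeros(grid.n)
        assert cb.tonic_force(z, z, grid, geom) == 0.0

    def test_symmetric_attached_near_zero_force(self, grid, geom):
        a = np.exp(-(grid.centers / grid.h) ** 2) * 0.3
        F = cb.tonic_force(a, a, grid, geom)
        scale = geom.rho * geom.Num_T * geom.K_T * grid.h ** 2
        assert abs(F) < 1e-3 * scale

    def test_isometric_steady_state_matches_nullspace_oracle(
            self, grid, pr, tr, geom, defaults):
        S_CaM = 1.0
        rf = cb.build_rate_field(grid, 1.0, S_CaM, pr, tr)

        def react(y):
            M, Mp, AMp, AM = y
            out = np.empty_like(y)
            out[0] = -rf.k1 * M + rf.k2 * Mp + rf.k7 * AM
            out[1] = rf.k1 * M - (rf.k2 + rf.k3) * Mp + rf.k4 * AMp
            out[2] = rf.k3 * Mp - (rf.k4 + rf.k5) * AMp + rf.k6 * AM
            out[3] = rf.k5 * AMp - (rf.k6 + rf.k7) * AM
            return out

        y = np.zeros((4, grid.n))
        y[0] = 1.0
        dt = 0.05
        for _ in range(int(1200 / dt)):
            y = godunov_step(y, 0.0, dt, grid, reaction=react)

        A_all = cb.tonic_rate_matrix(grid.centers, S_CaM, tr, pr.h,
                                     pr.dx_trans)
        for i in range(0, grid.n, 25):
            ns = null_space(A_all[:, :, i])
            assert ns.shape[1] == 1
            expected = ns[:, 0] / ns[:, 0].sum()
            assert np.max(np.abs(y[:, i] - expected)) < 1e-8

        F = cb.tonic_force(y[2], y[3], grid, geom)
        # quadrature oracle from the per-bin null space on the same grid
        AMp_ns = np.empty(grid.n)
        AM_ns = np.empty(grid.n)
        for i in range(grid.n):
            ns = null_space(A_all[:, :, i])[:, 0]
            ns = ns / ns.sum()
            AMp_ns[i], AM_ns[i] = ns[2], ns[3]
        F_oracle = geom.rho * geom.Num_T * geom.K_T * (
            moment(AMp_ns, grid, "x") + moment(AM_ns, grid, "x"))
        assert F == pytest.approx(F_oracle, rel=1e-6)


class TestConstantVelocitySteadyState:
    def test_matches_characteristic_ode_oracle(self, pr, geom):
        """Travelling steady state of the phasic PDE at constant shortening
        velocity vs integrating dn/dx = -[(1-n)f - n g]/v along the
        characteristic from the detached far field."""
        from lymphpump.params import load_config
        from lymphpump.transport import build_grid
        p40 = load_config({"run.n_per_h": 40})
        grid = build_grid(p40.run, pr.h)
        v = 5.0e-4  # cm/s shortening; distribution convects toward -x
        f = np.asarray(cb.phasic_attach_rate(grid.centers, 1.0, pr))
        g = np.asarray(cb.phasic_detach_rate(grid.centers, pr))
        n = np.zeros(grid.n)
        dt = 0.8 * grid.dx_min / v
        T = 2.5 * (grid.edges[-1] - grid.edges[0]) / v
        for _ in range(int(T / dt)):
            n = godunov_step(n, v, dt, grid,
                             reaction=lambda u: (1.0 - u) * f - u * g)

        def rhs(x, y):
            # steady transport: -v dn/dx = (1-n)f - n g
            fa = cb.phasic_attach_rate(x, 1.0, pr)
            ga = cb.phasic_detach_rate(x, pr)
            return [-((1.0 - y[0]) * fa - y[0] * ga) / v]

        sol = solve_ivp(rhs, (grid.edges[-1], grid.edges[0]), [0.0],
                        t_eval=grid.centers[::-1], rtol=1e-10, atol=1e-12,
                        max_step=pr.h / 50)
        n_oracle = sol.y[0][::-1]
        F_pde = cb.phasic_force(n, grid, geom)
        F_ode = cb.phasic_force(n_oracle, grid, geom)
        assert F_pde == pytest.approx(F_ode, rel=1e-3)


class TestEnergyLiberation:
    def _rate_field(self, grid, pr, tr, S_Trop, S_CaM):
        return cb.build_rate_field(grid, S_Trop, S_CaM, pr, tr)

    def test_all_detached_dephosphorylated_no_liberation(
            self, grid, pr, tr, geom, defaults):
        rf = self._rate_field(grid, pr, tr, 0.0, 0.0)
        tonic = cb.TonicState(M=np.ones(grid.n), Mp=np.zeros(grid.n),
                              AMp=np.zeros(grid.n), AM=np.zeros(grid.n))
        out = cb.energy_liberation_rates(np.zeros(grid.n), tonic, rf, grid,
                                         geom, defaults.cell)
        for key, val in out.items():
            assert val == 0.0, key

    def test_total_is_sum_of_components(self, grid, pr, tr, geom, defaults,
                                        rng):
        rf = self._rate_field(grid, pr, tr, 0.6, 0.4)
        y = rng.uniform(0.0, 1.0, size=(4, grid.n))
        y /= y.sum(axis=0)
        tonic = cb.TonicState(M=y[0], Mp=y[1], AMp=y[2], AM=y[3])
        out = cb.energy_liberation_rates(rng.uniform(0, 1, grid.n), tonic,
                                         rf, grid, geom, defaults.cell)
        total = (out["dEnergy_T_PhosDetach"] + out["dEnergy_T_UnphosDetach"]
                 + out["dEnergy_T_DetachPhos"] + out["dEnergy_T_AttachPhos"])
        assert out["dEnergy_T"] == pytest.approx(total, rel=1e-15)

    def test_steady_phasic_liberation_vs_quadrature(self, grid, pr, tr, geom,
                                                    defaults):
        n, f, g = relax_isometric_phasic(grid, pr, 1.0)
        rf = self._rate_field(grid, pr, tr, 1.0, 0.0)
        tonic = cb.TonicState(M=np.ones(grid.n), Mp=np.zeros(grid.n),
                              AMp=np.zeros(grid.n), AM=np.zeros(grid.n))
        out = cb.energy_liberation_rates(n, tonic, rf, grid, geom,
                                         defaults.cell)

        def gn(x):
            fa = cb.phasic_attach_rate(x, 1.0, pr)
            ga = cb.phasic_detach_rate(x, pr)
            return ga * fa / (fa + ga) if fa + ga > 0 else 0.0

        val, _ = quad(gn, 0.0, pr.h + pr.dx_trans, limit=500,
                      points=[pr.dx_trans, pr.h - pr.dx_trans, pr.h])
        cell = defaults.cell
        pre = cell.N_Cell * cell.N_Rows * geom.rho * cell.u * geom.Num_P \
            * geom.N_P
        assert out["dEnergy_P"] == pytest.approx(pre * val, rel=1e-3)


class TestMatrixExponentialOneStep:
    def test_reaction_step_matches_expm(self, grid, pr, tr, rng):
        rf = cb.build_rate_field(grid, 0.8, 0.5, pr, tr)

        def react(y):
            M, Mp, AMp, AM = y
            out = np.empty_like(y)
            out[0] = -rf.k1 * M + rf.k2 * Mp + rf.k7 * AM
            out[1] = rf.k1 * M - (rf.k2 + rf.k3) * Mp + rf.k4 * AMp
            out[2] = rf.k3 * Mp - (rf.k4 + rf.k5) * AMp + rf.k6 * AM
            out[3] = rf.k5 * AMp - (rf.k6 + rf.k7) * AM
            return out

        y0 = rng.uniform(0.1, 1.0, size=(4, grid.n))
        y0 /= y0.sum(axis=0)
        dt = 1e-4
        y1 = godunov_step(y0.copy(), 0.0, dt, grid, reaction=react)
        A_all = cb.tonic_rate_matrix(grid.centers, 0.5, tr, pr.h, pr.dx_trans)
        for i in range(0, grid.n, 50):
            exact = expm(A_all[:, :, i] * dt) @ y0[:, i]
            assert np.max(np.abs(y1[:, i] - exact)) < 1e-6
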