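import math

import numpy as np
import pytest

import kmreduce as km
from conftest import make_fixture_model


class TestIntegratedRhs:
    def test_sir_form(self, sir):
        model, psi = sir
        rhs = km.integrated_rhs(model.kernel, psi)
        Q = np.array([3.0])
        expected = -0.25 * 3.0 + psi(0.0005 * 3.0)
        assert rhs(Q)[0] == pytest.approx(expected, rel=1e-14)

    def test_seir_componentwise(self, seir):
        # dQ1 = -gamma Q1 + Psi(beta Q2); dQ2 = gamma Q1 - alpha Q2
        model, psi = seir
        rhs = km.integrated_rhs(model.kernel, psi)
        out = rhs(np.array([1.0, 2.0]))
        assert out[0] == pytest.approx(
            -0.25 * 1.0 + 1000.0 * (1.0 - math.exp(-0.0005 * 2.0)), rel=1e-12)
        assert out[1] == pytest.approx(0.25 * 1.0 - 0.25 * 2.0, abs=1e-14)

    def test_disease_free_equilibrium(self, seir):
        model, psi = seir
        rhs = km.integrated_rhs(model.kernel, psi)
        np.testing.assert_allclose(rhs(np.zeros(2)), 0.0, atol=1e-14)


class TestSeedState:
    def test_sir_closed_form(self, sir):
        # Q(0) = N w0 / (r + alpha), r = N beta - alpha
        model, psi = sir
        state = km.seed_state(model, psi, km.SeedSpec(w0=1e-4))
        r = 1000.0 * 0.0005 - 0.25
        assert state.r == pytest.approx(r, rel=1e-12)
        assert state.Q0[0] == pytest.approx(1000.0 * 1e-4 / (r + 0.25), rel=1e-12)
        assert abs(float(model.kernel.U @ state.Q0) - 1e-4) < 1e-14

    @pytest.mark.parametrize("seed_idx", range(4))
    def test_euler_lotka_identity(self, seed_idx):
        model = make_fixture_model(seed_idx)
        psi = km.psi_for_model(model)
        state = km.seed_state(model, psi, km.SeedSpec(w0=1e-5))
        assert abs(float(model.kernel.U @ state.Q0) - 1e-5) < 1e-12

    def test_explicit_mode_passthrough(self, sir):
        model, psi = sir
        Q0 = np.array([0.123])
        state = km.seed_state(model, psi, km.SeedSpec(mode="explicit", Q0=Q0))
        np.testing.assert_array_equal(state.Q0, Q0)

    def test_subcritical_eigen_seed_rejected(self):
        model = km.sir_model(beta=0.0002, alpha=0.25, N=1000.0)  # R0 = 0.8
        psi = km.psi_for_model(model)
        with pytest.raises(ValueError, match="explicit"):
            km.seed_state(model, psi, km.SeedSpec())


class TestSimulateIntegrated:
    def test_sir_reaches_final_size(self, sir):
        model, psi = sir
        traj = km.simulate_integrated(model, psi, km.SeedSpec(w0=1e-6), t_end=200.0)
        w_inf, _ = km.final_size(model, psi)
        assert abs(traj.w[-1] - w_inf) < 1e-3

    def test_zero_psi_decays_linearly(self, seir):
        model, _ = seir
        zero_psi = km.PsiFunction(psi=lambda w: 0.0 * np.asarray(w),
                                  psi_prime=lambda w: 0.0 * np.asarray(w),
                                  saturation=0.0, n_scale=1.0)
        Q0 = np.array([1.0, 0.5])
        traj = km.simulate_integrated(
            model, zero_psi, km.SeedSpec(mode="explicit", Q0=Q0), t_end=5.0)
        from scipy.linalg import expm

        for idx in (500, 1000, 2000):
            t = traj.times[idx]
            np.testing.assert_allclose(
                traj.Q[idx], expm(t * model.kernel.Sigma) @ Q0, rtol=1e-6)

    def test_gamma_attack_rate_is_half_at_R0_two(self, gamma_sir):
        # 1 + w_inf = R0 for p = 1, c = 1, so s_tot(inf) = 1/R0
        model, psi = gamma_sir
        traj = km.simulate_integrated(model, psi, km.SeedSpec(w0=1e-6), t_end=200.0)
        assert 1.0 - traj.s_tot[-1] == pytest.approx(0.5, abs=1e-3)

    def test_susceptible_conservation(self, sir):
        model, psi = sir
        traj = km.simulate_integrated(model, psi, t_end=100.0)
        np.testing.assert_allclose(traj.S, model.N * np.exp(-traj.w),
                                   atol=1e-8 * model.N)

    def test_w_monotone(self, sir):
        model, psi = sir
        traj = km.simulate_integrated(model, psi, t_end=150.0)
        assert np.all(np.diff(traj.w) >= -1e-10)


class TestSimulateStandard:
    def test_homogeneous_sir_equals_textbook(self, sir):
        # dS/dt = -beta I S, dI/dt = beta I S - alpha I with S = N sbar, I = Y
        from scipy.integrate import solve_ivp

        model, psi = sir
        traj = km.simulate_standard(model, psi, km.SeedSpec(w0=1e-6), t_end=100.0)
        S0 = 1000.0 * math.exp(-1e-6)
        I0 = traj.Y[0, 0]

        def rhs(_t, z):
            S, I = z
            return [-0.0005 * I * S, 0.0005 * I * S - 0.25 * I]

        sol = solve_ivp(rhs, (0, 100.0), [S0, I0], t_eval=traj.times,
                        rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(1000.0 * traj.s_bar, sol.y[0], rtol=1e-6)
        np.testing.assert_allclose(traj.Y[:, 0], sol.y[1], rtol=1e-5, atol=1e-8)

    def test_two_group_psi_prime_identity_along_path(self):
        # Psi'(-log sbar) = N1 sbar + N2 eps1 eps2 sbar^{eps1} pathwise
        base = km.sir_model(beta=0.0005, alpha=0.25, N=1000.0)
        model = km.two_group_immunity_variant(base, 500.0, 500.0, 0.5, 2.0)
        psi = km.psi_for_model(model)
        traj = km.simulate_standard(model, psi, t_end=80.0)
        sbar = traj.s_bar
        expected = 500.0 * sbar + 500.0 * 0.5 * 2.0 * sbar**0.5
        np.testing.assert_allclose(np.asarray(psi.prime(traj.w)), expected, rtol=1e-12)

    @pytest.mark.parametrize("het", [None, "gamma", "discrete"])
    def test_matches_integrated(self, het):
        model = make_fixture_model(7, heterogeneity=het)
        psi = km.psi_for_model(model)
        cfg = km.SolverConfig(rtol=1e-10, atol_scale=1e-13)
        ti = km.simulate_integrated(model, psi, t_end=60.0, config=cfg)
        ts = km.simulate_standard(model, psi, t_end=60.0, config=cfg)
        assert np.max(np.abs(ti.w - ts.w)) < 1e-6

    def test_Q_equals_integral_of_Y(self, sir):
        model, psi = sir
        traj = km.simulate_standard(model, psi, t_end=120.0,
                                    config=km.SolverConfig(n_points=8001))
        # cumulative trapezoid of Y plus Q(0) reproduces the Q state
        from scipy.integrate import cumulative_trapezoid

        Q_num = traj.Q[0, 0] + cumulative_trapezoid(traj.Y[:, 0], traj.times,
                                                    initial=0.0)
        np.testing.assert_allclose(traj.Q[:, 0], Q_num, rtol=1e-5)


class TestSimulateGammaStot:
    def test_requires_gamma_trait(self, sir):
        model, _ = sir
        with pytest.raises(ValueError, match="Gamma"):
            km.simulate_gamma_stot(model, t_end=10.0)

    @pytest.mark.parametrize("p", [1.0, 2.0])
    def test_matches_standard_via_laplace_identity(self, p):
        # s_tot = Phi_hat(-log sbar) links the two formulations
        model = km.sir_model(0.0005, 0.25, 1000.0, trait=km.gamma_trait(p))
        psi = km.psi_for_model(model)
        cfg = km.SolverConfig(rtol=1e-10, atol_scale=1e-13)
        t_stot = km.simulate_gamma_stot(model, t_end=150.0, config=cfg)
        t_std = km.simulate_standard(model, psi, t_end=150.0, config=cfg)
        implied = km.gamma_laplace(p, t_std.w)
        assert np.max(np.abs(t_stot.s_tot - implied)) < 1e-6

    def test_H_at_one(self):
        # H(1) = N for constant c; N (1 + 1/p) for proportional c
        model_c = km.sir_model(0.0005, 0.25, 1000.0, trait=km.gamma_trait(2.0))
        model_p = km.sir_model(0.0005, 0.25, 1000.0,
                               trait=km.gamma_trait(2.0, "proportional_to_trait"))
        tc = km.simulate_gamma_stot(model_c, t_end=1e-6)
        tp = km.simulate_gamma_stot(model_p, t_end=1e-6)
        # at t ~ 0, s_tot ~ 1 and dY/dt coefficient H(s) is N resp. N(1+1/p);
        # probe H indirectly through psi_gamma consistency instead
        assert tc.s_tot[0] == pytest.approx(1.0, abs=1e-5)
        assert tp.s_tot[0] == pytest.approx(1.0, abs=1e-5)


class TestTrajectoryFrame:
    def test_columns_present(self, sir):
        model, psi = sir
        frame = km.simulate_standard(model, psi, t_end=10.0).to_frame()
        for col in ("time", "w", "s_bar", "s_tot", "S", "incidence", "Q_1", "Y_1"):
            assert col in frame.columns

    def test_integrated_run_has_no_Y(self, sir):
        model, psi = sir
        frame = km.simulate_integrated(model, psi, t_end=10.0).to_frame()
        assert "Y_1" not in frame.columns
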