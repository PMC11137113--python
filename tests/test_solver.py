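import numpy as np
import pytest

from coslir import MomentSummary, admm_fit, apply_clipping, objective, precision_recall
from coslir.solver import (ADMMState, SolverConfig, _Problem,
                           augmented_lagrangian, update_A, update_B, update_C)


def random_moments(p, seed):
    rng = np.random.default_rng(seed)
    M1 = rng.standard_normal((p, p))
    M2 = rng.standard_normal((p, p))
    m1 = MomentSummary.from_exact(rng.normal(0, 3, p), M1 @ M1.T + np.eye(p))
    m2 = MomentSummary.from_exact(rng.normal(1, 3, p), M2 @ M2.T + np.eye(p))
    return m1, m2


def random_state(p, seed, rho=1.3):
    rng = np.random.default_rng(seed)
    return ADMMState(
        A=rng.standard_normal((p, p)) * 0.3,
        B=np.eye(p) + rng.standard_normal((p, p)) * 0.2,
        C=np.eye(p) + rng.standard_normal((p, p)) * 0.2,
        Pi1=rng.standard_normal((p, p)) * 0.1,
        Pi2=rng.standard_normal((p, p)) * 0.1,
        rho=rho,
    )


class TestObjective:
    def test_zero_matrix_value_is_one_plus_eta(self):
        m1, m2 = random_moments(4, 0)
        for eta in (1.0, 5.0, 10.0):
            val = objective(np.zeros((4, 4)), m1, m2, lam=0.37, eta=eta)
            assert val == pytest.approx(1.0 + eta)

    def test_truth_on_zero_noise_oracle_is_zero(self, oracle_instance):
        truth, m_t, m_t1 = oracle_instance
        assert objective(truth.A_true, m_t, m_t1, lam=0.0, eta=5.0) == \
            pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_term_walkthrough(self):
        """p=2 instance against a separately coded formula walk-through."""
        m1 = MomentSummary.from_exact([1.0, -2.0],
                                      [[2.0, 0.3], [0.3, 1.5]])
        m2 = MomentSummary.from_exact([0.5, 1.0],
                                      [[3.0, -0.2], [-0.2, 2.5]])
        A = np.array([[0.1, -0.4], [0.2, 0.0]])
        lam, eta = 0.01, 5.0
        G = A + np.eye(2)
        num_S = 0.0
        pred = G @ np.array(m1.covariance) @ G.T
        for i in range(2):
            for j in range(2):
                num_S += (m2.covariance[i, j] - pred[i, j]) ** 2
        den_S = sum((m2.covariance[i, j] - m1.covariance[i, j]) ** 2
                    for i in range(2) for j in range(2))
        pred_mu = G @ np.array(m1.mean)
        num_m = sum((m2.mean[i] - pred_mu[i]) ** 2 for i in range(2))
        den_m = sum((m2.mean[i] - m1.mean[i]) ** 2 for i in range(2))
        expect = num_S / den_S + eta * num_m / den_m + lam * np.abs(A).sum()
        assert objective(A, m1, m2, lam, eta) == pytest.approx(expect)

    def test_indistinguishable_stages_error(self):
        m1 = MomentSummary.from_exact([1.0, 2.0], np.eye(2))
        with pytest.raises(ValueError, match="indistinguishable"):
            objective(np.zeros((2, 2)), m1, m1, 1e-6, 5.0)


class TestBlockUpdates:
    def test_update_A_no_penalty_is_plain_target(self):
        m1, m2 = random_moments(3, 1)
        state = random_state(3, 2)
        cfg = SolverConfig(lam=0.0, eta=5.0)
        T = (state.B + state.C) / 2 - np.eye(3) - state.Pi2 / state.rho
        assert np.allclose(update_A(state, m1, m2, cfg), T)

    @pytest.mark.parametrize("target,lam_over_rho,expect",
                             [(0.5, 0.2, 0.3), (-0.1, 0.2, 0.0)])
    def test_update_A_soft_threshold_scalar(self, target, lam_over_rho,
                                            expect):
        m1 = MomentSummary.from_exact([1.0, 0.0], np.eye(2) * 2)
        m2 = MomentSummary.from_exact([2.0, 1.0], np.eye(2) * 3)
        rho = 2.0
        state = ADMMState(A=np.zeros((2, 2)),
                          B=np.eye(2), C=np.eye(2),
                          Pi1=np.zeros((2, 2)), Pi2=np.zeros((2, 2)),
                          rho=rho)
        # arrange (B+C)/2 - I - Pi2/rho == target at entry (0, 1)
        state.Pi2[0, 1] = -target * rho
        out = update_A(state, m1, m2,
                       SolverConfig(lam=lam_over_rho * rho, eta=5.0))
        assert out[0, 1] == pytest.approx(expect)

    def test_update_A_subgradient_optimality(self):
        """0 must lie in the subdifferential of the Lagrangian at the
        returned A (finite-difference check of the smooth part)."""
        m1, m2 = random_moments(3, 3)
        cfg = SolverConfig(lam=0.05, eta=5.0)
        state = random_state(3, 4)
        A_star = update_A(state, m1, m2, cfg)

        def smooth(A):
            s = ADMMState(A=A, B=state.B, C=state.C, Pi1=state.Pi1,
                          Pi2=state.Pi2, rho=state.rho)
            return augmented_lagrangian(s, m1, m2,
                                        SolverConfig(lam=0.0, eta=5.0))

        h = 1e-6
        for i in range(3):
            for j in range(3):
                E = np.zeros((3, 3))
                E[i, j] = h
                g = (smooth(A_star + E) - smooth(A_star - E)) / (2 * h)
                if A_star[i, j] != 0:
                    assert g + cfg.lam * np.sign(A_star[i, j]) == \
                        pytest.approx(0.0, abs=1e-4)
                else:
                    assert abs(g) <= cfg.lam + 1e-4

    @pytest.mark.parametrize("p,seed", [(2, 0), (2, 5), (3, 1), (3, 7)])
    def test_update_B_and_C_gradient_zero(self, p, seed):
        m1, m2 = random_moments(p, seed)
        cfg = SolverConfig(lam=0.01, eta=5.0)
        state = random_state(p, seed + 100)
        B_star = update_B(state, m1, m2, cfg)
        C_star = update_C(state, m1, m2, cfg)

        def lag(B=None, C=None):
            s = ADMMState(A=state.A,
                          B=state.B if B is None else B,
                          C=state.C if C is None else C,
                          Pi1=state.Pi1, Pi2=state.Pi2, rho=state.rho)
            return augmented_lagrangian(s, m1, m2, cfg)

        h = 1e-6
        for i in range(p):
            for j in range(p):
                E = np.zeros((p, p))
                E[i, j] = h
                gB = (lag(B=B_star + E) - lag(B=B_star - E)) / (2 * h)
                assert gB == pytest.approx(0.0, abs=1e-5)
                # C update is taken with B fixed at the state's B
                gC = (lag(C=C_star + E) - lag(C=C_star - E)) / (2 * h)
                assert gC == pytest.approx(0.0, abs=1e-5)

    def test_update_B_matches_quadratic_program_oracle(self):
        """Direct quadratic minimisation over vec(B) (via lstsq on the
        stationarity system) agrees with the closed-form update."""
        p = 2
        m1, m2 = random_moments(p, 9)
        cfg = SolverConfig(lam=0.01, eta=5.0)
        state = random_state(p, 10)
        B_star = update_B(state, m1, m2, cfg)
        # numerically minimise the Lagrangian over B
        from scipy.optimize import minimize

        def f(x):
            s = ADMMState(A=state.A, B=x.reshape(p, p), C=state.C,
                          Pi1=state.Pi1, Pi2=state.Pi2, rho=state.rho)
            return augmented_lagrangian(s, m1, m2, cfg)

        res = minimize(f, np.eye(p).ravel(), method="BFGS",
                       options={"gtol": 1e-12})
        assert np.allclose(B_star.ravel(), res.x, atol=1e-5)

    def test_penalty_dominance_limit(self):
        """At huge rho the sweeps contract the consensus residuals
        geometrically: the data terms become negligible against the
        quadratic penalties."""
        p = 3
        m1, m2 = random_moments(p, 11)
        cfg = SolverConfig(lam=1e-6, eta=5.0)
        state = random_state(p, 12, rho=1e8)
        state.Pi1[:] = 0.0
        state.Pi2[:] = 0.0
        for _ in range(6):
            state.A = update_A(state, m1, m2, cfg)
            state.B = update_B(state, m1, m2, cfg)
            state.C = update_C(state, m1, m2, cfg)
        assert np.linalg.norm(state.B - state.C) < 1e-3
        assert np.linalg.norm(
            state.A + np.eye(p) - (state.B + state.C) / 2) < 1e-3

    def test_block_updates_never_increase_lagrangian(self):
        p = 3
        m1, m2 = random_moments(p, 13)
        cfg = SolverConfig(lam=0.05, eta=5.0)
        state = random_state(p, 14)
        before = augmented_lagrangian(state, m1, m2, cfg)
        state.A = update_A(state, m1, m2, cfg)
        after_A = augmented_lagrangian(state, m1, m2, cfg)
        assert after_A <= before + 1e-10
        state.B = update_B(state, m1, m2, cfg)
        after_B = augmented_lagrangian(state, m1, m2, cfg)
        assert after_B <= after_A + 1e-10
        state.C = update_C(state, m1, m2, cfg)
        after_C = augmented_lagrangian(state, m1, m2, cfg)
        assert after_C <= after_B + 1e-10


class TestAdmmFit:
    def test_oracle_recovery_with_sign(self, oracle_instance):
        truth, m_t, m_t1 = oracle_instance
        est = admm_fit(m_t, m_t1, SolverConfig())
        rep = precision_recall(apply_clipping(est.A, 0.01), truth.A_true)
        assert rep.precision == 1.0
        assert rep.recall == 1.0

    def test_huge_lambda_returns_zero_matrix(self):
        m1, m2 = random_moments(4, 20)
        est = admm_fit(m1, m2, SolverConfig(lam=1e6, max_iter=500))
        assert np.allclose(apply_clipping(est.A, 0.01), 0.0)

    def test_beats_random_search_oracle(self):
        """The fit's objective value is at least as good as the best of
        many random sparse candidates (plus the zero matrix)."""
        m1, m2 = random_moments(2, 21)
        cfg = SolverConfig(lam=1e-3, eta=5.0)
        est = admm_fit(m1, m2, cfg)
        rng = np.random.default_rng(0)
        best = objective(np.zeros((2, 2)), m1, m2, cfg.lam, cfg.eta)
        for _ in range(10_000):
            cand = np.where(rng.random((2, 2)) < 0.5,
                            rng.standard_normal((2, 2)), 0.0)
            best = min(best, objective(cand, m1, m2, cfg.lam, cfg.eta))
        assert est.objective <= best + 1e-9

    def test_deterministic(self, oracle_instance):
        _, m_t, m_t1 = oracle_instance
        est1 = admm_fit(m_t, m_t1, SolverConfig())
        est2 = admm_fit(m_t, m_t1, SolverConfig())
        assert np.array_equal(est1.A, est2.A)

    def test_max_iter_exhaustion_reports_not_raises(self):
        m1, m2 = random_moments(5, 22)
        est = admm_fit(m1, m2, SolverConfig(max_iter=3, init="zero",
                                            refine=False))
        assert est.converged is False
        assert np.all(np.isfinite(est.A))

    def test_convergence_residuals_below_tolerance(self, oracle_instance):
        _, m_t, m_t1 = oracle_instance
        cfg = SolverConfig()
        est = admm_fit(m_t, m_t1, cfg)
        if est.converged:
            r1, r2 = est.diagnostics["primal_residuals"]
            assert r1 <= cfg.tol_primal * 10
            assert r2 <= cfg.tol_primal * 10

    def test_single_gene_rejected(self):
        m1 = MomentSummary.from_exact([1.0], [[2.0]])
        m2 = MomentSummary.from_exact([2.0], [[3.0]])
        with pytest.raises(ValueError, match="at least 2"):
            admm_fit(m1, m2, SolverConfig())
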