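import numpy as np
import pytest

from mmreml import (
    Component,
    build_mme,
    build_model,
    fit_mm,
    mm_step,
    mm_step_via_mme,
    mme_identities,
    select_strategy,
    trace_p_vk,
)
from mmreml.likelihood import projection_matrix, restricted_loglik
from mmreml.mme import restricted_loglik_mme


def _factored_instance(seed, n=30, sizes=(6, 4), p=2):
    """Model with low-dimensional factored components and identity error."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(p - 1)])
    comps = []
    for i, q in enumerate(sizes):
        Z = np.zeros((n, q))
        Z[np.arange(n), rng.integers(0, q, n)] = 1.0
        A = rng.standard_normal((q, q + 3))
        R = A @ A.T / (q + 3)
        R /= np.outer(np.sqrt(np.diag(R)), np.sqrt(np.diag(R)))
        comps.append(Component(f"u{i}", Z=Z, R=R))
    comps.append(Component("error"))
    from mmreml import simulate_phenotype

    gamma = rng.uniform(0.4, 1.5, len(sizes) + 1)
    y = simulate_phenotype((X, comps), gamma, beta=rng.normal(0, 1, p), seed=rng)
    return build_model(y, X, comps)


def _dense_P_delta(model, delta):
    """Oracle: P_delta from the dense covariance at gamma = (delta, 1)."""
    gamma = np.concatenate([delta, [1.0]])
    return projection_matrix(model, gamma).dense()


class TestBuildMME:
    def test_residual_decomposition_is_exact(self):
        model = _factored_instance(0)
        f = build_mme(model, np.array([0.8, 1.3]))
        recon = model.X @ f.beta_hat + f.Z @ f.u_hat + f.e_hat
        np.testing.assert_allclose(recon, model.y, atol=1e-10)

    def test_ridge_equivalence_single_identity_component(self):
        # K=2, R=I, V_ref=I: u-hat are ridge coefficients with penalty 1/delta
        rng = np.random.default_rng(1)
        n, q = 25, 6
        Z = rng.standard_normal((n, q))
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        model = build_model(y, X, [Component("u", Z=Z), Component("e")])
        delta = 0.7
        f = build_mme(model, np.array([delta]))
        # ridge on residuals from the jointly-estimated intercept
        r = y - X @ f.beta_hat
        ridge = np.linalg.solve(Z.T @ Z + np.eye(q) / delta, Z.T @ r)
        np.testing.assert_allclose(f.u_hat, ridge, atol=1e-8)

    def test_large_delta_limit_recovers_gls(self):
        model = _factored_instance(2)
        delta = np.array([1e6, 1e6])
        f = build_mme(model, delta)
        from mmreml import gls_beta

        beta, _ = gls_beta(model, np.concatenate([delta, [1.0]]))
        np.testing.assert_allclose(f.beta_hat, beta, rtol=1e-4)

    def test_singular_correlation_instructs_direct_path(self):
        n = 20
        rng = np.random.default_rng(3)
        Z = np.zeros((n, 4))
        Z[np.arange(n), rng.integers(0, 4, n)] = 1.0
        R = np.ones((4, 4))  # rank 1
        model = build_model(rng.standard_normal(n), np.ones((n, 1)),
                            [Component("u", Z=Z, R=R), Component("e")])
        with pytest.raises(np.linalg.LinAlgError, match="direct"):
            build_mme(model, np.array([1.0]))


class TestIdentities:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_three_identities_match_dense_projection(self, seed):
        model = _factored_instance(seed, n=35)
        delta = np.random.default_rng(seed).uniform(0.3, 2.0, 2)
        f = build_mme(model, delta)
        ids = mme_identities(f)
        P = _dense_P_delta(model, delta)
        np.testing.assert_allclose(ids["Py"], P @ model.y, atol=1e-8)
        np.testing.assert_allclose(ids["ZtPy"], f.Z.T @ P @ model.y, atol=1e-8)
        np.testing.assert_allclose(ids["ZtPZ"], f.Z.T @ P @ f.Z, atol=1e-8)

    def test_quadratic_form_two_routes_agree(self):
        model = _factored_instance(5)
        delta = np.array([0.9, 0.5])
        f = build_mme(model, delta)
        dense = float(model.y @ _dense_P_delta(model, delta) @ model.y)
        via_mme = float(model.y @ mme_identities(f)["Py"])
        assert via_mme == pytest.approx(dense, abs=1e-8)

    def test_small_delta_limit_consistent_with_dense(self):
        model = _factored_instance(6)
        delta = np.array([1e-8, 1e-8])
        f = build_mme(model, delta)
        P = _dense_P_delta(model, delta)
        np.testing.assert_allclose(mme_identities(f)["ZtPy"], f.Z.T @ P @ model.y,
                                   atol=1e-6)

    def test_loglik_via_mme_matches_dense(self):
        model = _factored_instance(7)
        gamma = np.array([0.6, 1.1, 0.9])
        delta = gamma[:2] / gamma[2]
        f = build_mme(model, delta)
        assert restricted_loglik_mme(model, gamma, f) == pytest.approx(
            restricted_loglik(model, gamma), abs=1e-8)


class TestTracePVK:
    def test_matches_dense_trace(self):
        model = _factored_instance(8, n=40)
        delta = np.array([1.2, 0.4])
        f = build_mme(model, delta)
        P = _dense_P_delta(model, delta)
        dense = float(np.trace(P @ model.components[-1].V))
        assert trace_p_vk(f, model.m) == pytest.approx(dense, abs=1e-8)
        assert trace_p_vk(f, model.m) > 0

    def test_no_random_effects_returns_m(self):
        from mmreml.mme import MMEFactors

        f = MMEFactors(C=np.eye(1), beta_hat=np.zeros(1), u_hat=np.zeros(0),
                       e_hat=np.zeros(3), Cinv_uu=np.zeros((0, 0)),
                       S=np.eye(3), G_inv=np.zeros((0, 0)), Z=np.zeros((3, 0)),
                       Vref_inv=np.eye(3), blocks=[], delta=np.zeros(0))
        assert trace_p_vk(f, 2) == 2.0


class TestMMStepViaMME:
    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_twenty_iterate_sequences_match_direct(self, seed):
        model = _factored_instance(seed)
        g_direct = g_mme = np.array([0.7, 1.1, 0.9])
        for _ in range(20):
            g_direct = mm_step(model, g_direct)
            g_mme = mm_step_via_mme(model, g_mme)
            np.testing.assert_allclose(g_mme, g_direct, atol=1e-8, rtol=1e-8)

    def test_same_final_fit_both_strategies(self):
        model = _factored_instance(10)
        f_on = fit_mm(model, tol=1e-8, use_mme="on")
        f_off = fit_mm(model, tol=1e-8, use_mme="off")
        np.testing.assert_allclose(f_on.gamma_hat, f_off.gamma_hat, atol=1e-6)
        assert abs(f_on.loglik - f_off.loglik) < 1e-6
        assert f_on.solver_tag == "mm+mme" and f_off.solver_tag == "mm"

    def test_fixed_point_property(self):
        model = _factored_instance(11)
        fit = fit_mm(model, tol=1e-12, max_iter=5000)
        np.testing.assert_allclose(mm_step_via_mme(model, fit.gamma_hat),
                                   fit.gamma_hat, rtol=1e-6)


class TestSelectStrategy:
    def test_low_dimensional_latents_choose_mme(self):
        rng = np.random.default_rng(0)
        n = 1000
        comps = []
        for q in (50, 50):
            Z = np.zeros((n, q))
            Z[np.arange(n), rng.integers(0, q, n)] = 1.0
            comps.append(Component(f"u{q}{len(comps)}", Z=Z))
        comps.append(Component("e"))
        model = build_model(rng.standard_normal(n), np.ones((n, 1)), comps)
        assert select_strategy(model) == "mme"

    def test_full_dimension_component_chooses_direct(self):
        rng = np.random.default_rng(1)
        n = 200
        A = rng.standard_normal((n, n + 5))
        model = build_model(rng.standard_normal(n), np.ones((n, 1)),
                            [Component("g", R=A @ A.T / (n + 5)), Component("e")])
        assert select_strategy(model) == "direct"

    def test_singular_correlation_forces_direct(self):
        rng = np.random.default_rng(2)
        n = 500
        Z = np.zeros((n, 10))
        Z[np.arange(n), rng.integers(0, 10, n)] = 1.0
        model = build_model(rng.standard_normal(n), np.ones((n, 1)),
                            [Component("u", Z=Z, R=np.ones((10, 10))), Component("e")])
        assert select_strategy(model) == "direct"
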