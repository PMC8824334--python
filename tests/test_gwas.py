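import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mmreml import (
    Component,
    FitResult,
    bic,
    build_model,
    declare_significant,
    fit_mm,
    gao_meff,
    kinship_from_markers,
    restricted_loglik,
    run_gwas,
    simulate_genotypes,
    simulate_phenotype,
    wald_test,
)


def _fit_stub(beta, cov):
    return FitResult(gamma_hat=np.array([1.0]), beta_hat=np.asarray(beta, float),
                     beta_cov=np.asarray(cov, float), loglik=0.0, converged=True,
                     n_iterations=1, solver_tag="stub")


class TestWaldTest:
    def test_borderline_z_score_gives_five_percent(self):
        fit = _fit_stub([0.0, 1.959964], np.eye(2))
        stat, df, p = wald_test(fit, [1])
        assert df == 1
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_null_estimate_gives_p_one(self):
        stat, df, p = wald_test(_fit_stub([1.0, 0.0], np.eye(2)), [1])
        assert stat == 0.0 and p == 1.0

    def test_two_df_block_matches_quadratic_form(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((3, 3))
        cov = A @ A.T
        beta = rng.standard_normal(3)
        stat, df, p = wald_test(_fit_stub(beta, cov), [0, 2])
        sub = cov[np.ix_([0, 2], [0, 2])]
        brute = float(beta[[0, 2]] @ np.linalg.inv(sub) @ beta[[0, 2]])
        assert df == 2 and stat == pytest.approx(brute, rel=1e-10)
        assert p == pytest.approx(float(stats.chi2.sf(brute, 2)), rel=1e-10)


def _line_panel(seed, n=120, L=40):
    rng = np.random.default_rng(seed)
    G = simulate_genotypes(n, L, rng=rng)
    K = kinship_from_markers(G)
    comps = [Component("g", R=K), Component("e")]
    return G, K, comps


class TestRunGwas:
    def test_spiked_marker_attains_smallest_pvalue(self):
        G, K, comps = _line_panel(1)
        X = np.ones((G.shape[0], 1))
        y = simulate_phenotype((X, comps), np.array([0.3, 1.0]), seed=5)
        y = y + 1.5 * G[:, 7]
        res = run_gwas(y, None, G, comps, mode="exact")
        ok = res[res["skipped_reason"] == ""]
        assert ok.loc[ok["p_value"].idxmin(), "marker_id"] == "m7"

    def test_approximate_close_to_exact_but_not_identical(self):
        G, K, comps = _line_panel(2, n=100, L=30)
        X = np.ones((G.shape[0], 1))
        y = simulate_phenotype((X, comps), np.array([0.8, 1.0]), seed=9)
        exact = run_gwas(y, None, G, comps, mode="exact")
        approx = run_gwas(y, None, G, comps, mode="approximate")
        pe, pa = exact["p_value"].to_numpy(), approx["p_value"].to_numpy()
        rho = stats.spearmanr(np.log(pe), np.log(pa)).statistic
        assert rho >= 0.99
        assert np.abs(pe - pa).max() > 0  # genuinely different procedures

    def test_monomorphic_markers_skipped_and_counted(self):
        G, K, comps = _line_panel(3, n=60, L=10)
        G[:, 4] = 2.0
        y = np.random.default_rng(0).standard_normal(60)
        res = run_gwas(y, None, G, comps, mode="approximate")
        assert (res["skipped_reason"] == "monomorphic").sum() == 1
        assert res.loc[res["marker_id"] == "m4", "p_value"].isna().all()

    def test_results_invariant_to_marker_order(self):
        G, K, comps = _line_panel(4, n=80, L=12)
        y = simulate_phenotype((np.ones((80, 1)), comps), np.array([0.5, 1.0]), seed=3)
        perm = np.random.default_rng(1).permutation(12)
        a = run_gwas(y, None, pd.DataFrame(G, columns=[f"m{j}" for j in range(12)]),
                     comps, mode="exact")
        b = run_gwas(y, None, pd.DataFrame(G[:, perm], columns=[f"m{j}" for j in perm]),
                     comps, mode="exact")
        merged = a.merge(b, on="marker_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["p_value_a"], merged["p_value_b"], rtol=1e-8)

    def test_missing_dosages_mean_imputed(self):
        G, K, comps = _line_panel(5, n=60, L=8)
        G[3, 2] = np.nan
        y = np.random.default_rng(2).standard_normal(60)
        with pytest.warns(UserWarning, match="imputed"):
            res = run_gwas(y, None, G, comps, mode="approximate")
        assert res.loc[res["marker_id"] == "m2", "p_value"].notna().all()

    def test_dominance_adds_two_df_test(self):
        G, K, comps = _line_panel(6, n=90, L=6)
        y = simulate_phenotype((np.ones((90, 1)), comps), np.array([0.5, 1.0]), seed=4)
        res = run_gwas(y, None, G, comps, mode="exact", dominance=True)
        ok = res[res["skipped_reason"] == ""]
        assert (ok["df"] == 2).all()
        assert ok["beta_dom"].notna().all()

    def test_loco_uses_off_chromosome_kinship(self):
        G, K, comps = _line_panel(7, n=80, L=30)
        chrom = np.repeat([1, 2, 3], 10)
        y = simulate_phenotype((np.ones((80, 1)), comps), np.array([0.5, 1.0]), seed=6)
        res = run_gwas(y, None, G, comps, mode="exact", loco=True, chromosomes=chrom)
        plain = run_gwas(y, None, G, comps, mode="exact", chromosomes=chrom)
        assert len(res) == len(plain)
        # LOCO changes the background model, hence the p-values
        assert np.abs(np.log(res["p_value"].to_numpy())
                      - np.log(plain["p_value"].to_numpy())).max() > 1e-6


class TestGaoMeff:
    def test_duplicated_markers_collapse_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.4, 200).astype(float)
        G = np.tile(x[:, None], (1, 6))
        assert gao_meff(G) == 1

    def test_independent_markers_counted_fully(self):
        G = simulate_genotypes(4000, 12, rng=1)
        assert gao_meff(G) == 12

    def test_never_exceeds_marker_count(self):
        G = simulate_genotypes(25, 40, rng=2)
        assert gao_meff(G) <= 40

    def test_chromosome_blocks_are_summed(self):
        G = simulate_genotypes(3000, 10, rng=3)
        chrom = np.repeat([1, 2], 5)
        assert gao_meff(G, chromosomes=chrom) == gao_meff(G[:, :5]) + gao_meff(G[:, 5:])


class TestDeclareSignificant:
    def test_threshold_at_published_meff(self):
        # alpha=0.05, Meff=3527: threshold 1.4177e-5, -log10 ~ 4.85
        thr = 0.05 / 3527
        assert thr == pytest.approx(1.4177e-5, rel=1e-4)
        assert -np.log10(thr) == pytest.approx(4.8484, abs=1e-3)
        recs = pd.DataFrame({"p_value": [10**-5.61, 10**-4.87, 10**-4.5]})
        kept = declare_significant(recs, 3527)
        assert len(kept) == 2

    def test_empty_and_all_null_inputs(self):
        empty = pd.DataFrame({"p_value": []})
        assert len(declare_significant(empty, 10)) == 0
        ones = pd.DataFrame({"p_value": [1.0, 1.0]})
        assert len(declare_significant(ones, 10)) == 0


class TestBic:
    def test_single_component_hand_computation(self):
        from .conftest import random_instance

        model, _ = random_instance(50, n=20, K=1)
        fit = fit_mm(model, tol=1e-10)
        expected = -2.0 * restricted_loglik(model, fit.gamma_hat) + 1.0 * np.log(model.m)
        assert bic(fit) == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_component_order(self):
        from .conftest import random_instance

        model, _ = random_instance(51, n=30, K=3)
        comps = model.components
        reordered = build_model(model.y, model.X,
                                [Component(c.name, Z=c.Z, R=c.R)
                                 for c in [comps[1], comps[0], comps[2]]])
        f1, f2 = fit_mm(model, tol=1e-9), fit_mm(reordered, tol=1e-9)
        assert bic(f1) == pytest.approx(bic(f2), abs=1e-5)

    def test_penalizes_spurious_component(self):
        # adding a component whose true variance is 0 should raise BIC
        rng = np.random.default_rng(60)
        n = 300
        A = rng.standard_normal((n, n + 10))
        V = A @ A.T / (n + 10)
        d = 1.0 / np.sqrt(np.diag(V))
        V = V * d[:, None] * d[None, :]
        B = rng.standard_normal((n, n + 10))
        V2 = B @ B.T / (n + 10)
        d2 = 1.0 / np.sqrt(np.diag(V2))
        V2 = V2 * d2[:, None] * d2[None, :]
        X = np.ones((n, 1))
        small = [Component("g", R=V), Component("e")]
        big = [Component("g", R=V), Component("null", R=V2), Component("e")]
        wins = 0
        n_rep = 100
        for r in range(n_rep):
            y = simulate_phenotype((X, small), np.array([1.0, 1.0]), seed=90_000 + r)
            f_small = fit_mm(build_model(y, X, small), tol=1e-6, compute_se=False)
            f_big = fit_mm(build_model(y, X, big), tol=1e-6, compute_se=False)
            if bic(f_big) > bic(f_small):
                wins += 1
        assert wins >= 0.90 * n_rep

    def test_unconverged_fit_warns(self):
        from .conftest import random_instance

        model, _ = random_instance(52, n=25, K=2)
        with pytest.warns(UserWarning):
            fit = fit_mm(model, tol=1e-13, max_iter=2)
        with pytest.warns(UserWarning, match="unconverged"):
            bic(fit)
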