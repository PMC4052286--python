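"""ML fitting, fit indices, standard errors, MI, effects and bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathsem.errors import IdentificationError
from pathsem.model import PathModel
from pathsem.sem import (
    FitConfig,
    SEMParameters,
    bootstrap_fit,
    degrees_of_freedom,
    effects_decomposition,
    fit_ml,
    implied_covariance,
    modification_indices,
    rmsea,
    rmsea_pclose,
    srmr,
)
from conftest import chain_beta, chain_model, draw


class TestImpliedCovariance:
    def test_identity(self):
        assert np.allclose(implied_covariance(SEMParameters(np.zeros((3, 3)), np.eye(3))), np.eye(3))

    def test_chain_hand_computation(self):
        B = np.array([[0.0, 0.0], [0.5, 0.0]])
        Sigma = implied_covariance(SEMParameters(B, np.eye(2)))
        assert np.allclose(Sigma, [[1.0, 0.5], [0.5, 1.25]])

    def test_feedback_matrix_inverse_oracle(self):
        B = np.array([[0.0, 0.5], [0.5, 0.0]])
        Sigma = implied_covariance(SEMParameters(B, np.eye(2)))
        assert np.allclose(Sigma, [[20 / 9, 16 / 9], [16 / 9, 20 / 9]])

    def test_singular_system_errors(self):
        B = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="non-convergent"):
            implied_covariance(SEMParameters(B, np.eye(2)))

    @pytest.mark.parametrize("p,seed", [(2, 0), (3, 1), (4, 2)])
    def test_kronecker_oracle_equivalence(self, p, seed):
        """Independent oracle: solve (I-B) Sigma (I-B)' = Psi as a linear
        system in vec(Sigma) via the Kronecker identity."""
        rng = np.random.default_rng(seed)
        B = np.tril(rng.uniform(-0.6, 0.6, (p, p)), k=-1)
        d = rng.uniform(0.5, 2.0, p)
        Psi = np.diag(d)
        IB = np.eye(p) - B
        vec_sigma = np.linalg.solve(np.kron(IB, IB), Psi.reshape(-1))
        assert np.allclose(
            implied_covariance(SEMParameters(B, Psi)), vec_sigma.reshape(p, p), atol=1e-10
        )


class TestFitML:
    def test_closed_form_regression(self):
        m = PathModel(["y1", "y2"])
        m.add_beta("y2", "y1")
        fit = fit_ml(m, S=np.array([[2.0, 1.0], [1.0, 2.0]]), n=50)
        est = fit.estimates()
        assert est["y2~y1"] == pytest.approx(0.5, abs=1e-6)
        assert est["y1~~y1"] == pytest.approx(2.0, abs=1e-6)
        assert est["y2~~y2"] == pytest.approx(1.5, abs=1e-6)
        assert fit.chisq == pytest.approx(0.0, abs=1e-8) and fit.df == 0

    def test_saturated_model_zero_chisq_and_srmr(self, rng):
        m = PathModel(["y1", "y2"])
        m.add_beta("y2", "y1")
        X = rng.standard_normal((80, 2))
        fit = fit_ml(m, X)
        assert fit.chisq < 1e-6 and fit.srmr < 1e-6

    def test_simulation_recovery_within_3se(self, rng):
        m = chain_model(4)
        B = chain_beta(4, 0.6)
        X = draw(B, 2000, rng)
        fit = fit_ml(m, pd.DataFrame(X, columns=m.variables))
        est, se = fit.estimates(), fit.se
        for k in range(3):
            lbl = f"y{k + 1}~y{k}"
            assert abs(est[lbl] - 0.6) < 3 * se[lbl]
        for i in range(4):
            lbl = f"y{i}~~y{i}"
            assert abs(est[lbl] - 1.0) < 3 * se[lbl]

    def test_non_pd_covariance_errors(self):
        m = PathModel(["y1", "y2"])
        with pytest.raises(ValueError, match="positive definite"):
            fit_ml(m, S=np.array([[1.0, 1.0], [1.0, 1.0]]), n=20)

    def test_small_n_warns(self):
        m = PathModel(["y1", "y2", "y3"])
        with pytest.warns(UserWarning, match="n="):
            fit_ml(m, S=np.eye(3), n=3)

    def test_likelihood_ratio_identity(self, chain5_data):
        """chisq equals n*F and -2[logL(model) - logL(saturated)]."""
        m, X, _ = chain5_data
        fit = fit_ml(m, X)
        n, p = fit.n, 5
        sign, logdetS = np.linalg.slogdet(fit.S)
        loglik_sat = -0.5 * n * (logdetS + p + p * np.log(2 * np.pi))
        assert fit.chisq == pytest.approx(-2 * (fit.loglik - loglik_sat), rel=1e-6)

    def test_nesting_monotonicity(self, chain5_data):
        m, X, _ = chain5_data
        base = fit_ml(m, X)
        for target, source in [("y2", "y0"), ("y4", "y0"), ("y3", "y1")]:
            freed = m.copy()
            freed.add_beta(target, source)
            assert fit_ml(freed, X).chisq <= base.chisq + 1e-6


class TestDegreesOfFreedom:
    def test_published_reconstruction(self):
        m = PathModel([f"v{i}" for i in range(17)])
        added = 0
        for i in range(17):
            for j in range(i + 1, 17):
                if added < 31:
                    m.add_beta(f"v{j}", f"v{i}")
                    added += 1
        assert degrees_of_freedom(m) == 105

    def test_saturated_zero(self):
        m = PathModel(["a", "b"])
        m.add_beta("b", "a")
        assert degrees_of_freedom(m) == 0

    def test_diagonal_model(self):
        assert degrees_of_freedom(PathModel(["a", "b", "c"])) == 3

    def test_over_parameterized_errors(self):
        m = PathModel(["a", "b"])
        m.add_beta("b", "a")
        m.add_beta("a", "b")
        with pytest.raises(ValueError, match="over-parameterized"):
            degrees_of_freedom(m)


class TestFitIndices:
    def test_rmsea_published_value(self):
        assert round(rmsea(339.410, 105, 27), 3) == 0.288

    def test_rmsea_truncates_at_zero(self):
        assert rmsea(5.0, 10, 100) == 0.0

    def test_rmsea_nminus1_closed_form(self):
        cfg = FitConfig(rmsea_n_convention="N_minus_1")
        assert rmsea(20.0, 10, 101, cfg) == pytest.approx(0.1)

    def test_rmsea_d0_errors(self):
        with pytest.raises(ValueError):
            rmsea(1.0, 0, 10)

    def test_pclose_perfect_fit_not_rejected(self):
        # at chisq = d (the perfect-fit expectation) close fit is retained
        # comfortably: P well above the alpha = 0.05 rejection region
        assert rmsea_pclose(10.0, 10, 100) > 0.5

    def test_pclose_tail_limit(self):
        assert rmsea_pclose(1e4, 10, 100) < 1e-10

    def test_pclose_zero_epsilon_reduces_to_central(self):
        cfg = FitConfig(close_fit_epsilon=0.0)
        assert rmsea_pclose(12.0, 10, 50, cfg) == pytest.approx(
            stats.chi2.sf(12.0, 10)
        )

    def test_pclose_monte_carlo_oracle(self, rng):
        d, n, chisq = 8, 60, 15.0
        lam = (n - 1) * d * 0.05**2
        draws = stats.ncx2.rvs(d, lam, size=200_000, random_state=rng)
        assert rmsea_pclose(chisq, d, n) == pytest.approx(
            (draws >= chisq).mean(), abs=0.01
        )

    def test_srmr_perfect_fit(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert srmr(S, S) == 0.0

    def test_srmr_hand_computation(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        Sig = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert srmr(S, Sig) == pytest.approx(np.sqrt(0.04 / 3))

    def test_srmr_diagonal_scaling_invariance(self, rng):
        S = np.array([[2.0, 0.8, 0.1], [0.8, 1.5, 0.4], [0.1, 0.4, 3.0]])
        Sig = S + rng.normal(0, 0.05, (3, 3))
        Sig = (Sig + Sig.T) / 2
        D = np.diag([2.0, 0.5, 3.0])
        assert srmr(D @ S @ D, D @ Sig @ D) == pytest.approx(srmr(S, Sig))

    def test_srmr_dimension_mismatch(self):
        with pytest.raises(ValueError):
            srmr(np.eye(2), np.eye(3))


class TestStandardErrors:
    def test_matches_ols_large_sample(self, rng):
        # closed-form large-sample regression SE as the analytic oracle
        n = 1500
        x = rng.standard_normal(n)
        y = 0.7 * x + rng.standard_normal(n)
        m = PathModel(["x", "y"])
        m.add_beta("y", "x")
        fit = fit_ml(m, pd.DataFrame({"x": x, "y": y}))
        resid_var = fit.estimates()["y~~y"]
        se_ols = np.sqrt(resid_var / (n * x.var()))
        assert fit.se["y~x"] == pytest.approx(se_ols, rel=0.05)

    def test_underidentified_model_raises(self, rng):
        # a bow (edge plus error covariance on the same pair) is not identified
        m = PathModel(["a", "b", "c"])
        m.add_beta("b", "a")
        m.add_psi("a", "b")
        X = rng.standard_normal((200, 3))
        fit = fit_ml(m, X)
        with pytest.raises(IdentificationError, match="under-identified"):
            fit.se

    def test_se_shrinks_with_root_n(self, rng):
        m = chain_model(3)
        B = chain_beta(3)
        X = draw(B, 4000, rng)
        fit_small = fit_ml(m, pd.DataFrame(X[:1000], columns=m.variables))
        fit_large = fit_ml(m, pd.DataFrame(X, columns=m.variables))
        ratio = fit_small.se["y1~y0"] / fit_large.se["y1~y0"]
        assert ratio == pytest.approx(2.0, rel=0.25)


class TestModificationIndices:
    def test_null_candidate_is_small(self, chain5_data):
        m, X, _ = chain5_data
        fit = fit_ml(m, X)
        mi = modification_indices(fit)
        # all candidates are truly zero here: MIs behave like chi2(1) draws
        assert mi.mi.max() < stats.chi2.ppf(0.999, 1) * 2

    def test_top_candidate_matches_refit(self, rng):
        B = chain_beta(4, 0.5)
        B[2, 0] = 0.5  # misspecification: an omitted edge
        X = draw(B, 600, rng)
        m = chain_model(4)
        fit = fit_ml(m, pd.DataFrame(X, columns=m.variables))
        mi = modification_indices(fit, candidates=[("beta", "y2", "y0")])
        freed = m.copy()
        freed.add_beta("y2", "y0")
        refit = fit_ml(freed, pd.DataFrame(X, columns=m.variables))
        drop = fit.chisq - refit.chisq
        assert abs(mi.mi.iloc[0] - drop) / drop < 0.2

    def test_zero_gradient_gives_zero_mi(self):
        # Fit to the model's own implied covariance: score vanishes everywhere.
        m = chain_model(3)
        B = chain_beta(3, 0.4)
        S = implied_covariance(SEMParameters(B, np.eye(3)))
        fit = fit_ml(m, S=S, n=100)
        mi = modification_indices(fit)
        assert mi.mi.max() < 1e-6

    def test_free_candidate_rejected(self, chain5_data):
        m, X, _ = chain5_data
        fit = fit_ml(m, X)
        with pytest.raises(ValueError, match="already free"):
            modification_indices(fit, candidates=[("beta", "y1", "y0")])

    def test_epc_sign_matches_omitted_effect(self, rng):
        B = chain_beta(3, 0.5)
        B[2, 0] = -0.6
        X = draw(B, 800, rng)
        m = chain_model(3)
        fit = fit_ml(m, pd.DataFrame(X, columns=m.variables))
        mi = modification_indices(fit, candidates=[("beta", "y2", "y0")])
        assert mi.epc.iloc[0] < 0


class TestEffectsDecomposition:
    def test_chain_single_path(self):
        B = np.zeros((3, 3))
        B[1, 0] = 0.4
        B[2, 1] = 0.5
        eff = effects_decomposition(B)
        assert eff.total[2, 0] == pytest.approx(0.2)
        assert eff.direct[2, 0] == 0.0
        assert eff.indirect[2, 0] == pytest.approx(0.2)

    def test_acyclic_path_enumeration_oracle(self, rng):
        import itertools

        import networkx as nx

        p = 4
        B = np.tril(rng.uniform(-0.5, 0.5, (p, p)), k=-1)
        eff = effects_decomposition(B)
        G = nx.DiGraph()
        G.add_nodes_from(range(p))
        for i, j in zip(*np.nonzero(B)):
            G.add_edge(j, i)  # source -> target
        for tgt, src in itertools.permutations(range(p), 2):
            total = 0.0
            for path in nx.all_simple_paths(G, src, tgt):
                prod = 1.0
                for a, b in zip(path[:-1], path[1:]):
                    prod *= B[b, a]
                total += prod
            assert eff.total[tgt, src] == pytest.approx(total, abs=1e-10)

    def test_zero_beta(self):
        eff = effects_decomposition(np.zeros((3, 3)))
        assert not eff.total.any() and not eff.indirect.any()

    def test_divergent_feedback_errors(self):
        B = np.array([[0.0, 1.2], [1.1, 0.0]])
        with pytest.raises(ValueError, match="divergent"):
            effects_decomposition(B)

    def test_te_equals_de_plus_ie(self, rng):
        B = np.tril(rng.uniform(-0.4, 0.4, (5, 5)), k=-1)
        eff = effects_decomposition(B)
        assert np.allclose(eff.total, eff.direct + eff.indirect)


class TestBootstrap:
    def test_single_rep_deterministic(self, rng):
        m = chain_model(3)
        X = pd.DataFrame(draw(chain_beta(3), 120, rng), columns=m.variables)
        b1 = bootstrap_fit(m, X, reps=1, mode="nonparametric", seed=5)
        b2 = bootstrap_fit(m, X, reps=1, mode="nonparametric", seed=5)
        pd.testing.assert_frame_equal(b1.params, b2.params)

    def test_nonparametric_mean_near_point_estimate(self, rng):
        m = chain_model(3)
        X = pd.DataFrame(draw(chain_beta(3), 250, rng), columns=m.variables)
        fit = fit_ml(m, X)
        boot = bootstrap_fit(m, X, reps=200, mode="nonparametric", seed=3)
        assert boot.n_failed == 0
        lbl = "y1~y0"
        boot_se = boot.params[lbl].std(ddof=1)
        assert abs(boot.params[lbl].mean() - fit.estimates()[lbl]) < 3 * boot_se / np.sqrt(200)

    def test_model_based_ci_coverage(self):
        """Nested simulation: percentile CIs cover the true coefficient."""
        truth = 0.5
        m = chain_model(2)
        covered = 0
        rounds = 100
        outer = np.random.default_rng(11)
        for r in range(rounds):
            X = pd.DataFrame(draw(chain_beta(2, truth), 150, outer), columns=m.variables)
            boot = bootstrap_fit(m, X, reps=60, mode="model_based", seed=r)
            lo, hi = np.percentile(boot.params["y1~y0"], [2.5, 97.5])
            covered += lo <= truth <= hi
        assert 0.90 <= covered / rounds <= 1.0

    def test_invalid_inputs(self, rng):
        m = chain_model(2)
        X = pd.DataFrame(draw(chain_beta(2), 50, rng), columns=m.variables)
        with pytest.raises(ValueError):
            bootstrap_fit(m, X, reps=0)
        with pytest.raises(ValueError):
            bootstrap_fit(m, X, reps=2, mode="bogus")
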