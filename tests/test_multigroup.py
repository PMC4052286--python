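"""Two-group omnibus tests and the node/edge/on-off screens."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathsem.model import PathModel
from pathsem.multigroup import (
    GroupedData,
    adjust_pvalues,
    edge_tests,
    fit_two_group,
    node_tests,
    omnibus_cov_test,
    omnibus_mean_test,
    onoff_tests,
    two_group_analysis,
    wald_pvalue_from_ci,
)
from pathsem.sem import FitConfig
from conftest import chain_beta, chain_model, draw


def _grouped(rng, p=4, n=120, shift=None, dbeta=None, coef=0.5, mu=0.0):
    """Two samples from a p-chain; optional mean shift / edge difference in group 1."""
    names = [f"y{i}" for i in range(p)]
    B2 = chain_beta(p, coef)
    B1 = B2.copy()
    if dbeta:
        (i, j), d = dbeta
        B1[i, j] += d
    X2 = draw(B2, n, rng) + mu
    X1 = draw(B1, n, rng) + mu
    if shift:
        idx, delta = shift
        X1[:, idx] += delta  # conditional shift on a node with no children? see tests
    return GroupedData(
        pd.DataFrame(X1, columns=names), pd.DataFrame(X2, columns=names)
    )


class TestGroupedData:
    def test_column_mismatch_rejected(self, rng):
        a = pd.DataFrame(rng.standard_normal((5, 2)), columns=["a", "b"])
        b = pd.DataFrame(rng.standard_normal((5, 2)), columns=["b", "a"])
        with pytest.raises(ValueError):
            GroupedData(a, b)

    def test_minimum_samples(self, rng):
        a = pd.DataFrame(rng.standard_normal((2, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            GroupedData(a, a)

    def test_from_frames_split(self, rng):
        expr = pd.DataFrame(rng.standard_normal((6, 2)), columns=["a", "b"])
        labels = pd.Series(["x", "x", "x", "c", "c", "c"], index=expr.index)
        gd = GroupedData.from_frames(expr, labels, "x")
        assert gd.n1 == 3 and gd.n2 == 3

    def test_centering_preserves_contrasts(self, rng):
        gd = _grouped(rng, mu=8.0, shift=(2, 1.0))
        c = gd.centered()
        raw_diff = gd.group1.mean() - gd.group2.mean()
        cen_diff = c.group1.mean() - c.group2.mean()
        pd.testing.assert_series_equal(raw_diff, cen_diff, atol=1e-10, rtol=0)


class TestFitTwoGroup:
    def test_identical_data_symmetric_estimates(self, rng):
        m = chain_model(3)
        X = pd.DataFrame(draw(chain_beta(3), 80, rng), columns=m.variables)
        fit = fit_two_group(m, GroupedData(X, X.copy()), "none")
        for i, j in [(1, 0), (2, 1)]:
            b1, _ = fit.estimate("beta", i, j, 0)
            b2, _ = fit.estimate("beta", i, j, 1)
            assert b1 == pytest.approx(b2, abs=1e-5)

    def test_loglik_nesting(self, rng):
        m = chain_model(3)
        gd = _grouped(rng, p=3)
        lls = {
            c: fit_two_group(m, gd, c).loglik
            for c in ("none", "equal_means", "equal_cov_structure", "both")
        }
        assert lls["none"] >= lls["equal_means"] - 1e-8
        assert lls["none"] >= lls["equal_cov_structure"] - 1e-8
        assert min(lls["equal_means"], lls["equal_cov_structure"]) >= lls["both"] - 1e-8

    def test_equal_cov_loses_nothing_under_shared_structure(self, rng):
        """Groups share B and Psi but differ in means: imposing the equal
        covariance structure costs only a chi-square(t)-sized amount."""
        m = chain_model(4)
        gd = _grouped(rng, p=4, n=200, shift=(0, 1.5))
        free = fit_two_group(m, gd, "none")
        eq = fit_two_group(m, gd, "equal_cov_structure")
        t = m.n_free_beta + m.n_free_psi
        dchi = eq.objective - free.objective
        assert 0 <= dchi < t + 5 * np.sqrt(2 * t)

    def test_bad_constraint_name(self, rng):
        m = chain_model(3)
        with pytest.raises(ValueError, match="constraints"):
            fit_two_group(m, _grouped(rng, p=3), "equalish")


class TestOmnibusTests:
    def test_mean_df_equals_p(self, rng):
        m = chain_model(5)
        res = omnibus_mean_test(m, _grouped(rng, p=5))
        assert res.df_diff == 5

    def test_cov_df_equals_t(self, rng):
        m = chain_model(4)
        res = omnibus_cov_test(m, _grouped(rng, p=4))
        assert res.df_diff == m.n_free_beta + m.n_free_psi == 7

    def test_mean_power_two_sd_shift(self, rng):
        m = chain_model(4)
        reject = 0
        for _ in range(10):
            gd = _grouped(rng, p=4, n=100, shift=(1, 2.0))
            reject += omnibus_mean_test(m, gd).p_value < 0.001
        assert reject >= 9

    def test_cov_power_planted_edge_difference(self, rng):
        m = chain_model(4)
        reject = 0
        for _ in range(10):
            gd = _grouped(rng, p=4, n=150, dbeta=((1, 0), 0.8))
            reject += omnibus_cov_test(m, gd).p_value < 0.05
        assert reject >= 8

    def test_chisq_diff_nonnegative(self, rng):
        m = chain_model(3)
        gd = _grouped(rng, p=3)
        assert omnibus_mean_test(m, gd).chisq_diff >= 0
        assert omnibus_cov_test(m, gd).chisq_diff >= 0


class TestNodeTests:
    def test_identical_groups_no_signal(self, rng):
        m = chain_model(4)
        X = pd.DataFrame(draw(chain_beta(4), 150, rng), columns=m.variables)
        table = node_tests(m, GroupedData(X, X.copy()))
        assert np.all(np.abs(table.difference) < 1e-5)

    def test_planted_shift_recovered_with_sign(self, rng):
        """delta = 1 on the terminal node: flagged, positive, in >= 95% of reps."""
        m = chain_model(4)
        hits = 0
        reps = 30
        for _ in range(reps):
            gd = _grouped(rng, p=4, n=150, shift=(3, 1.0))
            t = node_tests(m, gd)
            row = t.set_index("variable").loc["y3"]
            hits += (row.p_value < 0.05) and (row.difference > 0)
        assert hits / reps >= 0.95

    def test_ci_is_pm_196_se(self, rng):
        m = chain_model(3)
        t = node_tests(m, _grouped(rng, p=3))
        np.testing.assert_allclose(t.ci_high - t.difference, 1.96 * t.se, atol=1e-10)

    def test_difference_is_group1_minus_group2(self, rng):
        m = chain_model(3)
        t = node_tests(m, _grouped(rng, p=3))
        np.testing.assert_allclose(t.difference, t.est_group1 - t.est_group2, atol=1e-12)


class TestEdgeTests:
    def test_identical_groups_zero_differences(self, rng):
        m = chain_model(4)
        X = pd.DataFrame(draw(chain_beta(4), 150, rng), columns=m.variables)
        t = edge_tests(m, GroupedData(X, X.copy()))
        assert np.all(np.abs(t.difference) < 1e-5)

    def test_planted_difference_is_top_hit(self, rng):
        """delta-beta = 0.7 on one edge: smallest p in >= 90% of reps."""
        m = chain_model(4)
        hits = 0
        reps = 20
        for _ in range(reps):
            gd = _grouped(rng, p=4, n=150, dbeta=((2, 1), 0.7))
            t = edge_tests(m, gd)
            hits += t.sort_values("p_value").iloc[0]["edge"] == "y2~y1"
        assert hits / reps >= 0.9

    def test_bootstrap_p_close_to_asymptotic(self, rng):
        m = chain_model(3)
        gd = _grouped(rng, p=3, n=120, dbeta=((1, 0), 0.8))
        asym = edge_tests(m, gd).set_index("edge")
        cfg = FitConfig(pvalue_method="bootstrap", bootstrap_reps=400, seed=9)
        boot = edge_tests(m, gd, cfg).set_index("edge")
        row = asym.loc["y1~y0"]
        assert abs(row.z) > 2
        assert abs(boot.loc["y1~y0", "p_value"] - row.p_value) < 0.05


class TestOnOffTests:
    def test_null_edge_off_in_both(self, rng):
        """beta = 0 in both groups: OFF/OFF at the theoretical (1-alpha)^2
        rate of about 0.90 (checked within 3 Monte-Carlo SEs)."""
        names = ["a", "b"]
        m = PathModel(names)
        m.add_beta("b", "a", provenance="kegg:activation")
        offoff = 0
        reps = 150
        for _ in range(reps):
            X1 = pd.DataFrame(rng.standard_normal((150, 2)), columns=names)
            X2 = pd.DataFrame(rng.standard_normal((150, 2)), columns=names)
            t = onoff_tests(m, GroupedData(X1, X2))
            offoff += t.onoff.iloc[0] == "OFF/OFF"
        rate, expected = offoff / reps, 0.95**2
        assert abs(rate - expected) < 3 * np.sqrt(expected * (1 - expected) / reps)

    def test_active_in_group1_only(self, rng):
        names = ["a", "b"]
        m = PathModel(names)
        m.add_beta("b", "a", provenance="kegg:activation")
        onoff = 0
        reps = 60
        for _ in range(reps):
            B1 = np.array([[0.0, 0.0], [0.8, 0.0]])
            X1 = pd.DataFrame(draw(B1, 150, rng), columns=names)
            X2 = pd.DataFrame(rng.standard_normal((150, 2)), columns=names)
            t = onoff_tests(m, GroupedData(X1, X2))
            onoff += t.onoff.iloc[0] == "ON/OFF"
        assert onoff / reps >= 0.9

    def test_inhibition_direction_is_negative(self, rng):
        names = ["a", "b"]
        m = PathModel(names)
        m.add_beta("b", "a", provenance="kegg:inhibition")
        B1 = np.array([[0.0, 0.0], [-0.8, 0.0]])
        X1 = pd.DataFrame(draw(B1, 200, rng), columns=names)
        X2 = pd.DataFrame(rng.standard_normal((200, 2)), columns=names)
        t = onoff_tests(m, GroupedData(X1, X2))
        assert t.direction.iloc[0] == "-" and t.onoff.iloc[0] == "ON/OFF"

    def test_table_columns(self, rng):
        m = chain_model(3)
        t = onoff_tests(m, _grouped(rng, p=3))
        for col in ("edge", "type", "b_group1", "p_group1", "b_group2", "p_group2", "onoff"):
            assert col in t.columns


class TestSwapAntisymmetry:
    def test_label_swap_negates_differences(self, rng):
        m = chain_model(4)
        gd = _grouped(rng, p=4, n=100, shift=(1, 1.0), dbeta=((2, 1), 0.5))
        res = two_group_analysis(m, gd)
        res_sw = two_group_analysis(m, gd.swapped())
        np.testing.assert_allclose(
            res.node_table.difference, -res_sw.node_table.difference, atol=1e-5
        )
        np.testing.assert_allclose(
            res.edge_table.difference, -res_sw.edge_table.difference, atol=1e-5
        )
        np.testing.assert_allclose(
            res.node_table.p_value, res_sw.node_table.p_value, atol=1e-5
        )
        np.testing.assert_allclose(
            res.edge_table.p_value, res_sw.edge_table.p_value, atol=1e-5
        )
        assert list(res.onoff_table.state_group1) == list(res_sw.onoff_table.state_group2)
        assert res_sw.mean_test.p_value == pytest.approx(res.mean_test.p_value, abs=1e-6)


class TestEmptyGraphReduction:
    def test_node_tests_reduce_to_mean_comparison(self, rng):
        """With no edges, t_C is a marginal two-sample mean test; the z
        statistic agrees with a direct pooled/Welch computation within 5%."""
        p, n = 3, 100
        names = [f"y{i}" for i in range(p)]
        m = PathModel(names)  # G = (Y, empty set)
        X1 = rng.standard_normal((n, p)) + [0.5, 0.0, 0.0]
        X2 = rng.standard_normal((n, p))
        gd = GroupedData(pd.DataFrame(X1, columns=names), pd.DataFrame(X2, columns=names))
        table = node_tests(m, gd).set_index("variable")
        welch = stats.ttest_ind(X1, X2, equal_var=False)
        for k, v in enumerate(names):
            assert table.loc[v, "z"] == pytest.approx(welch.statistic[k], rel=0.05)


class TestWaldFromCI:
    @pytest.mark.parametrize(
        "est,lo,hi,expected",
        [(-0.484, -0.87, -0.10, 0.014), (-1.04, -1.65, -0.43, 0.001)],
    )
    def test_published_rows(self, est, lo, hi, expected):
        assert round(wald_pvalue_from_ci(est, lo, hi), 3) == expected

    def test_centered_estimate_gives_one(self):
        assert wald_pvalue_from_ci(0.0, -1.0, 1.0) == pytest.approx(1.0)

    def test_degenerate_ci_errors(self):
        with pytest.raises(ValueError):
            wald_pvalue_from_ci(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            wald_pvalue_from_ci(5.0, -1.0, 1.0)


class TestAdjustPvalues:
    def test_none_unchanged(self):
        t = pd.DataFrame({"p_value": [0.01, 0.5]})
        assert adjust_pvalues(t, "none") is t

    def test_equal_ps_unchanged_by_bh(self):
        t = pd.DataFrame({"p_value": [0.2, 0.2, 0.2]})
        out = adjust_pvalues(t, "bh")
        np.testing.assert_allclose(out.p_value_bh, 0.2)

    def test_bh_step_up_by_hand(self):
        # step-up: 0.04*4/4, min over tail of 0.03*4/3=0.04, 0.02*4/2=0.04, 0.01*4/1=0.04
        t = pd.DataFrame({"p_value": [0.01, 0.02, 0.03, 0.04]})
        out = adjust_pvalues(t, "bh")
        np.testing.assert_allclose(out.p_value_bh, [0.04, 0.04, 0.04, 0.04])
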