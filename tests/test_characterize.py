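"""Association screens, multinomial regression, FDR/FCR, stepwise AIC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cogtraj.characterize import (
    build_design,
    compare_proportions,
    fcr_adjusted_cis,
    fdr_adjust,
    fit_multinomial,
    global_association_tests,
    monte_carlo_fisher,
    stepwise_aic,
    weighted_multinomial,
)


class TestGlobalTests:
    def _profiles(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        cls = pd.Series(rng.integers(1, 4, size=n), index=range(n))
        prof = pd.DataFrame(
            {
                "age": rng.normal(80, 5, size=n) + cls * 2,
                "flag": rng.random(n) < 0.4,
                "constant": 1.0,
            },
            index=cls.index,
        )
        return cls, prof

    def test_continuous_uses_kruskal_wallis(self):
        cls, prof = self._profiles()
        res = {r.variable: r for r in global_association_tests(cls, prof)}
        assert res["age"].test == "kruskal_wallis"
        groups = [g.to_numpy() for _, g in prof["age"].groupby(cls)]
        stat, p = stats.kruskal(*groups)
        assert res["age"].statistic == pytest.approx(stat)
        assert res["age"].p_value == pytest.approx(p)

    def test_constant_variable_skipped_with_reason(self):
        cls, prof = self._profiles()
        res = {r.variable: r for r in global_association_tests(cls, prof)}
        assert res["constant"].test == "skipped"
        assert "constant" in res["constant"].note

    def test_chi_square_hand_formula(self):
        """2x2 table [[10,20],[20,10]]: chi2 = sum (O-E)^2/E = 20/3."""
        cls = pd.Series([1] * 30 + [2] * 30)
        x = pd.Series(["a"] * 10 + ["b"] * 20 + ["a"] * 20 + ["b"] * 10)
        prof = pd.DataFrame({"x": x})
        res = global_association_tests(cls, prof)[0]
        assert res.test == "chi_square"
        assert res.statistic == pytest.approx(20 / 3)
        assert res.df == 1

    def test_kruskal_two_groups_matches_rank_arithmetic(self):
        """Brute-force H from ranks on 6 values."""
        cls = pd.Series([1, 1, 1, 2, 2, 2])
        vals = pd.Series([3.0, 1.0, 4.0, 9.0, 6.0, 5.0])
        prof = pd.DataFrame({"v": vals})
        res = global_association_tests(cls, prof)[0]
        ranks = stats.rankdata(vals)
        n = 6
        h = 12 / (n * (n + 1)) * sum(
            len(ranks[cls == g]) * ranks[cls == g].mean() ** 2 for g in (1, 2)
        ) - 3 * (n + 1)
        assert res.statistic == pytest.approx(h)

    def test_low_expected_counts_switch_to_fisher(self):
        cls = pd.Series([1] * 6 + [2] * 7)
        prof = pd.DataFrame({"x": ["a", "a", "a", "b", "b", "c",
                                   "a", "b", "b", "b", "b", "c", "c"]})
        res = global_association_tests(cls, prof)[0]
        assert res.test == "fisher_exact"

    def test_single_class_raises(self):
        cls = pd.Series([1, 1, 1])
        with pytest.raises(ValueError):
            global_association_tests(cls, pd.DataFrame({"x": [1.0, 2.0, 3.0]}))


def test_monte_carlo_fisher_matches_exact_reference():
    """2x3 table against the exact conditional test (reference value
    0.324009 computed independently with R's fisher.test)."""
    p = monte_carlo_fisher(np.array([[3, 1, 2], [1, 4, 2]]),
                          n_draws=100_000, seed=0)
    assert p == pytest.approx(0.324009, abs=0.01)


def test_monte_carlo_fisher_2x2_is_exact():
    table = np.array([[3, 7], [8, 2]])
    assert monte_carlo_fisher(table) == pytest.approx(
        stats.fisher_exact(table)[1]
    )


class TestFitMultinomial:
    def _binary_data(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {"x1": rng.normal(size=n), "x2": (rng.random(n) < 0.4).astype(float)}
        )
        eta = 0.5 + 1.2 * X["x1"] - 0.8 * X["x2"]
        y = pd.Series(
            np.where(rng.random(n) < 1 / (1 + np.exp(-eta)), 2, 1), index=X.index
        )
        return X, y

    def test_two_classes_match_independent_logistic_fit(self):
        """Binary-reduction oracle: statsmodels Logit on the same design."""
        import statsmodels.api as sm

        X, y = self._binary_data()
        m = fit_multinomial(y, X, reference_class=1, adjust=False)
        ref = sm.Logit((y == 2).astype(int), sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            m.coef.loc[2].to_numpy(), ref.params.to_numpy(), atol=1e-6
        )
        np.testing.assert_allclose(
            m.se.loc[2].to_numpy(), ref.bse.to_numpy(), atol=1e-6
        )

    def test_gradient_vanishes_and_beats_intercept_only(self):
        X, y = self._binary_data()
        m = fit_multinomial(y, X, reference_class=1, adjust=False)
        assert m.grad_norm < 1e-6
        m0 = fit_multinomial(y, X[[]], reference_class=1, adjust=False)
        assert m.loglik >= m0.loglik

    def test_null_covariate_rrr_near_one(self):
        rng = np.random.default_rng(1)
        n = 2000
        X = pd.DataFrame({"noise": rng.normal(size=n)})
        y = pd.Series(rng.integers(1, 4, size=n), index=X.index)
        m = fit_multinomial(y, X, reference_class=2, adjust=False)
        assert np.abs(np.log(m.rrr["noise"].to_numpy())).max() < 0.15
        z = (m.coef["noise"] / m.se["noise"]).abs()
        assert (z < 3).all()

    def test_known_multinomial_effects_recovered(self):
        rng = np.random.default_rng(2)
        n = 6000
        x = (rng.random(n) < 0.3).astype(float)
        # classes 1..3, reference 3; log-RRRs for x: class1 = -1, class2 = +0.5
        eta = np.column_stack([-1.0 * x, 0.5 * x, np.zeros(n)])
        p = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
        u = rng.random(n)
        y = pd.Series(1 + (p.cumsum(axis=1) < u[:, None]).sum(axis=1))
        m = fit_multinomial(y, pd.DataFrame({"x": x}), reference_class=3,
                            adjust=False)
        assert m.coef.loc[1, "x"] == pytest.approx(-1.0, abs=0.2)
        assert m.coef.loc[2, "x"] == pytest.approx(0.5, abs=0.2)

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [0.0, 0.0, 0.0, 0.0]})
        y = pd.Series([1, 2, 1, 2])
        with pytest.raises(ValueError, match="b"):
            fit_multinomial(y, X, reference_class=1)

    def test_missing_reference_class_rejected(self):
        X, y = self._binary_data()
        with pytest.raises(ValueError, match="reference"):
            fit_multinomial(y, X, reference_class=9)


class TestWeightedMultinomial:
    def test_one_hot_posteriors_reduce_to_hard_fit(self):
        rng = np.random.default_rng(3)
        n = 300
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = pd.Series(rng.integers(1, 4, size=n), index=X.index)
        P = pd.DataFrame(0.0, index=X.index, columns=[1, 2, 3])
        for c in (1, 2, 3):
            P.loc[y == c, c] = 1.0
        hard = fit_multinomial(y, X, reference_class=2, adjust=False)
        soft = weighted_multinomial(P, X, reference_class=2, adjust=False)
        np.testing.assert_allclose(
            soft.coef.to_numpy(), hard.coef.to_numpy(), atol=1e-6
        )

    def test_uniform_posteriors_carry_no_information(self):
        rng = np.random.default_rng(4)
        n = 200
        X = pd.DataFrame({"x": rng.normal(size=n)})
        P = pd.DataFrame(1 / 3, index=X.index, columns=[1, 2, 3])
        m = weighted_multinomial(P, X, reference_class=2, adjust=False)
        np.testing.assert_allclose(m.coef.to_numpy(), 0.0, atol=1e-6)

    def test_invalid_posterior_rows_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2.0]})
        P = pd.DataFrame([[0.7, 0.6], [0.5, 0.5]], index=X.index, columns=[1, 2])
        with pytest.raises(ValueError, match="sum to 1"):
            weighted_multinomial(P, X, reference_class=1)


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust(np.array([0.03])), [0.03])

    def test_bh_step_up_hand_computation(self):
        # (0.01, 0.02, 0.03, 0.04) with m=4: min over tails of p*m/rank = 0.04 each
        out = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(fdr_adjust(np.ones(7)), np.ones(7))

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(5)
        p = rng.random(50)
        adj = fdr_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_nan_passthrough(self):
        out = fdr_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2]]).all()


class TestFcrIntervals:
    def test_all_selected_gives_standard_95(self):
        lo, hi = fcr_adjusted_cis(np.zeros(3), np.ones(3), 3, 3)
        z = stats.norm.ppf(0.975)
        np.testing.assert_allclose(np.log(hi), z, atol=1e-9)
        assert z == pytest.approx(1.959964, abs=1e-6)

    def test_half_selected_widens_to_9750_level(self):
        lo, hi = fcr_adjusted_cis(np.array([0.0]), np.array([1.0]), 1, 2)
        assert np.log(hi[0]) == pytest.approx(2.2414, abs=1e-4)

    def test_zero_coef_symmetric_on_log_scale(self):
        lo, hi = fcr_adjusted_cis(np.zeros(2), np.array([0.5, 1.0]), 2, 4)
        np.testing.assert_allclose(np.log(lo), -np.log(hi))

    def test_none_selected_gives_no_intervals(self):
        lo, hi = fcr_adjusted_cis(np.zeros(2), np.ones(2), 0, 5)
        assert np.isnan(lo).all() and np.isnan(hi).all()

    def test_r_greater_than_m_rejected(self):
        with pytest.raises(ValueError):
            fcr_adjusted_cis(np.zeros(1), np.ones(1), 3, 2)


class TestStepwiseAic:
    def _setup(self, n=1500, seed=6, with_noise=True):
        rng = np.random.default_rng(seed)
        x_true = (rng.random(n) < 0.3).astype(float)
        age = rng.normal(0, 1, size=n)
        eta = np.column_stack([1.5 * x_true + 0.3 * age, np.zeros(n)])
        p = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
        y = pd.Series(1 + (p.cumsum(axis=1) < rng.random(n)[:, None]).sum(axis=1))
        X = pd.DataFrame({"signal": x_true, "age": age})
        blocks = {"signal": ["signal"], "age": ["age"]}
        if with_noise:
            X["noise"] = rng.normal(size=n)
            blocks["noise"] = ["noise"]
        return y, X, blocks

    def test_informative_block_retained(self):
        y, X, blocks = self._setup(with_noise=False)
        model, ledger = stepwise_aic(y, X, blocks, ["signal"], ["age"], 2)
        assert "signal" in model.selected_blocks
        assert (ledger["action"] == "drop").sum() == 0

    def test_noise_block_dropped(self):
        y, X, blocks = self._setup()
        model, ledger = stepwise_aic(y, X, blocks, ["signal", "noise"], ["age"], 2)
        assert "noise" not in model.selected_blocks
        assert "signal" in model.selected_blocks
        dropped = ledger.loc[ledger["action"] == "drop", "variable"].tolist()
        assert dropped == ["noise"]

    def test_forced_blocks_never_dropped(self):
        y, X, blocks = self._setup()
        model, _ = stepwise_aic(y, X, blocks, ["noise"], ["age", "signal"], 2)
        assert "age" in model.selected_blocks and "signal" in model.selected_blocks


def test_build_design_encodings():
    prof = pd.DataFrame(
        {
            "age_at_baseline": [70.0, 80.0, 90.0],
            "gender": ["Male", "Female", "Male"],
            "honos_adl": ["None", "Mild", "ModerateSevere"],
            "med_x": [True, False, True],
        }
    )
    X, blocks = build_design(
        prof, ["age_at_baseline", "gender", "honos_adl", "med_x"]
    )
    assert blocks["gender"] == ["gender[Male]"]          # Female is reference
    assert "honos_adl[None]" not in X.columns            # None is reference
    assert set(blocks["honos_adl"]) == {"honos_adl[Mild]",
                                        "honos_adl[ModerateSevere]"}
    assert X["med_x"].tolist() == [1.0, 0.0, 1.0]


class TestCompareProportions:
    def _diag(self, subjects, diag="dx"):
        return pd.DataFrame(
            {"subject_id": subjects, "diagnosis": diag,
             "date": pd.Timestamp("2011-01-01")}
        )

    def test_identical_proportions_not_significant(self):
        rng = np.random.default_rng(7)
        n = 3000
        cls = pd.Series(rng.integers(3, 5, size=n),
                        index=[f"s{i}" for i in range(n)])
        diagnosed = cls.index[rng.random(n) < 0.5]
        out = compare_proportions(cls, self._diag(diagnosed))
        assert (out["p_value"].dropna() > 0.01).all()

    def test_constructed_split_detected(self):
        """~69% of 767 vs ~59% of 310 diagnosed: Pearson chi2 p < 0.05."""
        cls = pd.Series([3] * 767 + [4] * 310,
                        index=[f"s{i}" for i in range(1077)])
        diagnosed = list(cls.index[:529]) + list(cls.index[767:767 + 183])
        out = compare_proportions(cls, self._diag(diagnosed))
        row = out[out["scope"] == "class_3_vs_4"].iloc[0]
        # oracle: hand chi-square on the same 2x2 table
        expected = stats.chi2_contingency(
            np.array([[529, 183], [767 - 529, 310 - 183]]), correction=False
        )
        assert row["p_value"] == pytest.approx(expected[1])
        assert row["p_value"] < 0.05

    def test_universal_diagnosis_skipped(self):
        cls = pd.Series([3] * 20 + [4] * 20,
                        index=[f"s{i}" for i in range(40)])
        out = compare_proportions(cls, self._diag(cls.index))
        assert (out["test"] == "skipped").all()
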