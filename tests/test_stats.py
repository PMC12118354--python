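"""Statistical battery against independent hand-computed oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from standmix.exceptions import (
    DegenerateVarianceError,
    DomainError,
    IncompleteDesignError,
)
from standmix.stats import (
    compact_letters,
    gate_and_transform,
    linear_fit,
    one_way_anova,
    pearson_matrix,
    rf_importance,
    stars,
    student_t,
    tukey_hsd,
    two_way_anova,
    zscore,
)


def brute_force_anova(groups):
    """Independent sum-of-squares decomposition by explicit loops."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df_b, df_w = len(groups) - 1, len(all_vals) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, df_b, df_w


class TestOneWay:
    def test_identical_groups(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_hand_decomposition_oracle(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        res = one_way_anova(groups)
        f, df_b, df_w = brute_force_anova(groups)
        assert f == pytest.approx(27.0, rel=1e-12)
        assert res.statistic == pytest.approx(f, rel=1e-9)
        assert res.df == (df_b, df_w)
        assert res.pvalue == pytest.approx(float(sps.f.sf(27.0, 2, 6)), rel=1e-9)

    def test_one_constant_group_is_fine(self):
        res = one_way_anova([[5, 5, 5], [1, 2, 3]])
        assert np.isfinite(res.statistic)

    def test_all_constant_groups_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            one_way_anova([[1, 1, 1], [2, 2, 2]])


class TestStudentT:
    def test_identical_samples(self):
        res = student_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_hand_formula(self):
        res = student_t([1, 2, 3], [2, 3, 4])  # pooled SD 1, diff -1, n 3+3
        assert res.statistic == pytest.approx(-1.0 / np.sqrt(2 / 3), rel=1e-9)
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == (4,)

    def test_single_observation_rejected(self):
        with pytest.raises(DomainError):
            student_t([1.0], [1, 2, 3])

    def test_t_squared_equals_f_on_two_groups(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 12))
            b = rng.normal(loc=rng.normal(), size=rng.integers(3, 12))
            t = student_t(a, b).statistic
            f = one_way_anova([a, b]).statistic
            assert t * t == pytest.approx(f, rel=1e-9)


def check_letters_against_pairwise(groups, labels, letters, alpha=0.05):
    """Brute-force partition oracle: share a letter iff not significant."""
    res = sps.tukey_hsd(*groups)
    for i, j in itertools.combinations(range(len(groups)), 2):
        share = set(letters[labels[i]]) & set(letters[labels[j]])
        if res.pvalue[i, j] < alpha:
            assert not share, (labels[i], labels[j])
        else:
            assert share, (labels[i], labels[j])


class TestTukey:
    def test_two_groups_match_student_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), rng.normal(loc=1.0, size=8)
        pairwise, _ = tukey_hsd([a, b])
        t = student_t(a, b)
        # q = sqrt(2)|t| identity between studentized range and Student's t
        q = np.sqrt(2.0) * abs(t.statistic)
        p_from_t = float(sps.studentized_range.sf(q, 2, len(a) + len(b) - 2))
        assert pairwise["p"].iloc[0] == pytest.approx(p_from_t, abs=1e-5)
        assert pairwise["p"].iloc[0] == pytest.approx(t.pvalue, abs=1e-5)

    def test_well_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(loc, 0.1, size=5) for loc in (0.0, 10.0, 20.0)]
        _, letters = tukey_hsd(groups, labels=["lo", "mid", "hi"])
        assert letters == {"hi": "a", "mid": "b", "lo": "c"}

    def test_identical_groups_share_letter(self):
        groups = [[1.0, 2.0, 3.0]] * 3
        _, letters = tukey_hsd(groups, labels=["x", "y", "z"])
        assert set(letters.values()) == {"a"}

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_letters_match_partition_oracle(self, k):
        rng = np.random.default_rng(100 + k)
        for _ in range(15):
            locs = rng.uniform(0, 6, size=k)
            groups = [rng.normal(loc, 1.0, size=6) for loc in locs]
            labels = [f"g{i}" for i in range(k)]
            _, letters = tukey_hsd(groups, labels=labels)
            check_letters_against_pairwise(groups, labels, letters)

    def test_compact_letters_orders_by_mean(self):
        letters = compact_letters(["a", "b"], [1.0, 5.0], sig_pairs=[("a", "b")])
        assert letters == {"b": "a", "a": "b"}


def brute_force_two_way(y, fa, fb):
    """Classical balanced decomposition by explicit cell loops."""
    y = np.asarray(y, float)
    grand = y.mean()
    levels_a, levels_b = sorted(set(fa)), sorted(set(fb))
    ss_a = sum(
        np.sum(np.asarray(fa) == a) * (y[np.asarray(fa) == a].mean() - grand) ** 2
        for a in levels_a
    )
    ss_b = sum(
        np.sum(np.asarray(fb) == b) * (y[np.asarray(fb) == b].mean() - grand) ** 2
        for b in levels_b
    )
    ss_cells = 0.0
    for a in levels_a:
        for b in levels_b:
            mask = (np.asarray(fa) == a) & (np.asarray(fb) == b)
            ss_cells += mask.sum() * (y[mask].mean() - grand) ** 2
    ss_t = ((y - grand) ** 2).sum()
    return ss_a, ss_b, ss_cells - ss_a - ss_b, ss_t - ss_cells


class TestTwoWay:
    @staticmethod
    def _balanced(rng, n_per_cell=4, effect=None):
        fa, fb, y = [], [], []
        for a in ("a1", "a2"):
            for b in ("b1", "b2", "b3"):
                mu = effect(a, b) if effect else 0.0
                for _ in range(n_per_cell):
                    fa.append(a)
                    fb.append(b)
                    y.append(mu + rng.normal())
        return np.array(y), fa, fb

    def test_decomposition_matches_brute_force(self):
        rng = np.random.default_rng(7)
        y, fa, fb = self._balanced(rng)
        table = two_way_anova(y, fa, fb, a_name="A", b_name="B")
        ss = brute_force_two_way(y, fa, fb)
        for term, expected in zip(["A", "B", "A:B", "Residual"], ss):
            got = float(table.loc[table.term == term, "sum_sq"].iloc[0])
            assert got == pytest.approx(expected, rel=1e-9)
        # decomposition identity
        assert table["sum_sq"].sum() == pytest.approx(((y - y.mean()) ** 2).sum(), rel=1e-9)

    def test_pure_additive_effects_give_zero_interaction(self):
        effects = {"a1": 0.0, "a2": 3.0, "b1": 0.0, "b2": 1.0, "b3": 2.0}
        fa, fb, y = [], [], []
        for a in ("a1", "a2"):
            for b in ("b1", "b2", "b3"):
                for _ in range(3):
                    fa.append(a)
                    fb.append(b)
                    y.append(effects[a] + effects[b])
        # add tiny per-cell noise so residual variance exists
        rng = np.random.default_rng(0)
        y = np.array(y) + rng.normal(scale=1e-6, size=len(y))
        table = two_way_anova(y, fa, fb)
        ss_int = float(table.loc[table.term == "A:B", "sum_sq"].iloc[0])
        ss_a = float(table.loc[table.term == "A", "sum_sq"].iloc[0])
        # additive cell means put all structure in the main effects
        assert ss_int < 1e-9 * ss_a
        assert float(table.loc[table.term == "A:B", "p"].iloc[0]) > 0.5

    def test_constructed_interaction_is_detected(self):
        rng = np.random.default_rng(1)
        fa, fb, y = [], [], []
        means = {("a1", "b1"): 0, ("a1", "b2"): 0, ("a2", "b1"): 0, ("a2", "b2"): 1}
        for (a, b), mu in means.items():
            for _ in range(3):
                fa.append(a)
                fb.append(b)
                y.append(mu + rng.normal(scale=0.01))
        table = two_way_anova(np.array(y), fa, fb)
        assert float(table.loc[table.term == "A:B", "p"].iloc[0]) < 0.001

    def test_balanced_path_agrees_with_statsmodels_type2(self):
        import statsmodels.api as smapi
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        y, fa, fb = self._balanced(rng, effect=lambda a, b: (a == "a2") * 1.0)
        ours = two_way_anova(y, fa, fb, a_name="A", b_name="B")
        frame = pd.DataFrame({"y": y, "fa": fa, "fb": fb})
        ref = smapi.stats.anova_lm(smf.ols("y ~ C(fa) * C(fb)", frame).fit(), typ=2)
        for term, ref_term in (("A", "C(fa)"), ("B", "C(fb)"), ("A:B", "C(fa):C(fb)")):
            assert float(ours.loc[ours.term == term, "sum_sq"].iloc[0]) == pytest.approx(
                float(ref.loc[ref_term, "sum_sq"]), rel=1e-9
            )

    def test_unbalanced_uses_type2_and_runs(self):
        rng = np.random.default_rng(4)
        y, fa, fb = self._balanced(rng)
        y = np.append(y, [0.5, 0.1])
        fa += ["a1", "a1"]
        fb += ["b1", "b2"]
        table = two_way_anova(np.asarray(y), fa, fb)
        assert set(table.term) == {"A", "B", "A:B", "Residual"}
        assert table["p"].iloc[:3].between(0, 1).all()

    def test_empty_cell_named(self):
        with pytest.raises(IncompleteDesignError, match="a2.*b2"):
            two_way_anova(
                [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                ["a1", "a1", "a1", "a1", "a2", "a2"],
                ["b1", "b2", "b1", "b2", "b1", "b1"],
            )


class TestCorrelationRegression:
    def test_perfect_correlations(self):
        x = np.arange(5.0)
        table = pd.DataFrame({"x": x, "y": 2 * x, "z": -x})
        corr = pearson_matrix(table)
        assert corr.r.loc["x", "y"] == pytest.approx(1.0)
        assert corr.r.loc["x", "z"] == pytest.approx(-1.0)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        corr = pearson_matrix(table)
        np.testing.assert_allclose(corr.r.to_numpy(), corr.r.to_numpy().T)
        np.testing.assert_allclose(np.diag(corr.r.to_numpy()), 1.0)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame({"x": rng.normal(size=1000), "y": rng.normal(size=1000)})
        corr = pearson_matrix(table)
        assert abs(corr.r.loc["x", "y"]) < 0.1
        assert corr.p.loc["x", "y"] > 0.001

    def test_zero_variance_warned_and_missing(self):
        table = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning):
            corr = pearson_matrix(table)
        assert np.isnan(corr.r.loc["x", "y"])

    def test_star_thresholds(self):
        assert stars(0.0005) == "***"
        assert stars(0.005) == "**"
        assert stars(0.04) == "*"
        assert stars(0.2) == ""

    def test_exact_line(self):
        x = np.arange(10.0)
        fit = linear_fit(x, 3 * x + 1)
        assert fit.effect["slope"] == pytest.approx(3.0)
        assert fit.effect["intercept"] == pytest.approx(1.0)
        assert fit.effect["r_squared"] == pytest.approx(1.0)

    def test_constant_response(self):
        fit = linear_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert fit.effect["slope"] == 0.0 and fit.effect["r_squared"] == 0.0

    def test_r_squared_equals_pearson_r_squared(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        fit = linear_fit(x, y)
        r = sps.pearsonr(x, y).statistic
        assert fit.effect["r_squared"] == pytest.approx(r * r, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestZscore:
    def test_standardises(self):
        out = zscore(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert out["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["a"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame({"a": rng.normal(size=20)})
        once = zscore(table)
        twice = zscore(once)
        np.testing.assert_allclose(once["a"], twice["a"], atol=1e-12)

    def test_constant_column_named(self):
        with pytest.raises(DomainError, match="flat"):
            zscore(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))


class TestGate:
    def test_normal_data_untransformed(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(10, 1, 30) for _ in range(3)]
        out, report = gate_and_transform(groups)
        assert report.transform == "none"
        np.testing.assert_array_equal(out[0], groups[0])

    def test_lognormal_data_transformed_and_improved(self):
        triggered, improved = 0, 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            groups = [np.exp(rng.normal(0, 1.2, 25)) for _ in range(3)]
            _, report = gate_and_transform(groups)
            if report.transform == "log":
                triggered += 1
                if not report.rounds[1]["failed"]:
                    improved += 1
        assert triggered >= 35  # strong lognormality almost always trips the gate
        assert improved / triggered > 0.8  # log restores normality most of the time

    def test_zero_value_with_transform_required(self):
        rng = np.random.default_rng(11)
        groups = [np.exp(rng.normal(0, 1.5, 25)) for _ in range(2)]
        groups[0][0] = 0.0
        with pytest.raises(DomainError):
            gate_and_transform(groups)


class TestForest:
    @staticmethod
    def _signal_data(seed, n=120):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, 4)), columns=["x1", "x2", "x3", "x4"]
        )
        y = X["x1"] + 0.1 * rng.normal(size=n)
        return X, y

    def test_deterministic_under_seed(self):
        X, y = self._signal_data(0)
        a = rf_importance(X, y, n_trees=80, seed=5)
        b = rf_importance(X, y, n_trees=80, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_informative_predictor_dominates(self):
        X, y = self._signal_data(1)
        table = rf_importance(X, y, n_trees=120, seed=3)
        assert table.iloc[0]["predictor"] == "x1"
        assert table.iloc[0]["pct_inc_mse"] > 10 * abs(table.iloc[1]["pct_inc_mse"])

    def test_too_few_rows_rejected(self):
        X, y = self._signal_data(2, n=8)
        with pytest.raises(DomainError):
            rf_importance(X, y, n_trees=10, seed=0)

    def test_more_predictors_than_rows_warns(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(12, 20)))
        X.columns = [f"p{i}" for i in range(20)]
        y = rng.normal(size=12)
        with pytest.warns(UserWarning):
            rf_importance(X, y, n_trees=20, seed=0)
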