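"""Inferential layer: classical tests against oracles, stepwise regression,
bootstrap replicability, and the calibrated Bayes factor."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from limbrsa.stats import (
    bootstrap_stepwise,
    calibrated_bayes_factor,
    classify_trials,
    group_ttest,
    icc_consistency,
    mann_whitney,
    mixed_anova,
    one_sample_ttest,
    partial_correlation,
    spearman,
    stepwise_forward,
)


class TestTTests:
    def test_identical_paired_samples(self, rng):
        x = rng.normal(size=10)
        res = group_ttest(x, x, paired=True, family_size=3)
        assert res.statistic == 0.0
        assert res.p == 1.0
        assert res.alpha_adjusted == pytest.approx(0.05 / 3)

    def test_equal_means_independent(self):
        res = group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.dof == 4

    def test_pooled_variance_formula_oracle(self, rng):
        """Matches the textbook pooled-variance t computed from scratch."""
        for _ in range(20):
            a = rng.normal(size=rng.integers(4, 12))
            b = rng.normal(size=rng.integers(4, 12))
            res = group_ttest(a, b)
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            assert res.statistic == pytest.approx(t_oracle, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            group_ttest([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_one_sample_symmetric(self):
        res = one_sample_ttest([-2.0, -1.0, 1.0, 2.0], mu=0.0)
        assert res.statistic == pytest.approx(0.0)

    def test_one_sample_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_ttest([1.0, 1.0, 1.0], mu=1.0)

    def test_one_sample_formula_oracle(self, rng):
        x = rng.normal(size=9)
        res = one_sample_ttest(x, mu=0.3)
        t_oracle = (x.mean() - 0.3) / (x.std(ddof=1) / 3.0)
        assert res.statistic == pytest.approx(t_oracle, abs=1e-10)


class TestSpearman:
    def test_monotone(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.statistic == pytest.approx(1.0)

    def test_reversed(self):
        res = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.statistic == pytest.approx(-1.0)

    def test_rank_then_pearson_oracle(self, rng):
        x, y = rng.normal(size=25), rng.normal(size=25)
        res = spearman(x, y)
        oracle = np.corrcoef(scipy.stats.rankdata(x), scipy.stats.rankdata(y))[0, 1]
        assert res.statistic == pytest.approx(oracle, abs=1e-12)


class TestPartialCorrelation:
    def test_independent_covariate_matches_simple_regression(self, rng):
        n = 200
        x = rng.normal(size=n)
        cov = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        res = partial_correlation(y, x, cov)
        import statsmodels.api as sm

        simple = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.statistic == pytest.approx(simple.params[1], abs=0.05)

    def test_fully_explained_by_covariate(self, rng):
        n = 60
        cov = rng.normal(size=n)
        x = rng.normal(size=n)
        eps = rng.normal(size=n)
        # noise orthogonalized against x so the partial effect of x is exactly 0
        z = np.column_stack([np.ones(n), x, cov])
        eps -= z @ np.linalg.lstsq(z, eps, rcond=None)[0]
        y = 2.0 * cov + 0.1 * eps
        res = partial_correlation(y, x, cov)
        assert abs(res.statistic) < 1e-10
        assert res.p > 0.99

    def test_frisch_waugh_oracle(self, rng):
        """Coefficient equals the residual-on-residual regression slope."""
        n = 50
        cov = rng.normal(size=(n, 2))
        x = rng.normal(size=n) + cov @ [0.4, -0.2]
        y = 0.7 * x + cov @ [1.0, 0.5] + rng.normal(size=n)
        res = partial_correlation(y, x, cov)
        z = np.column_stack([np.ones(n), cov])
        rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
        ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
        slope = (rx @ ry) / (rx @ rx)
        assert res.statistic == pytest.approx(slope, abs=1e-8)

    def test_collinear_rejected(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(rng.normal(size=20), x, x)


def _mixed_df(values_by_group_area, subjects_per_group):
    rows = []
    sid = 0
    for g, per_area in values_by_group_area.items():
        for s in range(subjects_per_group):
            for area, vals in per_area.items():
                rows.append(
                    {"subject": f"s{sid}", "group": g, "area": area, "value": vals[s]}
                )
            sid += 1
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_no_interaction_when_area_effect_shared(self, rng):
        n = 12
        base = {g: rng.normal(size=n) for g in "abc"}
        data = _mixed_df(
            {g: {"x": base[g], "y": base[g] + 1.0 + 0.3 * rng.normal(size=n)} for g in "abc"},
            n,
        )
        res = mixed_anova(data, dv="value", between="group", within="area", subject="subject")
        assert res.p > 0.05  # shared area effect: no systematic interaction

    def test_injected_interaction_detected(self, rng):
        n = 12
        data = _mixed_df(
            {
                "a": {"x": rng.normal(size=n), "y": rng.normal(size=n) + 3.0},
                "b": {"x": rng.normal(size=n), "y": rng.normal(size=n)},
                "c": {"x": rng.normal(size=n), "y": rng.normal(size=n)},
            },
            n,
        )
        res = mixed_anova(data, dv="value", between="group", within="area", subject="subject")
        assert res.p < 0.05

    def test_sums_of_squares_oracle(self, rng):
        """Balanced two-level within design: interaction F from definitional
        sums of squares computed from scratch."""
        n = 8
        groups = ["a", "b", "c"]
        y = {g: {"x": rng.normal(size=n), "y": rng.normal(size=n)} for g in groups}
        data = _mixed_df(y, n)
        res = mixed_anova(data, dv="value", between="group", within="area", subject="subject")

        # oracle: classic split-plot decomposition
        arr = np.array([[y[g]["x"], y[g]["y"]] for g in groups])  # g x area x subj
        grand = arr.mean()
        g_means = arr.mean(axis=(1, 2))
        a_means = arr.mean(axis=(0, 2))
        ga_means = arr.mean(axis=2)
        subj_means = arr.mean(axis=1)  # g x subj
        k = 2
        ss_ga = n * np.sum(
            (ga_means - g_means[:, None] - a_means[None, :] + grand) ** 2
        )
        ss_within_subj_err = 0.0
        for gi in range(3):
            for si in range(n):
                for ai in range(k):
                    pred = (
                        subj_means[gi, si]
                        + ga_means[gi, ai]
                        - g_means[gi]
                    )
                    ss_within_subj_err += (arr[gi, ai, si] - pred) ** 2
        df_ga = (3 - 1) * (k - 1)
        df_err = (3 * n - 3) * (k - 1)
        f_oracle = (ss_ga / df_ga) / (ss_within_subj_err / df_err)
        assert res.statistic == pytest.approx(f_oracle, abs=1e-8)
        assert res.dof == (df_ga, df_err)

    def test_missing_cell_rejected(self, rng):
        data = _mixed_df({"a": {"x": rng.normal(size=4), "y": rng.normal(size=4)}}, 4)
        data = data.drop(index=0)
        with pytest.raises(ValueError):
            mixed_anova(data, dv="value", between="group", within="area", subject="subject")


def mann_whitney_enumeration_p(a, b):
    """Exact two-sided p by enumerating every assignment of ranks."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(combined)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = []
    for comb in itertools.combinations(range(na + nb), na):
        r = ranks[list(comb)]
        us.append(r.sum() - na * (na + 1) / 2)
    us = np.array(us)
    p_ge = np.mean(us >= u_obs)
    p_le = np.mean(us <= u_obs)
    return min(1.0, 2 * min(p_ge, p_le))


class TestMannWhitney:
    def test_maximal_separation(self):
        a = [10.0, 11.0, 12.0]
        b = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(a, b)
        assert res.statistic == len(a) * len(b)

    def test_exact_p_matches_enumeration(self, rng):
        for _ in range(5):
            a = rng.normal(size=3)
            b = rng.normal(size=9)
            res = mann_whitney(a, b)
            assert res.extra["method"] == "exact"
            assert res.p == pytest.approx(mann_whitney_enumeration_p(a, b), abs=1e-12)

    def test_exact_enumeration_all_small_sizes(self, rng):
        """Exact p equals full enumeration for every split of combined n <= 12."""
        for na in range(1, 6):
            nb_max = 12 - na
            for nb in range(1, nb_max + 1):
                a = rng.normal(size=na)
                b = rng.normal(size=nb)
                res = mann_whitney(a, b)
                assert res.p == pytest.approx(mann_whitney_enumeration_p(a, b), abs=1e-12)

    def test_ties_handled(self):
        res = mann_whitney([1.0], [1.0])
        assert np.isfinite(res.p)


class TestICC:
    def test_identical_sessions(self, rng):
        x = rng.normal(size=12)
        res = icc_consistency(x, x)
        assert res.statistic == pytest.approx(1.0)

    def test_independent_sessions_near_zero(self, rng):
        res = icc_consistency(rng.normal(size=10000), rng.normal(size=10000))
        assert abs(res.statistic) < 0.05

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        s1 = rng.normal(size=14)
        s2 = 0.7 * s1 + rng.normal(size=14) * 0.5
        res = icc_consistency(s1, s2)
        df = pd.DataFrame(
            {
                "targets": np.tile(np.arange(14), 2),
                "raters": np.repeat(["r1", "r2"], 14),
                "ratings": np.concatenate([s1, s2]),
            }
        )
        icc3 = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
        row = icc3[icc3["Type"] == "ICC(C,1)"].iloc[0]
        assert res.statistic == pytest.approx(row["ICC"], abs=1e-8)
        assert res.extra["F"] == pytest.approx(row["F"], abs=1e-8)
        assert res.dof == (row["df1"], row["df2"])
        # pingouin rounds the CI bounds to two decimals
        np.testing.assert_allclose(res.extra["ci95"], list(row["CI95"]), atol=6e-3)


class TestClassifyTrials:
    def test_degenerate_identical_channels_tie_break(self):
        traces = np.ones((2, 5, 30))
        tcs = np.tile(np.sin(np.linspace(0, 6, 30)), (2, 1))
        with pytest.warns(UserWarning, match="tied"):
            assign, _ = classify_trials(traces, tcs, instructed_digit=[0, 0])
        assert np.all(assign == 0)

    def test_exact_waveform_classified(self, rng):
        tcs = np.tile(np.sin(np.linspace(0, 6, 50)), (10, 1))
        traces = rng.normal(size=(10, 5, 50)) * 0.01
        instructed = rng.integers(0, 5, size=10)
        for k in range(10):
            traces[k, instructed[k]] += tcs[k]
        assign, pct = classify_trials(traces, tcs, instructed_digit=instructed)
        assert pct == 100.0


class TestStepwise:
    def test_perfect_predictor_selected(self, rng):
        n = 30
        x1 = rng.normal(size=n)
        X = np.column_stack([x1, rng.normal(size=n), rng.normal(size=n)])
        model = stepwise_forward(x1.copy(), X, names=["x1", "n1", "n2"])
        assert model.included == ["x1"]
        assert model.r2 == pytest.approx(1.0)

    def test_orthogonal_predictors_give_intercept_only(self, rng):
        n = 40
        y = rng.normal(size=n)
        y -= y.mean()
        # construct predictors exactly orthogonal to y
        X = rng.normal(size=(n, 3))
        X -= np.outer(y, y @ X) / (y @ y)
        model = stepwise_forward(y, X)
        assert model.included == []
        assert model.intercept == pytest.approx(y.mean() + 0.0, abs=1e-10)

    def test_greedy_path_matches_exhaustive_oracle(self, rng):
        """The selection path equals a brute-force evaluation of every
        candidate's R-squared at each step."""
        n = 60
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        X = np.column_stack([x1, x2, rng.normal(size=n), rng.normal(size=n)])
        y = 0.8 * x1 + 0.5 * x2 + 0.3 * rng.normal(size=n)
        model = stepwise_forward(y, X, delta_r2=0.1)

        def r2_of(cols):
            xx = np.column_stack([np.ones(n)] + [X[:, j] for j in cols])
            beta = np.linalg.lstsq(xx, y, rcond=None)[0]
            resid = y - xx @ beta
            return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

        included, current = [], 0.0
        while True:
            cand = [j for j in range(4) if j not in included]
            gains = [(r2_of(included + [j]) - current, j) for j in cand]
            best_gain, best_j = max(gains, key=lambda t: (t[0], -t[1]))
            if best_gain <= 0.1:
                break
            included.append(best_j)
            current += best_gain
        assert model.included == [f"x{j + 1}" for j in included]

    def test_coefficients_reproduce_fit(self, rng):
        n = 40
        X = rng.normal(size=(n, 3))
        y = X @ [1.0, -0.5, 0.0] + 0.1 * rng.normal(size=n)
        model = stepwise_forward(y, X, delta_r2=0.05)
        idx = [int(name[1:]) - 1 for name in model.included]
        fitted = model.intercept + X[:, idx] @ model.coefficients
        resid_var = np.var(y - fitted)
        assert 1 - resid_var / np.var(y) == pytest.approx(model.r2, abs=1e-10)


class TestBootstrapStepwise:
    def test_perfect_predictor_always_included(self, rng):
        n = 25
        x1 = rng.normal(size=n)
        X = np.column_stack([x1, rng.normal(size=n)])
        summary = bootstrap_stepwise(x1.copy(), X, B=100, seed=5, names=["x1", "noise"])
        assert summary.inclusion_proportion["x1"] == 1.0

    def test_determinism(self, rng):
        n = 20
        X = rng.normal(size=(n, 4))
        y = X[:, 0] + rng.normal(size=n)
        s1 = bootstrap_stepwise(y, X, B=50, seed=9)
        s2 = bootstrap_stepwise(y, X, B=50, seed=9)
        assert s1.inclusion_proportion == s2.inclusion_proportion
        assert s1.adj_r2_ci == s2.adj_r2_ci

    def test_pure_noise_rarely_included(self):
        """Under the null at n=18 no single noise predictor dominates."""
        rng = np.random.default_rng(31)
        y = rng.normal(size=18)
        X = rng.normal(size=(18, 4))
        summary = bootstrap_stepwise(y, X, B=400, seed=13)
        assert all(p < 0.5 for p in summary.inclusion_proportion.values())


def bayes_factor_grid_oracle(effect, se, dof, prior_scale, prior_dof, tail="positive"):
    """Independent fixed-grid (Simpson) quadrature of the same model."""
    sign = 1.0 if tail == "positive" else -1.0
    u = np.linspace(0.0, 12.0, 48001)
    delta = sign * u * prior_scale
    like = scipy.stats.t.pdf((effect - delta) / se, dof) / se
    prior = 2.0 * scipy.stats.t.pdf(u, prior_dof)
    mass = 2.0 * (scipy.stats.t.cdf(12.0, prior_dof) - 0.5)
    marginal = scipy.integrate.simpson(prior * like, x=u) / mass
    return marginal / (scipy.stats.t.pdf(effect / se, dof) / se)


import scipy.integrate  # noqa: E402


class TestCalibratedBayesFactor:
    def test_vanishing_prior_width_gives_unity(self):
        res = calibrated_bayes_factor(0.4, 0.1, 28, prior_scale=1e-8, prior_dof=23)
        assert abs(res.bf - 1.0) < 1e-3

    def test_null_effect_supports_null(self):
        res = calibrated_bayes_factor(0.0, 0.1, 28, prior_scale=0.5, prior_dof=23)
        assert res.bf < 1 / 3
        assert res.supports_null

    def test_prior_sized_effect_supports_alternative(self):
        res = calibrated_bayes_factor(0.5, 0.1, 28, prior_scale=0.5, prior_dof=23)
        assert res.bf > 3

    def test_matches_grid_oracle(self):
        for effect, se, scale in [(0.0, 0.1, 0.5), (0.3, 0.08, 0.5), (-0.2, 0.15, 0.4), (0.5, 0.1, 0.5)]:
            res = calibrated_bayes_factor(effect, se, 28, prior_scale=scale, prior_dof=23)
            oracle = bayes_factor_grid_oracle(effect, se, 28, scale, 23)
            assert res.bf == pytest.approx(oracle, abs=1e-6, rel=1e-6)

    def test_monotone_in_effect_along_tail(self):
        bfs = [
            calibrated_bayes_factor(e, 0.1, 28, prior_scale=0.5, prior_dof=23).bf
            for e in np.linspace(0.0, 0.8, 9)
        ]
        assert np.all(np.diff(bfs) > 0)

    def test_negative_tail_mirrors_positive(self):
        pos = calibrated_bayes_factor(0.3, 0.1, 28, 0.5, 23, tail="positive")
        neg = calibrated_bayes_factor(-0.3, 0.1, 28, 0.5, 23, tail="negative")
        assert pos.bf == pytest.approx(neg.bf, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            calibrated_bayes_factor(0.1, 0.0, 10, 0.5, 10)
        with pytest.raises(ValueError):
            calibrated_bayes_factor(0.1, 0.1, 10, -0.5, 10)


class TestFamilywiseError:
    def test_bonferroni_controls_three_comparison_family(self):
        """Across null families of three group contrasts, the any-rejection
        rate at alpha = 0.05/3 stays near or below 0.05."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_fam = 400
        for _ in range(n_fam):
            a, b, c = rng.normal(size=18), rng.normal(size=13), rng.normal(size=12)
            ps = [
                group_ttest(a, c, family_size=3).p,
                group_ttest(a, b, family_size=3).p,
                group_ttest(b, c, family_size=3).p,
            ]
            if min(ps) < 0.05 / 3:
                rejections += 1
        assert rejections / n_fam <= 0.07
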