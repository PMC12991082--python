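"""Interaction regression, Johnson-Neyman, piecewise, sigmoid, LOESS, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vasotrace import synthgen as sg
from vasotrace import trajstats as ts
from vasotrace.exceptions import (DegenerateCurveError, InvalidArgumentError,
                                  SingularDesignError)


def constructed_jn_fit(r1, r2, df=219, curvature=0.95):
    """Build (beta, V) whose JN quadratic has roots exactly at r1 and r2."""
    t_crit = stats.t.ppf(0.975, df)
    b3 = 1.0
    v33 = (b3 ** 2 - curvature) / t_crit ** 2
    b1 = -curvature * (r1 + r2) / 2
    v11 = (b1 ** 2 - curvature * r1 * r2) / t_crit ** 2
    cov = np.zeros((4, 4))
    cov[1, 1], cov[3, 3] = v11, v33
    params = np.array([0.0, b1, 0.0, b3])
    return ts.InteractionModelFit(params=params, cov=cov, df_resid=df, n=df + 4)


class TestInteractionModel:
    def test_exact_recovery_noise_free(self):
        tab = sg.simulate_cohort(sg.CohortSimSpec(
            age_slope=0.02, group_effect=0.1, interaction_coef=0.03,
            noise_sd=0.0))
        fit = ts.fit_interaction_model(tab, "outcome", "group", "age")
        np.testing.assert_allclose(fit.params, [1.2, 0.1, 0.02, 0.03], atol=1e-8)
        assert fit.df_resid == fit.n - 4

    def test_covariance_symmetric_psd(self):
        tab = sg.simulate_cohort(sg.CohortSimSpec(noise_sd=0.2, seed=3))
        fit = ts.fit_interaction_model(tab, "outcome", "group", "age")
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(fit.cov) > -1e-12)

    def test_duplicated_predictor_rejected(self):
        tab = sg.simulate_cohort(sg.CohortSimSpec(noise_sd=0.1))
        tab["age2"] = tab["age"]
        with pytest.raises(SingularDesignError):
            ts.fit_interaction_model(tab, "outcome", "age", "age2")

    def test_estimator_unbiased(self):
        """Mean coefficient error < 2 SE / sqrt(reps) over simulations."""
        true = np.array([1.2, 0.1, 0.02, 0.03])
        reps, errs, ses = 200, [], []
        for seed in range(reps):
            tab = sg.simulate_cohort(sg.CohortSimSpec(
                n_per_cell=3, age_slope=0.02, group_effect=0.1,
                interaction_coef=0.03, noise_sd=0.1, seed=seed))
            fit = ts.fit_interaction_model(tab, "outcome", "group", "age")
            errs.append(fit.params - true)
            ses.append(fit.bse)
        mean_err = np.abs(np.mean(errs, axis=0))
        bound = 2 * np.mean(ses, axis=0) / np.sqrt(reps)
        assert np.all(mean_err < bound)


class TestJohnsonNeyman:
    def test_constructed_roots_recovered(self):
        fit = constructed_jn_fit(7.3, 15.0)
        jn = ts.johnson_neyman(fit, (3.0, 18.0))
        np.testing.assert_allclose(jn.boundaries, [7.3, 15.0], atol=1e-6)
        # joint effect significant in the young and old intervals
        assert jn.significant_regions[0][0] == 3.0
        assert jn.significant_regions[-1][1] == 18.0

    def test_no_interaction_whole_range_significant(self):
        cov = np.diag([1e-4, 1e-4, 1e-4, 1e-8])
        fit = ts.InteractionModelFit(params=np.array([0.0, 5.0, 0.0, 0.0]),
                                     cov=cov, df_resid=100, n=104)
        jn = ts.johnson_neyman(fit, (0.0, 10.0))
        assert jn.significant_regions == [(0.0, 10.0)]

    def test_alpha_to_one_limit(self):
        # conditional effect with no zero crossing inside the range: as
        # t_crit -> 0 the whole observed range becomes significant
        fit = constructed_jn_fit(-30.0, -10.0)
        jn = ts.johnson_neyman(fit, (0.0, 10.0), alpha=0.9999)
        assert jn.significant_regions == [(0.0, 10.0)]

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_grid_oracle_on_random_fits(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(4, 4)) * 0.3
        cov = A @ A.T + np.eye(4) * 1e-6
        fit = ts.InteractionModelFit(params=rng.normal(0, 1, 4), cov=cov,
                                     df_resid=int(rng.integers(20, 300)),
                                     n=300)
        lo, hi = 0.0, 20.0
        jn = ts.johnson_neyman(fit, (lo, hi))
        grid = np.linspace(lo, hi, 1000)
        theta, se = ts._theta_se(fit, grid)
        sig = np.abs(theta) / se > jn.t_crit
        step = grid[1] - grid[0]
        flips = grid[np.flatnonzero(np.diff(sig.astype(int)))]
        assert len(flips) == len(jn.boundaries)
        for f, bdy in zip(flips, jn.boundaries):
            assert abs(f - bdy) < step
        # region membership agrees pointwise away from boundaries
        for g, s in zip(grid[::37], sig[::37]):
            if any(abs(g - b) < step for b in jn.boundaries):
                continue
            inside = any(a <= g <= b for a, b in jn.significant_regions)
            assert inside == bool(s)


class TestPiecewise:
    def test_exact_two_slope_recovery(self):
        tab = sg.simulate_cohort(sg.CohortSimSpec(n_per_cell=10, noise_sd=0.0))
        tab["y"] = np.where(tab["age"] <= 8, 2.0 * tab["age"], 16.0)
        lo, hi = ts.piecewise_fit(tab, "y", "age", knot=8.0)
        assert lo.slope == pytest.approx(2.0, abs=1e-8)
        assert hi.slope == pytest.approx(0.0, abs=1e-8)

    def test_knot_at_max_leaves_right_absent(self):
        tab = sg.simulate_cohort(sg.CohortSimSpec(noise_sd=0.1))
        lo, hi = ts.piecewise_fit(tab, "outcome", "age", knot=18.0)
        assert lo is not None and hi is None

    def test_slope_ci_coverage(self):
        """95% CI covers the true below-knot slope at the nominal rate."""
        hits = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            age = rng.uniform(3, 18, 60)
            y = np.where(age <= 8, 1.5 * age, 12.0) + rng.normal(0, 1.0, 60)
            tab = pd.DataFrame({"age": age, "y": y})
            lo, _ = ts.piecewise_fit(tab, "y", "age", knot=8.0)
            a, b = lo.slope_ci()
            hits += a <= 1.5 <= b
        assert 0.90 <= hits / reps <= 0.99


class TestSigmoid:
    def test_noise_free_inflection_recovery(self):
        ages = np.linspace(3, 18, 40)
        y = sg.sigmoid(ages, 0.0, 30.0, 0.8, 12.04)
        fit = ts.sigmoid_fit(ages, y)
        assert fit.converged
        assert fit.inflection == pytest.approx(12.04, abs=1e-4)
        assert fit.upper >= fit.lower

    def test_constant_data_flagged(self):
        fit = ts.sigmoid_fit(np.linspace(0, 10, 20), np.full(20, 3.0))
        assert not fit.converged

    def test_scale_equivariance(self):
        ages = np.linspace(3, 18, 50)
        y = sg.sigmoid(ages, 0.0, 10.0, 0.9, 11.0)
        f1 = ts.sigmoid_fit(ages, y)
        f2 = ts.sigmoid_fit(3.0 * ages, y)
        assert f2.inflection == pytest.approx(3.0 * f1.inflection, rel=1e-4)
        assert f2.rate == pytest.approx(f1.rate / 3.0, rel=1e-4)

    def test_gaussian_form_available(self):
        ages = np.linspace(3, 18, 40)
        y = sg.sigmoid(ages, 0.0, 30.0, 0.8, 12.04)
        fit = ts.sigmoid_fit(ages, y, form="gaussian")
        assert fit.converged
        assert fit.inflection == pytest.approx(12.04, abs=0.5)


class TestLoess:
    def test_linear_data_reproduced_exactly(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 10, 60))
        y = 2.0 * x + 1.0
        out = ts.loess_trajectory(x, y, span=0.4, n_boot=0)
        np.testing.assert_allclose(out["fit"], 2.0 * out["x"] + 1.0, atol=1e-8)

    def test_span_one_equals_global_linear_fit(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 10, 50))
        y = 2 * x + 1 + rng.normal(0, 1, 50)
        out = ts.loess_trajectory(x, y, span=1.0, n_boot=0)
        coef = np.polyfit(x, y, 1)
        np.testing.assert_allclose(out["fit"], np.polyval(coef, out["x"]), atol=1e-8)

    def test_consistency_on_sine(self):
        """Median RMSE against the true sine decreases as n grows."""
        rmses = {n: [] for n in (50, 500)}
        for n in rmses:
            for seed in range(7):
                rng = np.random.default_rng(seed)
                x = np.sort(rng.uniform(0, 2 * np.pi, n))
                y = np.sin(x) + rng.normal(0, 0.3, n)
                out = ts.loess_trajectory(x, y, span=0.3, n_boot=0)
                rmses[n].append(np.sqrt(np.mean((out["fit"] - np.sin(out["x"])) ** 2)))
        assert np.median(rmses[500]) < np.median(rmses[50])

    def test_bootstrap_band_brackets_fit(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 10, 80))
        y = np.sin(x) + rng.normal(0, 0.2, 80)
        out = ts.loess_trajectory(x, y, span=0.5, n_boot=100, seed=0)
        inner = out.iloc[5:-5]
        assert (inner["lo"] <= inner["fit"] + 1e-9).all()
        assert (inner["hi"] >= inner["fit"] - 1e-9).all()


class TestZScoreAlign:
    def test_identical_curves_overlay(self):
        x = np.linspace(0, 10, 30)
        y = np.sin(x) + 0.1 * x
        out = ts.zscore_align((x, y), (x, y))
        np.testing.assert_allclose(out["z_a"], out["z_b"], atol=1e-12)

    def test_affine_invariance(self):
        x = np.linspace(0, 10, 30)
        y = np.sin(x) + 0.1 * x
        out = ts.zscore_align((x, y), (x, 5.0 * y + 3.0))
        np.testing.assert_allclose(out["z_a"], out["z_b"], atol=1e-9)

    def test_late_rise_curves_align(self):
        """Mouse-like and human-like late-rise trajectories overlay closely."""
        mouse_age = np.linspace(3, 18, 40)
        human_age = np.linspace(45, 85, 40)
        mouse = sg.sigmoid(mouse_age, 1.1, 1.4, 0.9, 14.0)
        human = sg.sigmoid(human_age, 1.2, 1.6, 0.35, 75.0)
        out = ts.zscore_align((mouse_age, mouse), (human_age, human))
        assert np.abs(out["z_a"] - out["z_b"]).max() < 0.5

    def test_degenerate_curve_rejected(self):
        x = np.linspace(0, 10, 20)
        with pytest.raises(DegenerateCurveError):
            ts.zscore_align((x, np.ones(20)), (x, np.sin(x)))


class TestAnovaTukey:
    def test_identical_groups_null(self):
        vals = np.tile(np.arange(10.0), 3)
        tab = pd.DataFrame({"y": vals, "g": np.repeat(["a", "b", "c"], 10)})
        f, p, pair = ts.anova_tukey(tab, "y", "g")
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)
        assert (pair["p-adj"] > 0.999).all()

    def test_two_group_tukey_equals_t_test(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame({
            "y": np.concatenate([rng.normal(0, 1, 15), rng.normal(0.8, 1, 15)]),
            "g": np.repeat(["a", "b"], 15)})
        _, _, pair = ts.anova_tukey(tab, "y", "g")
        t_p = stats.ttest_ind(tab[tab.g == "a"]["y"], tab[tab.g == "b"]["y"]).pvalue
        assert pair["p-adj"].iloc[0] == pytest.approx(t_p, abs=1e-6)

    def test_small_group_dropped_with_warning(self):
        tab = pd.DataFrame({"y": [1.0, 2, 3, 4, 5, 9],
                            "g": ["a", "a", "b", "b", "b", "c"]})
        with pytest.warns(UserWarning):
            f, p, pair = ts.anova_tukey(tab, "y", "g")
        assert set(pair["group1"]) | set(pair["group2"]) == {"a", "b"}

    def test_familywise_error_calibrated_under_null(self):
        """Tukey FWER for 3 null groups stays near the nominal 5%."""
        reps, hits = 400, 0
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            tab = pd.DataFrame({"y": rng.normal(size=30),
                                "g": np.repeat(["a", "b", "c"], 10)})
            _, _, pair = ts.anova_tukey(tab, "y", "g")
            hits += (pair["p-adj"] < 0.05).any()
        assert 0.025 <= hits / reps <= 0.075
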