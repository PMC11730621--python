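"""Correlations, random-intercept models, diagnostics, effect sizes, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import gazesearch as gs
from gazesearch.inference import EYE_TERMS, prepare_analysis_table


def _trials_frame(rng, n_subj=30, n_trial=40, rt_fn=None):
    rows = []
    for p in range(n_subj):
        age = rng.uniform(19, 85)
        for t in range(n_trial):
            sim = t % 2
            m = 5 if t % 4 < 2 else 10
            rows.append({
                "participant": p, "trial_id": f"P{p}T{t}", "similarity": sim,
                "set_size": m, "target_present": False, "correct": True,
                "age": age, "skipping": rng.random(),
                "revisiting": rng.random(), "dwelling_ms": rng.lognormal(5.5, 0.3),
                "rt_ms": rng.lognormal(7.5, 0.4) if rt_fn is None else rt_fn(),
            })
    return pd.DataFrame(rows)


class TestTrialCorrelations:
    def test_symmetric_unit_diagonal(self, rng):
        c = gs.trial_correlations(_trials_frame(rng))
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)

    def test_independent_columns_have_near_zero_correlations(self, rng):
        df = _trials_frame(rng, n_subj=100, n_trial=40)  # 4000 trials
        # make age vary within subject-free: re-draw everything independently
        df["age"] = rng.uniform(19, 85, len(df))
        df["similarity"] = rng.integers(0, 2, len(df))
        df["set_size"] = rng.choice([5, 10], len(df))
        c = gs.trial_correlations(df)
        off = c.to_numpy()[~np.eye(len(c), dtype=bool)]
        assert np.nanmax(np.abs(off)) < 0.05

    def test_point_biserial_equals_group_difference_formula(self, rng):
        df = _trials_frame(rng, n_subj=40)
        r = gs.trial_correlations(df).loc["dwelling", "similarity"]
        x = df["dwelling_ms"]
        g1, g0 = x[df.similarity == 1], x[df.similarity == 0]
        p = (df.similarity == 1).mean()
        want = (g1.mean() - g0.mean()) * np.sqrt(p * (1 - p)) / x.std(ddof=0)
        assert r == pytest.approx(want, abs=1e-10)

    def test_constant_column_reported_missing(self, rng):
        df = _trials_frame(rng)
        df["age"] = 50.0
        c = gs.trial_correlations(df)
        assert c.loc["age"].drop("age").isna().all()


class TestFitRandomIntercept:
    def test_matches_ols_when_between_variance_is_zero(self, rng):
        n_subj, n_trial = 20, 30
        g = np.repeat(np.arange(n_subj), n_trial)
        x1 = rng.normal(size=g.size)
        x2 = rng.integers(0, 2, g.size).astype(float)
        y = 0.4 * x1 - 0.25 * x2 + rng.normal(0, 1, g.size)  # no group effect
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2, "participant": g})
        fit = gs.fit_random_intercept(df, "y", ["x1", "x2"])
        X = np.column_stack([np.ones(g.size), x1, x2])
        b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        for i, t in enumerate(["intercept", "x1", "x2"]):
            assert fit.coefficients[t].b == pytest.approx(b_ols[i], abs=1e-3)
        assert fit.var_random_intercept < 0.01

    def test_recovers_known_age_effect_with_nominal_coverage(self, rng):
        """Simulated beta = 0.36, intercept SD 0.5, residual SD 1, 45 x 40:
        the true value falls inside the 95% CI in the large majority of
        replicates, and the mean estimate is close to truth."""
        n_subj, n_trial, beta = 45, 40, 0.36
        hits, est = 0, []
        for _ in range(60):
            age = rng.normal(size=n_subj)
            g = np.repeat(np.arange(n_subj), n_trial)
            y = beta * age[g] + rng.normal(0, 0.5, n_subj)[g] + rng.normal(0, 1, g.size)
            df = pd.DataFrame({"y": y, "age": age[g], "participant": g})
            fit = gs.fit_random_intercept(df, "y", ["age"])
            c = fit.coefficients["age"]
            est.append(c.b)
            hits += abs(c.b - beta) < 1.96 * c.sd_b
        assert hits / 60 >= 0.85
        assert np.mean(est) == pytest.approx(beta, abs=0.05)

    def test_group_mean_centered_null_has_no_between_variance(self, rng):
        n_subj, n_trial = 30, 20
        g = np.repeat(np.arange(n_subj), n_trial)
        y = rng.normal(0, 1, g.size)
        y -= pd.Series(y).groupby(g).transform("mean").to_numpy()
        df = pd.DataFrame({"y": y, "x": rng.normal(size=g.size), "participant": g})
        fit = gs.fit_random_intercept(df, "y", ["x"])
        assert fit.var_random_intercept < 1e-3

    def test_singular_design_raises_naming_terms(self, rng):
        g = np.repeat(np.arange(10), 10)
        x = rng.normal(size=100)
        df = pd.DataFrame({"y": rng.normal(size=100), "a": x, "b": 2 * x,
                           "participant": g})
        with pytest.raises(ValueError, match="singular design.*"):
            gs.fit_random_intercept(df, "y", ["a", "b"])

    def test_standardized_coefficient_invariant_to_raw_units(self, rng):
        """Doubling a metrical predictor's raw units leaves its standardized
        coefficient unchanged (z-scoring absorbs the scale)."""
        df = _trials_frame(rng)
        a = prepare_analysis_table(df)
        fit1 = gs.fit_random_intercept(a, "rt", ["dwelling", "similarity"])
        df2 = df.assign(dwelling_ms=df["dwelling_ms"] * 2)
        a2 = prepare_analysis_table(df2)
        fit2 = gs.fit_random_intercept(a2, "rt", ["dwelling", "similarity"])
        assert fit1.coefficients["dwelling"].b == pytest.approx(
            fit2.coefficients["dwelling"].b, abs=1e-8)


class TestMarginalR2:
    def test_degenerate_limits(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        assert gs.marginal_r2(pred, 0.0, 0.0) == pytest.approx(1.0)
        assert gs.marginal_r2(np.full(4, 2.0), 0.3, 0.7) == pytest.approx(0.0)

    def test_equals_ols_r2_when_random_variance_zero(self, rng):
        n = 4000
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(0, 1, n)
        g = np.tile(np.arange(40), n // 40)
        df = pd.DataFrame({"y": y, "x": x, "participant": g})
        fit = gs.fit_random_intercept(df, "y", ["x"])
        r2_ols = sps.pearsonr(x, y).statistic ** 2
        assert fit.marginal_r2 == pytest.approx(r2_ols, abs=0.01)


class TestTolerance:
    def test_orthogonal_predictors(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        assert gs.tolerance(X) == pytest.approx({"a": 1.0, "b": 1.0})

    def test_two_correlated_predictors_closed_form(self, rng):
        # construct columns with empirical correlation exactly 0.6
        n = 500
        raw = rng.normal(size=(n, 2))
        raw -= raw.mean(axis=0)  # mean-zero columns -> QR output is mean-zero
        q, _ = np.linalg.qr(raw)
        u, v = q[:, 0], q[:, 1]
        X = pd.DataFrame({"a": u, "b": 0.6 * u + np.sqrt(1 - 0.36) * v})
        tol = gs.tolerance(X)
        assert tol["a"] == pytest.approx(1 - 0.6**2, abs=1e-10)
        assert tol["b"] == pytest.approx(0.64, abs=1e-10)

    def test_exact_collinearity_gives_zero(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        X = pd.DataFrame({"a": x, "b": y, "c": x + y})
        assert gs.tolerance(X)["c"] == pytest.approx(0.0, abs=1e-10)


class TestEffectSizeLabel:
    @pytest.mark.parametrize("b,label", [
        (0.05, "very small"), (-0.27, "small"), (0.36, "medium"),
        (0.8, "large"), (0.10, "small"), (0.30, "medium"), (0.50, "medium"),
        (0.51, "large"), (-0.09999, "very small"),
    ])
    def test_bins(self, b, label):
        assert gs.effect_size_label(b) == label

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            gs.effect_size_label(float("nan"))


class TestCorrelationPower:
    def test_null_power_equals_alpha(self):
        assert gs.correlation_power(0.0, 50) == pytest.approx(0.05, abs=1e-12)
        assert gs.correlation_power(0.0, 50, alpha=0.10) == pytest.approx(0.10)

    def test_monotone_in_n_and_consistent(self):
        ps = [gs.correlation_power(0.3, n) for n in (10, 30, 100, 300, 1000)]
        assert all(a < b for a, b in zip(ps, ps[1:]))
        assert ps[-1] > 0.999

    def test_matches_monte_carlo_rejection_rate(self, rng):
        for r, n in [(0.2, 50), (0.4, 40), (0.3, 100)]:
            rej = 0
            reps = 2000
            cov = np.array([[1, r], [r, 1]])
            for _ in range(reps):
                xy = rng.multivariate_normal([0, 0], cov, size=n)
                rej += sps.pearsonr(xy[:, 0], xy[:, 1]).pvalue < 0.05
            assert gs.correlation_power(r, n) == pytest.approx(rej / reps, abs=0.03)


class TestRunPaperModels:
    def test_constant_age_errors_out_naming_age(self, rng):
        df = _trials_frame(rng)
        df["age"] = 50.0
        with pytest.raises(ValueError, match="age"):
            gs.run_paper_models(df)

    def test_output_shape_on_noise_data(self, rng):
        res = gs.run_paper_models(_trials_frame(rng))
        assert set(res.eye_models) == {"skipping", "dwelling", "revisiting"}
        for fit in res.eye_models.values():
            assert set(fit.coefficients) == {"intercept", *EYE_TERMS}
            for c in fit.coefficients.values():
                assert c.t == pytest.approx(c.b / c.sd_b)
        assert 0.0 <= res.rt_model.marginal_r2 <= 1.0
        assert len(res.path_edges()) == 3 * 5 + 6
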