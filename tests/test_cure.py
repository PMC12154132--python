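"""Mixture cure model: EM mechanics, degenerate equivalences, bootstrap
standard errors and Wald z-values."""

import numpy as np
import pytest

from curemap.cure import (
    MCMStdErrors,
    bootstrap_se,
    incidence_probability,
    load_fit,
    mcm_fit,
    mcm_survival,
    save_fit,
    wald_z,
)
from curemap.survival import StepFunction, cox_fit
from curemap.synthetic import CohortConfig, generate_cohort, make_design


class TestIncidenceProbability:
    @pytest.mark.parametrize(
        "b, z, expected",
        [
            ([0.0], [1.0], 0.5),
            ([np.log(3)], [1.0], 0.75),
            ([30.0], [1.0], 1.0),  # saturates toward 1
        ],
    )
    def test_logistic_values(self, b, z, expected):
        assert incidence_probability(b, z) == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_linear_predictor(self):
        lps = np.linspace(-5, 5, 11)
        vals = [incidence_probability([lp], [1.0]) for lp in lps]
        assert np.all(np.diff(vals) > 0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            incidence_probability([1.0, 2.0], [1.0])


class TestMCMSurvival:
    @pytest.fixture
    def toy_fit(self, fitted_mcm):
        return fitted_mcm

    def test_survival_is_one_at_zero(self, toy_fit, rng):
        x = rng.normal(size=len(toy_fit.beta))
        z = rng.normal(size=len(toy_fit.b))
        assert mcm_survival(toy_fit, x, z, 0.0) == pytest.approx(1.0)

    def test_attains_cure_fraction_beyond_last_event(self, toy_fit, rng):
        x = rng.normal(size=len(toy_fit.beta)) * 0.1
        z = rng.normal(size=len(toy_fit.b)) * 0.1
        pi = incidence_probability(toy_fit.b, z)
        t_big = toy_fit.baseline_survival.knots[-1] + 1.0
        assert mcm_survival(toy_fit, x, z, t_big) == pytest.approx(1 - pi, abs=1e-12)

    def test_toy_step_function_substitution(self, toy_fit):
        from dataclasses import replace

        fit = replace(
            toy_fit,
            b=np.array([50.0]),  # pi ~ 1
            beta=np.array([0.0]),
            baseline_survival=StepFunction(np.array([1.0]), np.array([0.5])),
        )
        assert mcm_survival(fit, [0.0], [1.0], 1.0) == pytest.approx(0.5, abs=1e-9)

    def test_negative_time_rejected(self, toy_fit):
        with pytest.raises(ValueError):
            mcm_survival(toy_fit, np.zeros(len(toy_fit.beta)), np.zeros(len(toy_fit.b)), -1.0)


class TestMCMFit:
    def test_posterior_is_one_for_events(self, small_cohort, fitted_mcm):
        _, df, _, _ = small_cohort
        ev = df["event"].to_numpy() == 1
        assert np.all(fitted_mcm.posterior_uncured[ev] == 1.0)
        assert np.all((fitted_mcm.posterior_uncured >= 0) & (fitted_mcm.posterior_uncured <= 1))

    def test_loglik_trace_nondecreasing(self, fitted_mcm):
        ll = fitted_mcm.loglik_trace
        assert fitted_mcm.monotone
        assert np.all(np.diff(ll) >= -1e-8 * (1 + np.abs(ll[:-1])))

    def test_baseline_zero_tail(self, fitted_mcm):
        base = fitted_mcm.baseline_survival
        assert base.values[-1] == 0.0
        assert np.all(np.diff(base.values) <= 1e-12)
        assert np.all((base.values >= 0) & (base.values <= 1))

    def test_forced_uncured_equals_plain_cox(self, small_cohort, small_designs):
        _, df, _, _ = small_cohort
        X, _, Z, _ = small_designs
        t, e = df["time"].to_numpy(), df["event"].to_numpy()
        mcm = mcm_fit(X, Z, t, e, force_uncured=True)
        cox = cox_fit(X, t, e)
        np.testing.assert_allclose(mcm.beta, cox.beta, atol=1e-3)

    def test_nearly_uncured_truth_close_to_cox(self):
        coefs = dict.fromkeys(
            ["intercept", "transplant_transplant", "race_Black", "race_Other",
             "hispanic_yes", "primary_disease_hypertension",
             "primary_disease_gn_ckd", "comorbidity_index"], 0.0)
        coefs["intercept"] = 30.0
        cfg = CohortConfig(n_subjects=3000, incidence_coefs=coefs, seed=21)
        df, _, _ = generate_cohort(cfg)
        X, _ = make_design(df, cfg.covariate_schema)
        Z, _ = make_design(df, cfg.covariate_schema, intercept=True)
        t, e = df["time"].to_numpy(), df["event"].to_numpy()
        mcm = mcm_fit(X, Z, t, e)
        cox = cox_fit(X, t, e)
        # admin-censored survivors get weight 0 under the zero tail, so the
        # agreement is close but not exact
        np.testing.assert_allclose(mcm.beta, cox.beta, atol=0.05)

    def test_rejects_degenerate_inputs(self, small_cohort, small_designs):
        _, df, _, _ = small_cohort
        X, _, Z, _ = small_designs
        t = df["time"].to_numpy()
        with pytest.raises(ValueError):
            mcm_fit(X, Z, t, np.zeros(len(t)))  # no events
        with pytest.raises(ValueError):
            mcm_fit(np.ones_like(X), Z, t, df["event"].to_numpy())  # constant column
        with pytest.raises(ValueError):
            mcm_fit(X, X, t, df["event"].to_numpy())  # no intercept in z


class TestBootstrap:
    def test_same_seed_reproducible(self, small_cohort, small_designs):
        _, df, _, _ = small_cohort
        X, _, Z, _ = small_designs
        t, e = df["time"].to_numpy(), df["event"].to_numpy()
        kw = dict(n_bootstrap=5, seed=42, fit_options={"coef_tol": 1e-4})
        s1 = bootstrap_se(X, Z, t, e, **kw)
        s2 = bootstrap_se(X, Z, t, e, **kw)
        np.testing.assert_array_equal(s1.se_b, s2.se_b)
        np.testing.assert_array_equal(s1.se_beta, s2.se_beta)
        assert np.all(s1.se_b > 0) and np.all(s1.se_beta > 0)

    def test_too_few_resamples_rejected(self, small_cohort, small_designs):
        _, df, _, _ = small_cohort
        X, _, Z, _ = small_designs
        with pytest.raises(ValueError):
            bootstrap_se(X, Z, df["time"].to_numpy(), df["event"].to_numpy(), n_bootstrap=1)

    def test_se_shrinks_with_sample_size(self):
        ses = {}
        for n in (1000, 4000):
            cfg = CohortConfig(n_subjects=n, seed=17)
            df, _, _ = generate_cohort(cfg)
            X, _ = make_design(df, cfg.covariate_schema)
            Z, _ = make_design(df, cfg.covariate_schema, intercept=True)
            ses[n] = bootstrap_se(
                X, Z, df["time"].to_numpy(), df["event"].to_numpy(),
                n_bootstrap=15, seed=1, fit_options={"coef_tol": 1e-4},
            )
        # expect roughly sqrt(4) = 2x shrinkage; allow a factor-1.5 band
        ratio = np.median(ses[1000].se_beta / ses[4000].se_beta)
        assert 2 / 1.5 < ratio < 2 * 1.5


class TestWaldZ:
    def test_ratio_values(self, fitted_mcm):
        p, q = len(fitted_mcm.b), len(fitted_mcm.beta)
        ses = MCMStdErrors(np.full(p, 0.002), np.full(q, 0.5), 10, 0, 0)
        from dataclasses import replace

        fit = replace(fitted_mcm, b=np.full(p, 0.340), beta=np.full(q, 1.0))
        z_b, z_beta = wald_z(fit, ses)
        np.testing.assert_allclose(z_b, 170.0)
        np.testing.assert_allclose(z_beta, 2.0)

    def test_zero_estimate_and_zero_se(self, fitted_mcm):
        p, q = len(fitted_mcm.b), len(fitted_mcm.beta)
        from dataclasses import replace

        fit = replace(fitted_mcm, b=np.zeros(p))
        ses = MCMStdErrors(np.full(p, 1.0), np.r_[0.0, np.ones(q - 1)], 10, 0, 0)
        with pytest.warns(UserWarning):
            z_b, z_beta = wald_z(fit, ses)
        assert np.all(z_b == 0.0)
        assert np.isnan(z_beta[0])


def test_fit_serialization_roundtrip(fitted_mcm, tmp_path):
    path = tmp_path / "fit.txt"
    save_fit(fitted_mcm, path)
    back = load_fit(path)
    np.testing.assert_allclose(back.b, fitted_mcm.b)
    np.testing.assert_allclose(back.beta, fitted_mcm.beta)
    np.testing.assert_allclose(back.baseline_survival.values, fitted_mcm.baseline_survival.values)
    np.testing.assert_allclose(back.baseline_survival.knots, fitted_mcm.baseline_survival.knots)
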