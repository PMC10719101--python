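"""Mixed-effects meta-regression: oracles, trimming, heterogeneity, selection."""

import itertools
import math

import numpy as np
import pytest

from burdenproof import (
    CovariateSpec,
    FitError,
    MetaRegression,
    SyntheticTruth,
    ValidationError,
    select_bias_covariates,
    simulate_dataset,
    simulate_null_ensemble,
)


def ivw_mean(y, se):
    w = 1.0 / np.asarray(se) ** 2
    return float((w * np.asarray(y)).sum() / w.sum())


class TestFixedEffectOracle:
    def test_two_equal_se_observations_give_arithmetic_mean(self, dataset_factory):
        ds = dataset_factory([0.2, 0.8], [0.1, 0.1], study_ids=["a", "b"])
        res = MetaRegression(ds, min_studies=1).fit(trim=0.0, fix_gamma=0.0)
        assert res.beta0 == pytest.approx(0.5, abs=1e-10)

    def test_matches_closed_form_ivw_mean(self, rng, dataset_factory):
        y = rng.normal(0.4, 0.3, size=12)
        se = rng.uniform(0.05, 0.5, size=12)
        ds = dataset_factory(list(y), list(se))
        res = MetaRegression(ds).fit(trim=0.0, fix_gamma=0.0)
        assert res.beta0 == pytest.approx(ivw_mean(y, se), abs=1e-8)
        # GLS variance of the mean equals 1/sum(w)
        assert res.var_beta0 == pytest.approx(1.0 / (1.0 / se**2).sum(), rel=1e-8)

    def test_free_gamma_shrinks_to_zero_when_data_homogeneous(self, dataset_factory):
        ds = dataset_factory([0.5, 0.5, 0.5, 0.5], [0.1, 0.2, 0.1, 0.3])
        res = MetaRegression(ds).fit(trim=0.0)
        assert res.gamma == 0.0
        assert res.beta0 == pytest.approx(0.5, abs=1e-9)


class TestGammaEstimation:
    def test_parameter_recovery_single_seed(self):
        t = SyntheticTruth(beta0=math.log(2), gamma=0.04, n_studies=50,
                           obs_per_study=1, seed=7)
        ds, _ = simulate_dataset(t)
        res = MetaRegression(ds).fit(trim=0.0)
        lo, hi = res.fixed_effect_ci()
        assert lo < math.log(2) < hi
        assert 0.005 < res.gamma < 0.1

    def test_sd_gamma_closed_form_equal_information_studies(self, dataset_factory):
        # m studies, one observation each, common sigma: marginal variance
        # v = sigma^2 + gamma and sd(gamma-hat) = v * sqrt(2/m)
        m, sigma, gamma = 25, 0.2, 0.05
        ds = dataset_factory([0.0] * m, [sigma] * m)
        res = MetaRegression(ds).fit(trim=0.0, fix_gamma=gamma)
        v = sigma**2 + gamma
        assert res.sd_gamma == pytest.approx(v * math.sqrt(2.0 / m), rel=1e-10)

    def test_sd_gamma_shrinks_with_more_studies(self):
        sds = []
        for m in (10, 40):
            vals = []
            for s in range(20):
                t = SyntheticTruth(beta0=0.3, gamma=0.04, n_studies=m,
                                   obs_per_study=1, seed=100 + s)
                ds, _ = simulate_dataset(t)
                vals.append(MetaRegression(ds).fit(trim=0.0).sd_gamma)
            sds.append(np.mean(vals))
        assert sds[1] < sds[0]

    def test_gamma_invariant_to_order_and_shift(self):
        t = SyntheticTruth(beta0=0.5, gamma=0.06, n_studies=15, obs_per_study=(1, 3),
                           seed=21)
        ds, _ = simulate_dataset(t)
        res = MetaRegression(ds).fit(trim=0.0)

        perm = np.random.default_rng(1).permutation(ds.n_obs)
        ds_perm = ds.subset(np.ones(ds.n_obs, bool))  # copy
        ds_perm = type(ds)(ds.risk_name, ds.outcome_name,
                           tuple(ds.observations[i] for i in perm), ds.covariate_specs)
        res_perm = MetaRegression(ds_perm).fit(trim=0.0)
        assert res_perm.gamma == pytest.approx(res.gamma, abs=1e-7)
        assert res_perm.beta0 == pytest.approx(res.beta0, abs=1e-7)

        import dataclasses
        shifted = type(ds)(ds.risk_name, ds.outcome_name,
                           tuple(dataclasses.replace(o, log_rr=o.log_rr + 1.0) for o in ds),
                           ds.covariate_specs)
        res_shift = MetaRegression(shifted).fit(trim=0.0)
        assert res_shift.beta0 == pytest.approx(res.beta0 + 1.0, abs=1e-6)
        assert res_shift.gamma == pytest.approx(res.gamma, abs=1e-7)


class TestTrimming:
    def _outlier_dataset(self, seed):
        t = SyntheticTruth(beta0=math.log(2), gamma=0.0, n_studies=10, obs_per_study=1,
                           outlier_fraction=0.1, outlier_shift=3.0, seed=seed)
        return simulate_dataset(t)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_outlier_removed_and_matches_exhaustive_search(self, seed):
        ds, truth = self._outlier_dataset(seed)
        res = MetaRegression(ds).fit(trim=0.1)
        trimmed = np.flatnonzero(~res.trim_mask)
        assert trimmed.tolist() == list(truth.outlier_indices)
        # independent oracle: best leave-one-out subset by refitted likelihood
        lls = []
        for i in range(ds.n_obs):
            keep = np.ones(ds.n_obs, bool)
            keep[i] = False
            lls.append(MetaRegression(ds.subset(keep)).fit(trim=0.0).loglik)
        assert int(np.argmax(lls)) == trimmed[0]

    def test_trim_count_and_activation_threshold(self, dataset_factory):
        # 9 observations: below the >=10 threshold, no trimming even if asked
        ds9 = dataset_factory(list(np.linspace(0, 1, 9)), [0.1] * 9)
        res9 = MetaRegression(ds9).fit(trim=0.1)
        assert res9.n_obs_retained == 9
        # 14 observations: retained = ceil(0.9 * 14) = 13
        ds14 = dataset_factory(list(np.linspace(0, 1, 14)), [0.1] * 14)
        res14 = MetaRegression(ds14).fit(trim=0.1)
        assert res14.n_obs_retained == 13

    def test_trimmed_subset_beats_random_subsets(self):
        t = SyntheticTruth(beta0=0.2, gamma=0.01, n_studies=12, obs_per_study=1,
                           outlier_fraction=0.1, outlier_shift=2.5, seed=5)
        ds, _ = simulate_dataset(t)
        res = MetaRegression(ds).fit(trim=0.1)
        k = res.n_obs_retained
        rng = np.random.default_rng(0)
        for _ in range(200):
            idx = rng.choice(ds.n_obs, size=k, replace=False)
            keep = np.zeros(ds.n_obs, bool)
            keep[idx] = True
            ll = MetaRegression(ds.subset(keep)).fit(trim=0.0).loglik
            assert res.loglik >= ll - 1e-8


class TestCovariateAdjustment:
    def test_reference_prediction_recovers_gold_standard_mean(self, dataset_factory):
        # covariate = 1 rows shifted +0.3; reference rows centred at log 2
        rng = np.random.default_rng(3)
        n = 40
        x = np.array([0, 1] * (n // 2))
        y = math.log(2) + 0.3 * x + rng.normal(0, 0.1, n)
        ds = dataset_factory(list(y), [0.1] * n, covariates=[{"bias": int(v)} for v in x])
        res = MetaRegression(ds, covariates=["bias"]).fit(trim=0.0)
        log_ref, var_ref = res.predict_reference()
        assert log_ref == pytest.approx(math.log(2), abs=3 * math.sqrt(var_ref))
        assert abs(log_ref - float(np.mean(y))) > 0.05  # not the raw pooled mean
        assert res.beta_cov["bias"] == pytest.approx(0.3, abs=0.1)

    def test_no_covariates_identity(self, dataset_factory):
        ds = dataset_factory([0.1, 0.4, 0.3], [0.1, 0.2, 0.15])
        res = MetaRegression(ds).fit(trim=0.0)
        assert res.predict_reference() == (res.beta0, res.var_beta0)

    def test_collinear_covariates_raise(self, dataset_factory):
        covs = [{"a": v, "b": v} for v in (0, 0, 1, 1, 1, 0)]
        ds = dataset_factory([0.1] * 6, [0.1] * 6, covariates=covs)
        with pytest.raises(FitError, match="singular"):
            MetaRegression(ds, covariates=["a", "b"]).fit(trim=0.0)

    def test_unknown_covariate_rejected(self, dataset_factory):
        ds = dataset_factory([0.1, 0.2, 0.3], [0.1] * 3)
        with pytest.raises(ValidationError, match="unknown covariate"):
            MetaRegression(ds, covariates=["ghost"])

    def test_two_study_dataset_refused(self, dataset_factory):
        ds = dataset_factory([0.1, 0.2, 0.3], [0.1] * 3, study_ids=["a", "a", "b"])
        with pytest.raises(ValidationError, match="at least 3"):
            MetaRegression(ds)


class TestCovariateSelection:
    def test_strong_covariate_selected(self):
        t = SyntheticTruth(beta0=0.2, beta_cov={"biased_design": 0.5}, gamma=0.0,
                           se_range=(0.08, 0.12), n_studies=30, obs_per_study=1, seed=13)
        ds, _ = simulate_dataset(t)
        selected = select_bias_covariates(ds, ["biased_design"])
        assert selected == ["biased_design"]

    def test_null_covariate_selection_rate_bounded(self):
        # pure-noise covariate should rarely survive the Lasso + Wald gate
        tmpl = SyntheticTruth(beta0=0.0, beta_cov={"noise": 0.0}, gamma=0.01,
                              n_studies=15, obs_per_study=1, seed=77)
        hits = 0
        n_rep = 200
        for ds in simulate_null_ensemble(tmpl, n_rep):
            hits += bool(select_bias_covariates(ds, ["noise"]))
        assert hits / n_rep <= 0.10

    def test_empty_candidates(self, dataset_factory):
        ds = dataset_factory([0.1, 0.2, 0.3], [0.1] * 3)
        assert select_bias_covariates(ds, []) == []

    def test_untestable_candidate_rejected(self, dataset_factory):
        ds = dataset_factory([0.1, 0.2, 0.3], [0.1] * 3,
                             covariates=[{"x": 0}, {"x": 0}, {"x": 1}])
        with pytest.raises(ValidationError, match="not testable"):
            select_bias_covariates(ds, [CovariateSpec("x", testable=False)])

    def test_selection_is_deterministic(self):
        t = SyntheticTruth(beta0=0.1, beta_cov={"a": 0.4, "b": 0.0}, gamma=0.01,
                           n_studies=25, obs_per_study=1, seed=8)
        ds, _ = simulate_dataset(t)
        first = select_bias_covariates(ds, ["a", "b"])
        assert all(select_bias_covariates(ds, ["a", "b"]) == first for _ in range(3))
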