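import numpy as np
import pytest

import locmix as lm
from locmix.bias import BiasSpec
from locmix.model import condition_compare, crossval_response_sampling

FAST = dict(n_polish=3)


class TestMLERecovery:
    def test_central_cell_median_recovery_error_near_zero(self):
        rng = np.random.default_rng(21)
        errs = []
        for _ in range(20):
            ds = lm.simulate_dataset(lm.TaskDesign(), 0.3, 0.3, 30.0, rng)
            res = lm.SpatialMixtureModel(ds).fit()
            p = res.params
            errs.append([p["beta"] - 0.3, p["gamma"] - 0.3, p["sigma"] - 30.0])
        med = np.median(errs, axis=0)
        assert abs(med[0]) < 0.07 and abs(med[1]) < 0.07 and abs(med[2]) < 4.0

    def test_pure_guess_data_recovers_high_gamma(self):
        design = lm.TaskDesign(n_trials=500)
        ds = lm.simulate_dataset(design, 0.0, 1.0, 30.0, np.random.default_rng(22))
        res = lm.SpatialMixtureModel(ds).fit()
        assert res.params["gamma"] > 0.9

    def test_mle_beats_truth_on_loglik(self, central_dataset):
        model = lm.SpatialMixtureModel(central_dataset)
        res = model.fit()
        assert res.llf >= model.loglike(np.array([0.3, 0.3, 30.0]))

    def test_fit_requires_enough_trials(self, screen):
        ds = lm.simulate_dataset(lm.TaskDesign(n_trials=3), 0.2, 0.2, 30.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            lm.SpatialMixtureModel(ds).fit()

    def test_results_object_carries_bic_and_summary(self, central_dataset):
        res = lm.SpatialMixtureModel(central_dataset).fit()
        assert res.bic == pytest.approx(3 * np.log(res.nobs) - 2 * res.llf)
        text = res.summary()
        assert "BIC" in text and "sigma" in text
        assert 0 <= res.alpha <= 1

    def test_standard_model_has_two_parameters(self, central_dataset):
        res = lm.SpatialMixtureModel(central_dataset, misbinding=False).fit()
        assert list(res.params.index) == ["gamma", "sigma"]
        assert res.k_params == 2


class TestModelSelection:
    def test_bic_selects_generating_model(self):
        # misbinding (beta=.3) vs no-misbinding data, n=100: BIC picks the
        # generator in >= 80% of replicates
        rng = np.random.default_rng(23)
        design = lm.TaskDesign()
        correct = 0
        n_rep = 30
        for i in range(n_rep):
            beta = 0.3 if i % 2 == 0 else 0.0
            ds = lm.simulate_dataset(design, beta, 0.2, 30.0, rng)
            b_misbind = lm.SpatialMixtureModel(ds).fit(**FAST).bic
            b_standard = lm.SpatialMixtureModel(ds, misbinding=False).fit(**FAST).bic
            picked_misbind = b_misbind < b_standard
            correct += picked_misbind == (beta > 0)
        assert correct / n_rep >= 0.8


class TestBiasCorrectedFits:
    def test_unbiased_data_recovers_zero_bias(self):
        ds = lm.simulate_dataset(lm.TaskDesign(n_trials=200), 0.2, 0.2, 30.0, np.random.default_rng(24))
        plain = lm.SpatialMixtureModel(ds).fit()
        corrected = lm.SpatialMixtureModel(ds, bias="constant").fit(**FAST)
        assert abs(corrected.params["bias_x"]) < 15
        assert abs(corrected.params["bias_y"]) < 15
        assert corrected.params["sigma"] == pytest.approx(plain.params["sigma"], rel=0.15)

    def test_constant_bias_recovered_and_improves_fit(self):
        rng = np.random.default_rng(25)
        spec = BiasSpec(kind="constant")
        errs_plain, errs_corr, bx = [], [], []
        for _ in range(6):
            ds = lm.simulate_dataset(lm.TaskDesign(), 0.2, 0.2, 30.0, rng,
                                     bias_spec=spec, bias_values=[100.0, 0.0])
            plain = lm.SpatialMixtureModel(ds).fit(**FAST)
            corr = lm.SpatialMixtureModel(ds, bias="constant").fit(**FAST)
            errs_plain.append(abs(plain.params["sigma"] - 30.0))
            errs_corr.append(abs(corr.params["sigma"] - 30.0))
            bx.append(corr.params["bias_x"])
        assert np.mean(bx) == pytest.approx(100.0, abs=25.0)
        assert np.mean(errs_corr) < np.mean(errs_plain)

    def test_radial_bias_correction_improves_sigma_recovery(self):
        rng = np.random.default_rng(26)
        spec = BiasSpec(kind="radial", center="screen_center")
        errs_plain, errs_corr = [], []
        for _ in range(6):
            ds = lm.simulate_dataset(lm.TaskDesign(), 0.2, 0.2, 30.0, rng,
                                     bias_spec=spec, bias_values=[0.3])
            plain = lm.SpatialMixtureModel(ds).fit(**FAST)
            corr = lm.SpatialMixtureModel(ds, bias=spec).fit(**FAST)
            errs_plain.append(abs(plain.params["sigma"] - 30.0))
            errs_corr.append(abs(corr.params["sigma"] - 30.0))
        assert np.mean(errs_corr) < np.mean(errs_plain)


class TestTwoClassModel:
    def test_two_class_fit_recovers_asymmetric_swap_rates(self):
        design = lm.ignore_update_design(n_trials=400)
        ds = lm.simulate_dataset(design, 0.0, 0.1, 20.0, np.random.default_rng(27),
                                 beta_by_class={1: 0.3, 2: 0.05})
        res = lm.SpatialMixtureModel(ds, two_class=True).fit(**FAST)
        assert res.params["beta1"] > res.params["beta2"]
        assert res.params["beta1"] == pytest.approx(0.3, abs=0.12)


class TestConditionCompare:
    def test_identical_fits_give_p_near_one(self, central_dataset):
        res = lm.SpatialMixtureModel(central_dataset).fit()
        stat, p, df = condition_compare(res, res)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)
        assert df == 3

    def test_power_for_separated_conditions(self):
        rng = np.random.default_rng(28)
        design = lm.TaskDesign()
        rejections = 0
        n_rep = 15
        for _ in range(n_rep):
            ds_a = lm.simulate_dataset(design, 0.1, 0.1, 20.0, rng)
            ds_b = lm.simulate_dataset(design, 0.4, 0.4, 60.0, rng)
            fa = lm.SpatialMixtureModel(ds_a).fit(**FAST)
            fb = lm.SpatialMixtureModel(ds_b).fit(**FAST)
            _, p, _ = condition_compare(fa, fb, ridge=1e-8)
            rejections += p <= 0.05
        assert rejections / n_rep > 0.5  # far above the 5% false-positive rate

    def test_type_i_rate_calibrated(self):
        rng = np.random.default_rng(29)
        design = lm.TaskDesign()
        rejections = 0
        n_rep = 25
        for _ in range(n_rep):
            ds_a = lm.simulate_dataset(design, 0.3, 0.3, 30.0, rng)
            ds_b = lm.simulate_dataset(design, 0.3, 0.3, 30.0, rng)
            fa = lm.SpatialMixtureModel(ds_a).fit(**FAST)
            fb = lm.SpatialMixtureModel(ds_b).fit(**FAST)
            _, p, _ = condition_compare(fa, fb, ridge=1e-8)
            rejections += p <= 0.05
        assert rejections / n_rep <= 0.25


class TestCrossValidation:
    def test_structured_guesses_favor_kde_model(self):
        # guesses drawn from a right-biased blob: response sampling should
        # predict held-out trials at least as well as the uniform model
        rng = np.random.default_rng(30)
        scr = lm.DEFAULT_SCREEN

        def right_blob(n, r):
            return scr.clip(r.normal([1100, 400], [120, 120], size=(n, 2)))

        ds = lm.simulate_dataset(lm.TaskDesign(n_trials=150), 0.1, 0.5, 25.0, rng,
                                 guess_sampler=right_blob)
        cv = crossval_response_sampling(ds, reps=20, seed=1, fit_kw=FAST)
        assert cv["kde"].mean() > cv["uniform"].mean()

    def test_uniform_guesses_show_no_kde_inflation(self):
        ds = lm.simulate_dataset(lm.TaskDesign(n_trials=150), 0.1, 0.5, 25.0,
                                 np.random.default_rng(31))
        cv = crossval_response_sampling(ds, reps=20, seed=2, fit_kw=FAST)
        # held-out likelihoods agree within a small tolerance: no overfitting
        assert cv["kde"].mean() == pytest.approx(cv["uniform"].mean(), rel=0.15)

    def test_seeded_splits_reproducible(self, central_dataset):
        a = crossval_response_sampling(central_dataset, reps=3, seed=5, fit_kw=FAST)
        b = crossval_response_sampling(central_dataset, reps=3, seed=5, fit_kw=FAST)
        assert a.equals(b)


class TestCovariance:
    def test_hessian_covariance_positive_variances(self, central_dataset):
        res = lm.SpatialMixtureModel(central_dataset).fit()
        cov = res.cov_params()
        assert (np.diag(cov) > 0).all()
        assert res.bse["sigma"] < 10.0  # sigma well identified at n=100
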