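import numpy as np
import pytest

import locmix as lm
from locmix.data import TrialDataset

SCREEN = lm.DEFAULT_SCREEN


def _dataset(resp, targ, nts):
    return TrialDataset(np.asarray(resp, float), np.asarray(targ, float),
                        np.asarray(nts, float), SCREEN)


class TestDistances:
    def test_three_four_five_triangle(self):
        ds = _dataset([[103, 104]], [[100, 100]], np.empty((1, 0, 2)))
        assert lm.target_distance(ds)[0] == pytest.approx(5.0)

    def test_response_on_target_is_zero(self):
        ds = _dataset([[55, 66]], [[55, 66]], np.empty((1, 0, 2)))
        assert lm.target_distance(ds)[0] == 0.0

    def test_matches_independent_oracle(self, rng):
        resp = SCREEN.sample_uniform(100, rng)
        targ = SCREEN.sample_uniform(100, rng)
        ds = _dataset(resp, targ, np.empty((100, 0, 2)))
        expected = [np.hypot(*(r - t)) for r, t in zip(resp, targ)]
        np.testing.assert_allclose(lm.target_distance(ds), expected)

    def test_nearest_neighbor_zero_on_nontarget(self):
        ds = _dataset([[200, 200]], [[600, 600]], [[[200, 200], [900, 100]]])
        assert lm.nearest_neighbor_distance(ds)[0] == 0.0

    def test_nearest_neighbor_reduces_to_target_distance_single_item(self):
        ds = _dataset([[300, 300]], [[350, 300]], np.empty((1, 0, 2)))
        assert lm.nearest_neighbor_distance(ds)[0] == lm.target_distance(ds)[0]

    def test_nearest_neighbor_never_exceeds_target_distance(self, rng):
        ds = lm.simulate_dataset(lm.TaskDesign(n_trials=500), 0.3, 0.3, 40.0, rng)
        assert (lm.nearest_neighbor_distance(ds) <= lm.target_distance(ds) + 1e-12).all()


class TestSwapErrors:
    def test_response_on_nontarget_counts(self):
        ds = _dataset([[200, 200]], [[600, 600]], [[[200, 200]]])
        assert lm.swap_errors(ds, threshold=5.0, chance_corrected=False) == 1.0

    def test_distant_nontargets_make_correction_zero(self):
        # nontarget farther than target distance + threshold: no candidate
        # location on the circle can be a swap, so corrected == uncorrected
        ds = _dataset([[510, 400]], [[500, 400]], [[[900, 700]]])
        raw = lm.swap_errors(ds, threshold=20.0, chance_corrected=False)
        corr = lm.swap_errors(ds, threshold=20.0, chance_corrected=True)
        assert raw == corr == 0.0

    def test_corrected_never_exceeds_uncorrected(self, rng):
        ds = lm.simulate_dataset(lm.TaskDesign(n_trials=300), 0.3, 0.3, 40.0, rng)
        raw = lm.swap_errors(ds, chance_corrected=False)
        corr = lm.swap_errors(ds, chance_corrected=True)
        assert corr <= raw

    def test_no_nontargets_flagged_missing(self):
        ds = _dataset([[100, 100]], [[120, 100]], np.empty((1, 0, 2)))
        with pytest.warns(UserWarning):
            out = lm.swap_errors(ds)
        assert np.isnan(out)

    def test_correction_matches_monte_carlo_oracle(self, rng):
        # oracle: uniform random angles on the circle of radius = target
        # distance, clipped to the screen
        from locmix.metrics import _chance_swap_fraction

        ds = lm.simulate_dataset(lm.TaskDesign(n_trials=30), 0.2, 0.4, 60.0,
                                 np.random.default_rng(8))
        thr = 44.0
        det = _chance_swap_fraction(ds, thr)
        r = lm.target_distance(ds)
        n_mc = 40_000
        for i in range(0, 30, 7):
            ang = rng.uniform(0, 2 * np.pi, n_mc)
            pts = ds.targets[i] + r[i] * np.column_stack([np.cos(ang), np.sin(ang)])
            ok = SCREEN.contains(pts)
            dnt = np.linalg.norm(pts[:, None, :] - ds.nontargets[i][None], axis=2).min(axis=1)
            mc = (dnt[ok] < thr).mean() if ok.any() else 0.0
            assert det[i] == pytest.approx(mc, abs=1e-2)

    def test_mean_threshold_variant(self):
        # all responses on target: threshold 0 and no swaps
        ds = _dataset([[100, 100], [300, 300]], [[100, 100], [300, 300]],
                      [[[500, 500]], [[600, 600]]])
        assert lm.swap_errors_mean_threshold(ds) == 0.0

    def test_mean_threshold_matches_fixed_when_equal(self, rng):
        ds = lm.simulate_dataset(lm.TaskDesign(n_trials=200), 0.3, 0.3, 40.0, rng)
        thr = float(lm.target_distance(ds).mean())
        assert lm.swap_errors_mean_threshold(ds) == lm.swap_errors(ds, threshold=thr)

    def test_scale_invariance_of_proportion(self):
        resp = np.array([[100.0, 100.0], [400.0, 250.0]])
        targ = np.array([[150.0, 100.0], [380.0, 250.0]])
        nts = np.array([[[110.0, 100.0]], [[600.0, 300.0]]])
        small = TrialDataset(resp, targ, nts, lm.ScreenGeometry(683, 384))
        big = TrialDataset(2 * resp, 2 * targ, 2 * nts, lm.ScreenGeometry(1366, 768))
        assert lm.swap_errors_mean_threshold(small) == pytest.approx(
            lm.swap_errors_mean_threshold(big)
        )


class TestSplitHalf:
    def _participants(self, seed, n_people=12, spread=True):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_people):
            if spread:
                beta = rng.uniform(0.05, 0.4)
                gamma = rng.uniform(0.05, 0.4)
                sigma = rng.uniform(10, 60)
            else:
                beta, gamma, sigma = 0.2, 0.2, 30.0
            out.append(lm.simulate_dataset(lm.TaskDesign(), beta, gamma, sigma, rng))
        return out

    def test_identical_measure_gives_unity(self):
        people = self._participants(1, n_people=5)
        fixed = {id(p): i * 1.7 for i, p in enumerate(people)}
        # measure depends only on which participant the half came from
        counter = {"i": 0}

        def measure(ds):
            idx = counter["i"] // 2 % 5
            counter["i"] += 1
            return float(idx)

        rho = lm.split_half_reliability(people, measure, n_iterations=4)
        assert rho == pytest.approx(1.0)

    def test_pure_noise_measure_near_zero(self):
        people = self._participants(2, n_people=10)
        noise_rng = np.random.default_rng(99)
        rho = lm.split_half_reliability(
            people, lambda ds: float(noise_rng.random()), n_iterations=50
        )
        assert abs(rho) < 0.2

    def test_target_distance_more_reliable_than_swaps(self):
        # heterogeneous simulated participants: overall error level is a far
        # stabler individual trait than the rare-event swap proportion
        people = self._participants(3, n_people=12)
        rho_td = lm.split_half_reliability(
            people, lambda ds: float(lm.target_distance(ds).mean()), n_iterations=20, seed=4
        )
        rho_swap = lm.split_half_reliability(
            people, lambda ds: lm.swap_errors(ds), n_iterations=20, seed=4
        )
        assert rho_td > rho_swap

    def test_preconditions(self):
        people = self._participants(4, n_people=1)
        with pytest.raises(ValueError):
            lm.split_half_reliability(people, lambda ds: 1.0)


def test_metric_sweep_reproduces_expected_signs():
    # reduced sweep: target distance falls with alpha, NN distance rises
    # with gamma, their difference rises with beta, corrected swaps fall
    # with sigma
    cells = lm.sweep_grid(n_values=5)
    design = lm.TaskDesign(**lm.PAPER_CONSTRAINTS)
    runs = lm.recovery.metric_sweep(cells, design, iterations=2, seed=17)
    rho = lm.metric_parameter_correlations(runs)
    assert rho["target_dist~alpha"] < -0.8
    assert rho["nn_dist~gamma"] > 0.8
    assert rho["target_minus_nn~beta"] > 0.7
    assert rho["swaps_corrected~sigma"] < -0.3
    assert rho["nn_dist~sigma"] > 0.1
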