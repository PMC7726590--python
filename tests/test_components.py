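import math

import numpy as np
import pytest
from scipy.integrate import quad, simpson
from scipy.special import i0

import locmix as lm
from locmix.components import UNIFORM_CIRCULAR_SD

A = 1366 * 768
TWO_PI = 2 * math.pi


class TestDensity2D:
    def test_pure_guessing_is_uniform_over_screen(self, screen, rng):
        pts = screen.sample_uniform(50, rng)
        dens = lm.mixture_density_2d(pts, pts[::-1], np.empty((50, 0, 2)), 0.0, 1.0, 10.0, screen)
        np.testing.assert_allclose(dens, 1.0 / A)

    def test_gaussian_mode_value(self, screen):
        # alpha=1, sigma=30, response on target: 1 / (2 pi sigma^2)
        d = lm.mixture_density_2d([[683, 384]], [[683, 384]], np.empty((1, 0, 2)), 0.0, 0.0, 30.0, screen)
        assert d[0] == pytest.approx(1.0 / (TWO_PI * 900), rel=1e-12)

    def test_half_target_half_guess_sum(self, screen):
        # derived by summing the two closed forms by hand
        expected = 0.5 / (TWO_PI * 900) + 0.5 / A
        d = lm.mixture_density_2d([[683, 384]], [[683, 384]], np.empty((1, 0, 2)), 0.0, 0.5, 30.0, screen)
        assert d[0] == pytest.approx(expected, rel=1e-12)

    def test_misbinding_averages_over_nontargets(self, screen):
        resp = np.array([[400.0, 300.0]])
        targ = np.array([[100.0, 100.0]])
        nts = np.array([[[400.0, 300.0], [700.0, 200.0]]])
        d = lm.mixture_density_2d(resp, targ, nts, 1.0, 0.0, 20.0, screen)
        g = lambda sq: math.exp(-sq / (2 * 400)) / (TWO_PI * 400)
        expected = 0.5 * (g(0.0) + g(300.0**2 + 100.0**2))
        assert d[0] == pytest.approx(expected, rel=1e-12)

    def test_no_nontargets_with_beta_warns_and_drops_term(self, screen):
        with pytest.warns(UserWarning):
            d = lm.mixture_density_2d([[10, 10]], [[10, 10]], np.empty((1, 0, 2)), 0.3, 0.2, 30.0, screen)
        expected = 0.5 / (TWO_PI * 900) + 0.2 / A
        assert d[0] == pytest.approx(expected, rel=1e-12)

    def test_non_finite_inputs_rejected(self, screen):
        with pytest.raises(ValueError):
            lm.mixture_density_2d([[np.nan, 0]], [[1, 1]], np.empty((1, 0, 2)), 0, 0.5, 10, screen)
        with pytest.raises(ValueError):
            lm.mixture_density_2d([[1, 1]], [[1, 1]], np.empty((1, 0, 2)), 0, 0.5, -3.0, screen)

    def test_integrates_to_one_away_from_edges(self, screen):
        # all items >= 5 sigma from every edge: Simpson integral == 1 to 1e-4
        sigma = 30.0
        resp_grid_x = np.linspace(0, screen.width, 901)
        resp_grid_y = np.linspace(0, screen.height, 501)
        xx, yy = np.meshgrid(resp_grid_x, resp_grid_y, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        n = pts.shape[0]
        targ = np.tile([500.0, 400.0], (n, 1))
        nts = np.tile(np.array([[[800.0, 300.0], [300.0, 500.0]]]), (n, 1, 1))
        dens = lm.mixture_density_2d(pts, targ, nts, 0.3, 0.2, sigma, screen)
        grid = dens.reshape(xx.shape)
        integral = simpson(simpson(grid, x=resp_grid_y, axis=1), x=resp_grid_x)
        assert integral == pytest.approx(1.0, abs=1e-4)

    def test_translation_invariance(self, screen):
        shift = np.array([37.0, -12.0])
        resp = np.array([[400.0, 300.0]])
        targ = np.array([[450.0, 280.0]])
        nts = np.array([[[600.0, 500.0]]])
        d1 = lm.mixture_density_2d(resp, targ, nts, 0.2, 0.3, 25.0, screen)
        d2 = lm.mixture_density_2d(resp + shift, targ + shift, nts + shift, 0.2, 0.3, 25.0, screen)
        np.testing.assert_allclose(d1, d2, rtol=1e-12)

    def test_truncated_mode_renormalises_edge_mass(self, screen):
        # target in a corner loses Gaussian mass off-screen; the truncated
        # density integrates to ~1 where the plain one integrates to less
        sigma = 60.0
        gx = np.linspace(0, screen.width, 1001)
        gy = np.linspace(0, screen.height, 561)
        xx, yy = np.meshgrid(gx, gy, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        targ = np.tile([30.0, 30.0], (pts.shape[0], 1))
        args = (pts, targ, np.empty((pts.shape[0], 0, 2)), 0.0, 0.0, sigma, screen)
        plain = simpson(simpson(lm.mixture_density_2d(*args).reshape(xx.shape), x=gy, axis=1), x=gx)
        trunc = simpson(
            simpson(
                lm.mixture_density_2d(*args, truncated=True).reshape(xx.shape), x=gy, axis=1
            ),
            x=gx,
        )
        assert plain < 0.8
        assert trunc == pytest.approx(1.0, abs=1e-3)


class TestDensity1D:
    def test_pure_guessing_uniform(self):
        d = lm.mixture_density_1d([0.3, -2.0], [0.0, 1.0], np.empty((2, 0)), 0.0, 1.0, 2.0)
        np.testing.assert_allclose(d, 1 / TWO_PI)

    def test_small_kappa_approaches_uniform(self):
        d = lm.mixture_density_1d([1.0], [0.0], np.empty((1, 0)), 0.0, 0.0, 1e-8)
        assert d[0] == pytest.approx(1 / TWO_PI, rel=1e-6)

    def test_von_mises_mode_value(self):
        # alpha=1, kappa=2, response on target: e^2 / (2 pi I0(2))
        d = lm.mixture_density_1d([0.5], [0.5], np.empty((1, 0)), 0.0, 0.0, 2.0)
        assert d[0] == pytest.approx(math.e**2 / (TWO_PI * i0(2)), rel=1e-10)

    @pytest.mark.parametrize("beta,gamma,kappa", [(0.0, 0.0, 2.0), (0.3, 0.2, 5.0), (0.5, 0.4, 0.5)])
    def test_integrates_to_one(self, beta, gamma, kappa):
        f = lambda x: lm.mixture_density_1d([x], [0.7], np.array([[1.9, -2.0]]), beta, gamma, kappa)[0]
        integral, _ = quad(f, -math.pi, math.pi, limit=200)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_invalid_kappa(self):
        with pytest.raises(ValueError):
            lm.mixture_density_1d([0.0], [0.0], np.empty((1, 0)), 0.0, 0.5, 0.0)


class TestLogLikelihoodAndBic:
    def test_two_pure_guess_trials(self, screen):
        dens = lm.mixture_density_2d(
            [[5, 5], [900, 700]], [[10, 10], [20, 20]], np.empty((2, 0, 2)), 0.0, 1.0, 10.0, screen
        )
        assert lm.log_likelihood(dens) == pytest.approx(2 * math.log(1 / A), rel=1e-12)

    def test_nontarget_permutation_invariance(self, screen, rng):
        resp = screen.sample_uniform(10, rng)
        targ = screen.sample_uniform(10, rng)
        nts = screen.sample_uniform(30, rng).reshape(10, 3, 2)
        d1 = lm.mixture_density_2d(resp, targ, nts, 0.4, 0.2, 40.0, screen)
        d2 = lm.mixture_density_2d(resp, targ, nts[:, ::-1, :], 0.4, 0.2, 40.0, screen)
        np.testing.assert_allclose(
            np.log(d1).sum(), np.log(d2).sum(), rtol=1e-12
        )

    def test_additive_over_partitions(self, screen, rng):
        resp = screen.sample_uniform(20, rng)
        targ = screen.sample_uniform(20, rng)
        nts = screen.sample_uniform(40, rng).reshape(20, 2, 2)
        dens = lm.mixture_density_2d(resp, targ, nts, 0.3, 0.3, 30.0, screen)
        whole = lm.log_likelihood(dens)
        parts = lm.log_likelihood(dens[:7]) + lm.log_likelihood(dens[7:])
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_matches_per_trial_brute_force(self, screen, rng):
        # independent oracle: per-trial loop via scipy's multivariate normal
        from scipy.stats import multivariate_normal

        beta, gamma, sigma = 0.25, 0.15, 35.0
        resp = screen.sample_uniform(20, rng)
        targ = screen.sample_uniform(20, rng)
        nts = screen.sample_uniform(40, rng).reshape(20, 2, 2)
        expected = 0.0
        for i in range(20):
            cov = np.eye(2) * sigma**2
            p = (1 - beta - gamma) * multivariate_normal.pdf(resp[i], targ[i], cov)
            p += beta * np.mean([multivariate_normal.pdf(resp[i], nt, cov) for nt in nts[i]])
            p += gamma / screen.area
            expected += math.log(p)
        dens = lm.mixture_density_2d(resp, targ, nts, beta, gamma, sigma, screen)
        assert lm.log_likelihood(dens) == pytest.approx(expected, rel=1e-10)

    def test_bic_arithmetic(self):
        assert lm.bic(-500.0, 3, 100) == pytest.approx(3 * math.log(100) + 1000)
        assert lm.bic(-123.4, 0, 50) == pytest.approx(246.8)
        # nested-model identity: dBIC = 2 dlnL - dk ln n
        b1, b2 = lm.bic(-480.0, 4, 100), lm.bic(-500.0, 3, 100)
        assert b1 - b2 == pytest.approx(-2 * (-480 + 500) + 1 * math.log(100))
        with pytest.raises(ValueError):
            lm.bic(-1.0, 3, 0)


class TestTwoClassDensity:
    def _trial(self):
        resp = np.array([[500.0, 400.0]])
        targ = np.array([[200.0, 200.0]])
        nts = np.array([[[450.0, 380.0], [700.0, 500.0]]])
        cls = np.array([[1, 2]])
        return resp, targ, nts, cls

    def test_equal_betas_reduce_to_single_class(self, screen):
        resp, targ, nts, cls = self._trial()
        d2c = lm.mixture_density_2d_two_class(resp, targ, nts, cls, 0.2, 0.2, 0.1, 30.0, screen)
        d1c = lm.mixture_density_2d(resp, targ, nts, 0.4, 0.1, 30.0, screen)
        assert d2c[0] == pytest.approx(d1c[0], rel=1e-12)

    def test_pure_guess_ignores_classes(self, screen):
        resp, targ, nts, cls = self._trial()
        d = lm.mixture_density_2d_two_class(resp, targ, nts, cls, 0.0, 0.0, 1.0, 30.0, screen)
        assert d[0] == pytest.approx(1 / A, rel=1e-12)

    def test_beta2_zero_reduces_to_class1_only(self, screen, rng):
        resp = screen.sample_uniform(20, rng)
        targ = screen.sample_uniform(20, rng)
        nts = screen.sample_uniform(80, rng).reshape(20, 4, 2)
        cls = np.tile([1, 1, 2, 2], (20, 1))
        d2c = lm.mixture_density_2d_two_class(resp, targ, nts, cls, 0.3, 0.0, 0.2, 25.0, screen)
        d1c = lm.mixture_density_2d(resp, targ, nts[:, :2, :], 0.3, 0.2, 25.0, screen)
        np.testing.assert_allclose(np.log(d2c).sum(), np.log(d1c).sum(), rtol=1e-12)


class TestKappaSdConversion:
    def test_limits(self):
        assert lm.kappa_to_sd(1e8) == pytest.approx(0.0, abs=1e-3)
        assert lm.kappa_to_sd(0.0) == pytest.approx(UNIFORM_CIRCULAR_SD)
        with pytest.raises(ValueError):
            lm.kappa_to_sd(-1.0)

    def test_monotone_decreasing(self):
        kappas = np.logspace(-2, 3, 40)
        sds = [lm.kappa_to_sd(k) for k in kappas]
        assert all(a > b for a, b in zip(sds, sds[1:]))

    def test_monte_carlo_oracle_kappa_2(self):
        # circular SD of 1e6 von Mises draws matches the formula to 3 decimals
        draws = np.random.default_rng(7).vonmises(0.0, 2.0, size=6_000_000)
        rbar = np.abs(np.exp(1j * draws).mean())
        mc_sd = math.sqrt(-2 * math.log(rbar))
        assert lm.kappa_to_sd(2.0) == pytest.approx(mc_sd, abs=1e-3)

    def test_round_trip(self):
        for sd in (0.05, 0.3, 1.0, 1.7):
            assert lm.kappa_to_sd(lm.sd_to_kappa(sd)) == pytest.approx(sd, rel=1e-6)
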