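"""Segregating three-component mixture: likelihood, EM fit, posteriors."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

import minmod as mm
from minmod.effects import PointMassEffect
from minmod.mixture import kindred_loglik, posterior_class


def brute_force_kindred_loglik(y, params, baseline, n_quad=12):
    """Independent oracle: exhaustive sum over all carrier configurations
    and latent classes, using scipy's NB pmf directly."""
    y = np.asarray(y)
    n = len(y)
    k, mu = baseline.shape, baseline.mean

    def pmf(val, fold):
        return stats.nbinom.pmf(val, k, k / (k + fold * mu))

    class_likes = [float(np.prod(pmf(y, 1.0)))]
    for effect in (params.suppressor, params.enhancer):
        folds, w = effect.quadrature(n_quad)
        total = 0.0
        for f, wq in zip(folds, w):
            config_sum = 0.0
            for config in itertools.product([0, 1], repeat=n):
                prob = np.prod(
                    [params.segregation if c else 1 - params.segregation for c in config]
                )
                like = np.prod([pmf(v, f if c else 1.0) for v, c in zip(y, config)])
                config_sum += prob * like
            total += wq * config_sum
        class_likes.append(total)
    w = np.asarray(params.weights)
    return float(logsumexp(np.log(class_likes) + np.log(w)))


class TestKindredLoglik:
    def test_matches_exhaustive_enumeration(self, default_mixture, baseline):
        """For kindreds of <= 4 animals the product-form likelihood equals
        the exhaustive carrier-configuration sum to 1e-10."""
        rng = np.random.default_rng(0)
        for n in (1, 2, 3, 4):
            for _ in range(3):
                y = rng.integers(5, 400, size=n)
                got = kindred_loglik(y, default_mixture, baseline)
                want = brute_force_kindred_loglik(y, default_mixture, baseline)
                assert got == pytest.approx(want, abs=1e-10)

    def test_degenerate_mixture_is_baseline(self, baseline):
        params = mm.MixtureParams(
            (1.0, 0.0, 0.0),
            mm.TruncatedLogNormalEffect.suppressor(),
            mm.TruncatedLogNormalEffect.enhancer(),
        )
        y = np.array([80, 120, 99])
        with np.errstate(divide="ignore"):
            got = kindred_loglik(y, params, baseline)
        assert got == pytest.approx(float(baseline.logpdf(y).sum()), abs=1e-10)

    def test_exchangeable_in_animal_order(self, default_mixture, baseline):
        y = np.array([20, 150, 310, 99])
        base = kindred_loglik(y, default_mixture, baseline)
        for perm in itertools.permutations(y):
            assert kindred_loglik(np.array(perm), default_mixture, baseline) == pytest.approx(
                base, abs=1e-12
            )

    def test_empty_kindred_rejected(self, default_mixture, baseline):
        with pytest.raises(ValueError):
            kindred_loglik(np.array([]), default_mixture, baseline)

    def test_negative_phenotype_rejected(self, default_mixture, baseline):
        with pytest.raises(ValueError):
            kindred_loglik(np.array([-3, 10]), default_mixture, baseline)


class TestFitMixture:
    def test_null_simulation_consistency(self, colony, baseline):
        """Data simulated with no modifiers: fitted unaffected weight >= 0.95.

        Clusters of 15 animals make a spurious near-null modifier
        component expensive enough in likelihood for the weights to be
        identifiable."""
        classes = mm.ModifierClassParams(class_weights=(1.0, 0.0, 0.0))
        kins = mm.simulate_kindreds(colony, classes, 500, 15, seed=23)
        fit = mm.fit_mixture(kins, baseline, n_restarts=2, seed=1)
        assert fit.weights[0] >= 0.95

    def test_loglik_path_non_decreasing(self, colony, baseline):
        kins = mm.simulate_kindreds(colony, mm.ModifierClassParams(), 300, 8, seed=29)
        fit = mm.fit_mixture(kins, baseline, n_restarts=1, seed=2)
        path = np.array(fit.loglik_path)
        assert np.all(np.diff(path) >= -1e-6 * (np.abs(path[:-1]) + 1))

    def test_label_ordering_constraint(self, colony, baseline):
        """Suppressor support stays below fold 1 and enhancer above: the
        components cannot swap labels."""
        kins = mm.simulate_kindreds(colony, mm.ModifierClassParams(), 400, 10, seed=31)
        fit = mm.fit_mixture(kins, baseline, n_restarts=2, seed=3)
        f_s, _ = fit.params.suppressor.quadrature(8)
        f_e, _ = fit.params.enhancer.quadrature(8)
        assert np.all(f_s < 1.0)
        assert np.all(f_e > 1.0)

    def test_too_few_kindreds_rejected(self, baseline):
        with pytest.raises(ValueError):
            mm.fit_mixture([np.array([50, 60])], baseline)

    def test_lifespan_channel_fit_runs(self, colony):
        """The same fit machinery accepts the Gaussian log-lifespan
        channel through the shared density interface."""
        kins = mm.simulate_kindreds(colony, mm.ModifierClassParams(), 100, 6, seed=41)
        lifespans = [k.lifespans for k in kins]
        model = colony.lifespan_model()
        fit = mm.fit_mixture(lifespans, model, n_restarts=1, seed=4,
                             tol=1e-6, max_iter=120, screen_max_iter=120)
        path = np.array(fit.loglik_path)
        assert np.all(np.diff(path) >= -1e-6 * (np.abs(path[:-1]) + 1))
        assert np.isfinite(fit.log_likelihood)


class TestPosterior:
    def test_degenerate_prior_gives_degenerate_posterior(self, baseline):
        params = mm.MixtureParams(
            (1.0, 0.0, 0.0),
            mm.TruncatedLogNormalEffect.suppressor(),
            mm.TruncatedLogNormalEffect.enhancer(),
        )
        fit = mm.MixtureFit(params=params, baseline=baseline, log_likelihood=0.0)
        post = posterior_class(np.array([90, 110]), fit)
        assert post == pytest.approx([1.0, 0.0, 0.0], abs=1e-12)

    def test_normalization(self, default_mixture, baseline):
        fit = mm.MixtureFit(params=default_mixture, baseline=baseline, log_likelihood=0.0)
        rng = np.random.default_rng(5)
        for _ in range(10):
            y = rng.integers(1, 500, size=rng.integers(1, 12))
            post = posterior_class(y, fit)
            assert post.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(post >= 0)

    def test_strong_enhancer_kindred_identified(self, colony, baseline):
        """A kindred carrying a 10-fold enhancer is assigned to the
        enhancer class with posterior > 0.9 at 10 progeny."""
        classes = mm.ModifierClassParams(
            class_weights=(0.0, 0.0, 1.0), enhancer_effect=PointMassEffect(10.0)
        )
        kins = mm.simulate_kindreds(colony, classes, 20, 10, seed=37)
        params = mm.MixtureParams(
            (0.39, 0.41, 0.20),
            mm.TruncatedLogNormalEffect.suppressor(),
            mm.TruncatedLogNormalEffect.enhancer(median=1.8, log_sd=0.8),
        )
        fit = mm.MixtureFit(params=params, baseline=baseline, log_likelihood=0.0)
        hits = sum(posterior_class(k.tumor_counts, fit)[2] > 0.9 for k in kins)
        assert hits >= 18
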