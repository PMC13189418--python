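"""The three-parameter Gamma mixture core against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as scipy_gamma

from renalswin.gamma import (EMState, GammaMixture, GammaParams, em_fit,
                             fit_gamma_mom, gamma_feature_map, gamma_moments,
                             gamma_pdf, hierarchical_init, mixture_mean,
                             posterior_responsibilities, segment_by_mixture)
from renalswin.io import ImageSlice
from renalswin.phantom import PhantomSpec, generate_phantom, tiered_laws


class TestGammaPdf:
    def test_shifted_exponential_at_origin(self):
        # alpha=1 reduces to a shifted exponential with density 1/beta
        assert gamma_pdf(1e-12, GammaParams(1.0, 2.0, 0.0)) == pytest.approx(0.5, rel=1e-9)

    def test_zero_outside_support(self):
        p = GammaParams(2.0, 3.0, 10.0)
        assert gamma_pdf(10.0, p) == 0.0
        assert gamma_pdf(5.0, p) == 0.0
        assert gamma_pdf(5.0, p, log=True) == -np.inf

    def test_matches_scipy_density(self, rng):
        for _ in range(10):
            a, b, g = rng.uniform(0.5, 8), rng.uniform(0.5, 20), rng.uniform(-5, 100)
            y = g + rng.uniform(0.01, 50, size=20)
            mine = gamma_pdf(y, GammaParams(a, b, g))
            ref = scipy_gamma.pdf(y, a=a, loc=g, scale=b)
            np.testing.assert_allclose(mine, ref, rtol=1e-10)

    def test_normalizes_by_quadrature(self):
        p = GammaParams(3.7, 12.1, 5.0)
        total, _ = quad(lambda y: gamma_pdf(y, p), 5.0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestMoments:
    def test_closed_form(self):
        m = gamma_moments(GammaParams(2.0, 3.0, 1.0))
        assert m.mean == 7.0
        assert m.variance == 18.0
        assert m.skewness == pytest.approx(2.0 / np.sqrt(2.0))

    def test_location_shift_moves_mean_only(self):
        base = gamma_moments(GammaParams(4.0, 2.0, 0.0))
        shifted = gamma_moments(GammaParams(4.0, 2.0, 12.5))
        assert shifted.mean == base.mean + 12.5
        assert shifted.variance == base.variance

    def test_monte_carlo_agreement(self, rng):
        p = GammaParams(4.0, 10.0, 100.0)
        n = 10 ** 6
        s = p.sample(rng, n)
        se_mean = np.sqrt(400.0 / n)
        assert abs(s.mean() - 140.0) < 3 * se_mean
        # variance of the sample variance for Gamma: use 4th central moment
        m4 = np.mean((s - s.mean()) ** 4)
        se_var = np.sqrt((m4 - 400.0 ** 2) / n)
        assert abs(s.var() - 400.0) < 3 * se_var


class TestMomFit:
    def test_reproduces_sample_mean_exactly(self, rng):
        y = GammaParams(3.0, 5.0, 2.0).sample(rng, 500)
        fit = fit_gamma_mom(y, 2.0)
        assert 2.0 + fit.alpha * fit.beta == pytest.approx(y.mean(), rel=1e-12)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        y = GammaParams(2.0, 3.0, 1.0).sample(rng, 10 ** 5)
        fit = fit_gamma_mom(y, 1.0)
        assert fit.alpha == pytest.approx(2.0, abs=0.05)
        assert fit.beta == pytest.approx(3.0, abs=0.08)

    def test_tight_cluster_limit(self, rng):
        y = 50.0 + rng.normal(0, 1e-3, size=100)  # near point mass at loc+c
        fit = fit_gamma_mom(y, 40.0)
        assert fit.alpha > 1e4
        assert fit.alpha * fit.beta == pytest.approx(10.0, abs=0.01)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            fit_gamma_mom(np.full(20, 5.0), 1.0)
        with pytest.raises(ValueError):
            fit_gamma_mom(np.arange(5.0) + 1, 0.0)  # too few


class TestHierarchicalInit:
    def test_unimodal_gives_one_component(self):
        rng = np.random.default_rng(0)
        y = GammaParams(4.0, 5.0, 10.0).sample(rng, 5000)
        assert hierarchical_init(y, max_k=5, seed=1).K == 1

    def test_two_separated_clusters(self):
        rng = np.random.default_rng(1)
        lo = GammaParams(25, 2, 0).sample(rng, 3000)     # mean 50, sd 10
        hi = GammaParams(25, 2, 150).sample(rng, 2000)   # mean 200, 15 sd away
        mix = hierarchical_init(np.concatenate([lo, hi]), max_k=5, seed=1)
        assert mix.K == 2
        # brute-force cluster fractions via the midpoint threshold
        assert mix.weights[0] == pytest.approx(0.6, abs=0.03)

    def test_weights_sum_to_one(self, rng):
        y = rng.uniform(0, 200, size=2000)
        mix = hierarchical_init(y, max_k=4, seed=3)
        assert mix.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_bad_max_k(self, rng):
        with pytest.raises(ValueError):
            hierarchical_init(rng.uniform(size=100), max_k=0)


class TestEM:
    def test_k1_single_step_equals_mom(self):
        rng = np.random.default_rng(5)
        y = GammaParams(3.0, 4.0, 0.0).sample(rng, 2000)
        init = GammaMixture([fit_gamma_mom(y, -0.5)], np.array([1.0]))
        state = em_fit(y, init, max_iter=1)
        ref = fit_gamma_mom(y, -0.5)
        assert state.mixture.components[0].alpha == pytest.approx(ref.alpha, rel=1e-9)
        assert state.mixture.components[0].beta == pytest.approx(ref.beta, rel=1e-9)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(7)
        true = GammaMixture([GammaParams(25, 2, 0), GammaParams(25, 2, 100)],
                            np.array([0.4, 0.6]))
        y = true.sample(rng, 20000)
        state = em_fit(y, hierarchical_init(y, max_k=5, seed=2))
        assert state.mixture.K == 2
        means = np.sort(state.mixture.component_means)
        np.testing.assert_allclose(means, [50.0, 150.0], rtol=0.02)
        np.testing.assert_allclose(np.sort(state.mixture.weights), [0.4, 0.6],
                                   atol=0.03)

    @pytest.mark.parametrize("seed", range(20))
    def test_loglik_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        mix = GammaMixture([GammaParams(5, 4, 10), GammaParams(6, 5, 150)],
                           np.array([0.5, 0.5]))
        y = mix.sample(rng, 2000)
        state = em_fit(y, hierarchical_init(y, max_k=4, seed=seed), max_iter=50)
        trace = state.loglik_trace
        assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_nonfinite_init_raises(self):
        y = np.array([1.0, 2.0, 3.0] * 10)
        init = GammaMixture([GammaParams(2.0, 1.0, 5.0)], np.array([1.0]))
        with pytest.raises(FloatingPointError):
            em_fit(y, init)


class TestPosteriors:
    def test_k1_all_ones(self, rng):
        mix = GammaMixture([GammaParams(2, 3, 0)], np.array([1.0]))
        r = posterior_responsibilities(rng.uniform(1, 10, size=50), mix)
        np.testing.assert_allclose(r, 1.0)

    def test_rows_sum_to_one(self, rng):
        mix = GammaMixture([GammaParams(4, 3, 0), GammaParams(4, 3, 20),
                            GammaParams(4, 3, 40)], np.array([0.2, 0.5, 0.3]))
        r = posterior_responsibilities(rng.uniform(41, 100, size=200), mix)
        np.testing.assert_allclose(r.sum(axis=-1), 1.0, atol=1e-12)

    def test_equidensity_point_is_half(self):
        # mirror-symmetric components around 50 with equal weights
        mix = GammaMixture([GammaParams(9, 2, 20), GammaParams(9, 2, 64)],
                           np.array([0.5, 0.5]))
        # by symmetry of mean placement (38, 82) the equi-density point is
        # found numerically, then posteriors must be (0.5, 0.5) there
        ys = np.linspace(40, 80, 40001)
        d0 = gamma_pdf(ys, mix.components[0])
        d1 = gamma_pdf(ys, mix.components[1])
        y_eq = ys[np.argmin(np.abs(d0 - d1))]
        r = posterior_responsibilities(np.array([y_eq]), mix)
        np.testing.assert_allclose(r[0], [0.5, 0.5], atol=1e-3)


class TestSegmentByMixture:
    def test_matches_bruteforce_density_argmax(self, rng):
        mix = GammaMixture([GammaParams(4, 5, 0), GammaParams(6, 8, 60),
                            GammaParams(3, 4, 150)], np.array([0.3, 0.4, 0.3]))
        img = ImageSlice(rng.uniform(1, 200, size=(16, 16)))
        seg = segment_by_mixture(img, mix)
        # brute force: per-pixel weighted density comparison
        expect = np.zeros((16, 16), dtype=int)
        for i in range(16):
            for j in range(16):
                y = img.pixels[i, j]
                dens = [w * gamma_pdf(y, c)
                        for c, w in zip(mix.components, mix.weights)]
                expect[i, j] = int(np.argmax(dens))
        np.testing.assert_array_equal(seg.labels, expect)

    def test_two_region_phantom_accuracy(self):
        img, mask, _ = generate_phantom(PhantomSpec(class_label="normal", seed=3))
        y = img.pixels.ravel()
        state = em_fit(y, hierarchical_init(y, max_k=4, seed=0), max_iter=20)
        assert state.mixture.K == 2
        seg = segment_by_mixture(img, state.mixture)
        acc = np.mean((seg.labels > 0) == (mask.labels > 0))
        assert acc >= 0.99

    def test_tie_breaks_to_lowest_index(self):
        p = GammaParams(2, 3, 0)
        mix = GammaMixture([p, p], np.array([0.5, 0.5]))  # identical laws
        img = ImageSlice(np.full((8, 8), 5.0))
        assert segment_by_mixture(img, mix).labels.max() == 0


class TestMixtureMean:
    def test_weighted_average(self):
        mix = GammaMixture([GammaParams(1, 10, 0), GammaParams(1, 20, 0)],
                           np.array([0.5, 0.5]))
        assert mixture_mean(mix) == pytest.approx(15.0)

    def test_mc_agreement(self):
        rng = np.random.default_rng(9)
        mix = GammaMixture([GammaParams(4, 5, 10), GammaParams(3, 8, 100)],
                           np.array([0.7, 0.3]))
        n = 200000
        s = mix.sample(rng, n)
        se = s.std() / np.sqrt(n)
        assert abs(mixture_mean(mix) - s.mean()) < 3 * se


class TestFeatureMap:
    def test_scores_in_unit_interval(self, rng):
        mix = GammaMixture([GammaParams(4, 10, 0)], np.array([1.0]))
        img = ImageSlice(rng.uniform(1, 300, size=(16, 16)))
        m = gamma_feature_map(img, mix).pixels
        assert m.min() >= 0.0 and m.max() <= 1.0

    def test_mode_scores_near_zero(self):
        p = GammaParams(4, 10, 100)  # mode at 100 + 3*10
        mix = GammaMixture([p], np.array([1.0]))
        img = ImageSlice(np.full((8, 8), 130.0))
        assert gamma_feature_map(img, mix).pixels.max() < 1e-9

    def test_lesion_scores_above_parenchyma_at_reduced_contrast(self):
        # mild tier: lesion mean 2 pooled SDs from parenchyma
        les, par = [], []
        for seed in range(4):
            img, mask, _ = generate_phantom(
                PhantomSpec(class_label="cyst", contrast_level="mild", seed=seed))
            laws = tiered_laws("mild")
            w_bg = float(np.mean(mask.labels == 0))
            mix = GammaMixture([laws["background"], laws["parenchyma"]],
                               np.array([w_bg, 1 - w_bg]))
            m = gamma_feature_map(img, mix).pixels
            les.append(m[mask.labels == 2].mean())
            par.append(m[mask.labels == 1].mean())
        assert np.mean(les) > np.mean(par)
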