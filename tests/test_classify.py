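import numpy as np
import pytest

from defringe import (GaussianMixtureTissueModel, PearsonSimilarityMap,
                      build_nri_cube, correlation_map, drop_bands, gmm_fit,
                      gmm_predict, reference_spectrum)
from defringe.classify import EXCLUDED_LABEL
from defringe.nri import apply_exclusion_mask


class TestGmmFit:
    def test_k1_closed_form(self, rng):
        X = rng.normal(3.0, 2.0, (500, 3))
        model = gmm_fit(X, k=1, seed=0)
        np.testing.assert_allclose(model.means[0], X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(model.covariances[0],
                                   np.cov(X.T, bias=True), atol=1e-4)
        assert model.weights[0] == pytest.approx(1.0)

    def test_two_separated_gaussians_recovered(self):
        rng = np.random.default_rng(7)
        lo = rng.normal(0, 1, (1000, 2))
        hi = rng.normal(10, 1, (1000, 2))
        model = gmm_fit(np.vstack([lo, hi]), k=2, seed=3)
        means = model.means[np.argsort(model.means[:, 0])]
        # at 10 sigma separation the fit recovers each cluster's own
        # sample mean almost exactly
        assert np.linalg.norm(means[0] - lo.mean(axis=0)) < 0.02
        assert np.linalg.norm(means[1] - hi.mean(axis=0)) < 0.02
        np.testing.assert_allclose(model.weights, [0.5, 0.5], atol=0.05)

    def test_log_likelihood_trace_non_decreasing(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(0, 1, (300, 2)),
                       rng.normal(3, 1.5, (300, 2))])
        model = gmm_fit(X, k=2, seed=0)
        trace = np.array(model.log_likelihood)
        assert len(trace) >= 1
        assert np.all(np.diff(trace) >= -1e-8)

    def test_weights_sum_to_one_and_covariances_spd(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (400, 3))
        model = gmm_fit(X, k=3, seed=1)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)
        for cov in model.covariances:
            np.testing.assert_allclose(cov, cov.T, atol=1e-12)
            assert np.min(np.linalg.eigvalsh(cov)) > 0

    def test_degenerate_features_warn_but_fit(self):
        X = np.ones((50, 2))
        with pytest.warns(UserWarning, match="constant"):
            model = gmm_fit(X, k=1, seed=0)
        assert np.all(np.isfinite(model.covariances))

    def test_parameter_validation(self, rng):
        X = rng.normal(0, 1, (10, 2))
        with pytest.raises(ValueError):
            gmm_fit(X, k=0)
        with pytest.raises(ValueError):
            gmm_fit(X, k=20)  # fewer rows than components
        with pytest.raises(ValueError):
            gmm_fit(np.array([[np.nan, 1.0]]), k=1)

    def test_subsampling_deterministic(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (5000, 2))
        m1 = gmm_fit(X, k=2, seed=9, subsample=1000)
        m2 = gmm_fit(X, k=2, seed=9, subsample=1000)
        np.testing.assert_array_equal(m1.means, m2.means)


class TestGmmPredict:
    def test_component_mean_maps_to_its_label(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (500, 2)),
                       rng.normal(8, 1, (500, 2))])
        model = gmm_fit(X, k=2, seed=0)
        labels = gmm_predict(model, model.means).labels
        assert labels[0] != labels[1]

    def test_excluded_pixels_flagged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (20, 2))
        model = gmm_fit(X, k=1, seed=0)
        excl = np.zeros(20, bool)
        excl[::2] = True
        lm = gmm_predict(model, X, excluded=excl)
        assert np.all(lm.labels[::2] == EXCLUDED_LABEL)
        assert np.all(lm.labels[1::2] == 0)

    def test_label_proportions_track_weights(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (1500, 2)),
                       rng.normal(12, 1, (500, 2))])
        model = gmm_fit(X, k=2, seed=1)
        lm = gmm_predict(model, X)
        props = np.sort(np.bincount(lm.labels, minlength=2) / len(X))
        np.testing.assert_allclose(props, np.sort(model.weights), atol=0.03)

    def test_dimension_mismatch_rejected(self, rng):
        model = gmm_fit(rng.normal(0, 1, (50, 3)), k=1, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            gmm_predict(model, rng.normal(0, 1, (5, 2)))


class TestReferenceSpectrum:
    def test_uniform_region_returns_its_spectrum(self):
        planes = np.tile(np.array([0.2, -0.4, 0.6])[:, None, None], (1, 20, 20))
        mask = np.zeros((20, 20), bool)
        mask[:10, :10] = True  # exactly 100 pixels
        ref = reference_spectrum(planes, mask, n_pixels=100, seed=0)
        np.testing.assert_allclose(ref, [0.2, -0.4, 0.6])

    def test_seed_determinism(self, rng):
        planes = rng.normal(0, 1, (4, 30, 30))
        mask = np.ones((30, 30), bool)
        r1 = reference_spectrum(planes, mask, seed=5)
        r2 = reference_spectrum(planes, mask, seed=5)
        np.testing.assert_array_equal(r1, r2)
        r3 = reference_spectrum(planes, mask, seed=6)
        assert not np.array_equal(r1, r3)

    def test_sample_mean_near_mask_mean(self, rng):
        planes = rng.normal(0.3, 0.1, (2, 80, 80))
        mask = np.ones((80, 80), bool)
        ref = reference_spectrum(planes, mask, n_pixels=100, seed=1)
        full = planes.reshape(2, -1).mean(axis=1)
        # CLT: sd of the sample mean ~ 0.1/10; allow 4 sigma
        np.testing.assert_allclose(ref, full, atol=4 * 0.1 / 10)

    def test_small_mask_uses_all_with_warning(self, rng):
        planes = rng.normal(0, 1, (2, 5, 5))
        mask = np.zeros((5, 5), bool)
        mask[0, :3] = True
        with pytest.warns(UserWarning, match="using all"):
            ref = reference_spectrum(planes, mask, n_pixels=100, seed=0)
        np.testing.assert_allclose(ref, planes[:, 0, :3].mean(axis=1))


class TestCorrelationMap:
    def test_reference_itself_scores_one(self, rng):
        ref = rng.normal(0, 1, 6)
        planes = np.tile(ref[:, None, None], (1, 3, 3))
        cm = correlation_map(planes, ref)
        np.testing.assert_allclose(cm.values, 1.0, atol=1e-12)

    def test_brightness_and_offset_invariance(self, rng):
        ref = rng.normal(0, 1, 8)
        scaled = (2.5 * ref + 7.0)[:, None, None]
        cm = correlation_map(scaled, ref)
        assert cm.values[0, 0] == pytest.approx(1.0)

    def test_negated_reference_scores_minus_one(self, rng):
        ref = rng.normal(0, 1, 8)
        cm = correlation_map(-ref[:, None, None], ref)
        assert cm.values[0, 0] == pytest.approx(-1.0)

    def test_constant_pixel_flagged_undefined(self, rng):
        ref = rng.normal(0, 1, 5)
        planes = np.stack([np.full((2, 2), v) for v in ref])
        planes[:, 1, 1] = 3.0  # constant across features
        cm = correlation_map(planes, ref)
        assert cm.undefined[1, 1]
        assert np.isnan(cm.values[1, 1])
        assert not cm.undefined[0, 0]

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_map(np.zeros((3, 2, 2)), np.ones(3))


class TestOnSyntheticCube:
    def test_tissues_separate(self, small_cube):
        cube, lesion, sr = small_cube
        work = drop_bands(cube, [0, 1])
        nri = build_nri_cube(work)
        # supervised: lesion reference separates lesion from healthy
        ref = reference_spectrum(nri, lesion & ~sr, n_pixels=100, seed=5)
        cm = correlation_map(nri, ref)
        median = np.nanmedian(cm.values)
        frac = np.mean(cm.values[lesion & ~sr] > median)
        assert frac >= 0.95
        # unsupervised: k=2 GMM purity after optimal label matching
        table, retained = apply_exclusion_mask(nri, sr)
        model = GaussianMixtureTissueModel(n_components=2, random_state=7)
        labels = model.fit_predict(table)
        truth = lesion.ravel()[retained]
        purity = max(np.mean((labels == 0) == truth),
                     np.mean((labels == 1) == truth))
        assert purity >= 0.95


def test_pearson_similarity_estimator(rng):
    ref_rows = rng.normal(0, 1, (10, 6)) + np.linspace(0, 5, 6)
    est = PearsonSimilarityMap().fit(ref_rows)
    scores = est.predict(est.reference_[None, :] * 3.0 + 1.0)
    assert scores[0] == pytest.approx(1.0)
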