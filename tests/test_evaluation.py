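"""Metric oracles (FID, PSNR), volumetrics, segmentation, regressors."""

import dataclasses

import numpy as np
import pytest
import scipy.linalg

from cardiosynth.evaluation import (EvalTable, FeatureStats,
                                    extract_features, fid,
                                    normalized_variation,
                                    predicted_covariate_mae, psnr,
                                    segment_generated,
                                    septum_width_from_mask,
                                    train_covariate_regressor,
                                    train_feature_extractor,
                                    volumetric_metrics)
from cardiosynth.phantom import (LV, PhantomConfig, generate_samples,
                                 geometry_from_covariates, render_phantom,
                                 sample_phantom, toy_phantom_config)


class TestFid:
    def test_identical_stats_give_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(50, 4))
        st = FeatureStats(a.mean(0), np.cov(a, rowvar=False))
        assert fid(st, st) == pytest.approx(0.0, abs=1e-10)

    def test_equal_covariance_reduces_to_mean_distance(self):
        sigma = np.array([[2.0, 0.3], [0.3, 1.0]])
        d = np.array([0.7, -1.2])
        a = FeatureStats(np.zeros(2), sigma)
        b = FeatureStats(d, sigma)
        assert fid(a, b) == pytest.approx(float(d @ d), rel=1e-10)

    def test_scalar_closed_form_example(self):
        # 1-D Gaussians: (mu1-mu2)^2 + (sd1-sd2)^2 = 1 + (1-2)^2 = 2
        a = FeatureStats(np.array([0.0]), np.array([[1.0]]))
        b = FeatureStats(np.array([1.0]), np.array([[4.0]]))
        assert fid(a, b) == pytest.approx(2.0, rel=1e-10)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_scalar_closed_form_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        m1, m2 = rng.normal(size=2)
        s1, s2 = rng.uniform(0.1, 3.0, size=2)
        a = FeatureStats(np.array([m1]), np.array([[s1 ** 2]]))
        b = FeatureStats(np.array([m2]), np.array([[s2 ** 2]]))
        assert fid(a, b) == pytest.approx((m1 - m2) ** 2 + (s1 - s2) ** 2,
                                          abs=1e-8)

    @pytest.mark.parametrize("dim", [2, 4, 8])
    def test_matches_matrix_function_oracle(self, dim):
        """Independent route: trace of scipy.linalg.sqrtm of the plain
        product Sigma_a @ Sigma_b."""
        rng = np.random.default_rng(dim)
        for _ in range(5):
            A = rng.normal(size=(dim + 4, dim))
            B = rng.normal(size=(dim + 4, dim))
            sa = np.cov(A, rowvar=False)
            sb = np.cov(B, rowvar=False)
            mua, mub = A.mean(0), B.mean(0)
            cross = scipy.linalg.sqrtm(sa @ sb)
            if np.iscomplexobj(cross):
                cross = cross.real
            expected = float((mua - mub) @ (mua - mub) + np.trace(sa)
                             + np.trace(sb) - 2 * np.trace(cross))
            got = fid(FeatureStats(mua, sa), FeatureStats(mub, sb))
            assert got == pytest.approx(expected, rel=1e-6, abs=1e-8)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(30, 3))
        B = rng.normal(size=(30, 3)) + 1.0
        a = FeatureStats(A.mean(0), np.cov(A, rowvar=False))
        b = FeatureStats(B.mean(0), np.cov(B, rowvar=False))
        assert fid(a, b) == pytest.approx(fid(b, a), rel=1e-9)
        assert fid(a, b) >= 0

    def test_dimension_mismatch_rejected(self):
        a = FeatureStats(np.zeros(2), np.eye(2))
        b = FeatureStats(np.zeros(3), np.eye(3))
        with pytest.raises(ValueError):
            fid(a, b)


class TestPsnr:
    def test_identical_images_sentinel_infinity(self):
        img = np.random.default_rng(0).uniform(0, 1, (8, 8))
        assert psnr(img, img) == np.inf

    def test_known_mse_values(self):
        a = np.zeros((10, 10))
        b = np.full((10, 10), 0.1)       # MSE = 0.01 -> 20 dB
        assert psnr(a, b) == pytest.approx(20.0, abs=1e-12)
        c = np.ones((10, 10))            # MSE = 1 -> 0 dB
        assert psnr(a, c) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_decreasing_in_noise_level(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0.2, 0.8, (32, 32))
        vals = []
        for sd in (0.01, 0.02, 0.05, 0.1, 0.2):
            noisy = img + np.random.default_rng(7).normal(0, sd, img.shape)
            vals.append(psnr(img, noisy))
        assert np.all(np.diff(vals) < 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4)), np.zeros((5, 5)))


class TestVolumetrics:
    def test_septum_and_lv_area_recover_geometry(self, noiseless_config):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            age = float(rng.uniform(45, 82))
            params = geometry_from_covariates(age, config=noiseless_config)
            s = render_phantom(params, noise_sd=0.0)
            m = volumetric_metrics(s.mask)
            assert abs(m["septum_width"] - params.septum_width) <= 1.0
            expected_area = np.pi * params.lv_cavity_radius ** 2
            assert m["lv_area"] == pytest.approx(expected_area, rel=0.05)

    def test_ejection_fraction_identities(self):
        mask_ed = np.zeros((32, 32), dtype=np.uint8)
        mask_ed[8:16, 8:16] = LV
        mask_ed[8:16, 16:20] = 2
        mask_ed[8:16, 20:25] = 3
        m = volumetric_metrics(mask_ed, es_mask=mask_ed)
        assert m["ejection_fraction"] == 0.0
        mask_es = mask_ed.copy()
        mask_es[12:16, 8:16] = 0          # halve the LV area
        m2 = volumetric_metrics(mask_ed, es_mask=mask_es)
        assert m2["ejection_fraction"] == pytest.approx(0.5)

    def test_missing_label_error_names_region(self):
        with pytest.raises(ValueError, match="lv_cavity"):
            volumetric_metrics(np.zeros((16, 16), dtype=np.uint8))

    def test_ed_es_phantom_pair_has_positive_ejection_fraction(self):
        ed = sample_phantom(60, phase="ED", noise_sd=0.0, rng_seed=1)
        es = sample_phantom(60, phase="ES", noise_sd=0.0, rng_seed=1)
        ef = volumetric_metrics(ed.mask, es.mask)["ejection_fraction"]
        assert 0.3 < ef < 0.7


class TestNormalizedVariation:
    def test_identities(self):
        orig = np.array([10.0, 12.0, 8.0])     # mean 10
        nv = normalized_variation([10.0, 10.5], orig)
        np.testing.assert_allclose(nv, [0.0, 0.05])
        assert normalized_variation(orig, orig).mean() \
            == pytest.approx(0.0, abs=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            normalized_variation([1.0], [1.0, -1.0])


class TestSegmentation:
    @pytest.mark.parametrize("seed", range(20))
    def test_agreement_with_ground_truth_masks(self, seed):
        """Noiseless phantoms at the reference resolution: >= 98% of pixels
        match the renderer's mask (residual disagreement is half-pixel
        boundary quantization, which scales with perimeter/area)."""
        s = sample_phantom(float(45 + (seed * 2) % 37), 27, "F", seed,
                           image_size=128, noise_sd=0.0)
        pred = segment_generated(s.image)
        agreement = (pred == s.mask).mean()
        assert agreement >= 0.98

    def test_zero_image_raises_no_region(self):
        with pytest.raises(ValueError, match="region"):
            segment_generated(np.zeros((64, 64)))

    def test_deterministic(self):
        s = sample_phantom(60, 27, "F", 3, image_size=64, noise_sd=0.01)
        np.testing.assert_array_equal(segment_generated(s.image),
                                      segment_generated(s.image))


class _PerfectRegressor:
    """Oracle regressor: reads the covariate straight from phantom geometry
    (septum width is invertible in age); used to isolate the evaluation
    arithmetic from regressor quality."""

    def __init__(self, mapping):
        self._m = mapping

    def predict(self, images):
        return np.array([self._m(img) for img in np.atleast_3d(
            np.asarray(images))])


class _IdentityGenerator:
    def synthesize(self, x, a_d):
        from cardiosynth.networks import SynthesisResult
        x = np.asarray(x)
        return SynthesisResult(x=x, mapping=np.zeros_like(x), output=x)


class TestPredictedCovariateMae:
    def setup_method(self):
        self.ages = np.array([50.0, 60.0, 70.0])
        self.images = np.stack([np.full((8, 8), a / 100) for a in self.ages])
        self.lookup = {round(float(i.mean()), 6): a
                       for i, a in zip(self.images, self.ages)}
        self.reg = _PerfectRegressor(
            lambda img: self.lookup[round(float(img.mean()), 6)])

    def test_zero_order_with_perfect_regressor_equals_gap(self):
        table = predicted_covariate_mae(self.reg, _IdentityGenerator(),
                                        self.images, self.ages, [-10, 5, 20])
        for g in (-10, 5, 20):
            assert table.row(g, "zero_order")["mae_mean"] \
                == pytest.approx(abs(g))
            # identity generator == zero order here
            assert table.row(g, "model")["mae_mean"] == pytest.approx(abs(g))

    def test_perfect_generator_and_regressor_give_zero(self):
        class PerfectGen:
            def synthesize(inner, x, a_d):
                from cardiosynth.networks import SynthesisResult
                x = np.asarray(x)
                out = x + a_d / 100.0
                return SynthesisResult(x=x, mapping=out - x, output=out)

        reg = _PerfectRegressor(lambda img: float(img.mean()) * 100)
        table = predicted_covariate_mae(reg, PerfectGen(), self.images,
                                        self.ages, [10.0])
        assert table.row(10.0, "model")["mae_mean"] \
            == pytest.approx(0.0, abs=1e-6)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            predicted_covariate_mae(self.reg, _IdentityGenerator(),
                                    np.empty((0, 8, 8)), np.empty(0), [5])


class TestRegressorTraining:
    def test_noiseless_cohort_age_is_decodable(self):
        """Jitter off, no noise: geometry is a deterministic function of
        age, so a small CNN reaches held-out MAE < 2 years (the septum
        width alone decodes age exactly)."""
        cfg = dataclasses.replace(toy_phantom_config(32), jitter=False)
        samples = generate_samples(300, "uniform", "age", 5, config=cfg,
                                   image_size=32, noise_sd=0.0)
        x = np.stack([s.image for s in samples])
        y = np.array([s.age for s in samples])
        reg = train_covariate_regressor(x, y, width=8, epochs=10, seed=0)
        assert reg.heldout_mae < 2.0
        # determinism of the fit
        reg2 = train_covariate_regressor(x, y, width=8, epochs=10, seed=0)
        assert reg.heldout_mae == reg2.heldout_mae

    def test_shuffled_labels_fall_back_to_null_error(self):
        cfg = dataclasses.replace(toy_phantom_config(32), jitter=False)
        samples = generate_samples(120, "uniform", "age", 6, config=cfg,
                                   image_size=32, noise_sd=0.0)
        x = np.stack([s.image for s in samples])
        y = np.array([s.age for s in samples])
        y_shuf = np.random.default_rng(0).permutation(y)
        reg = train_covariate_regressor(x, y_shuf, width=6, epochs=3, seed=1)
        null_mae = np.abs(y - y.mean()).mean()
        assert reg.heldout_mae > 0.5 * null_mae

    def test_degenerate_labels_rejected(self):
        x = np.zeros((10, 32, 32), dtype=np.float32)
        with pytest.raises(ValueError, match="variance"):
            train_covariate_regressor(x, np.full(10, 60.0))


class TestFeatureStats:
    def test_duplicated_image_set_gives_zero_fid(self, phantom_batch32):
        x, ages = phantom_batch32
        ext = train_feature_extractor(x, ages, width=4, epochs=1, seed=0)
        a = extract_features(x, ext)
        b = extract_features(x.copy(), ext)
        assert fid(a, b) == pytest.approx(0.0, abs=1e-10)

    def test_shrinkage_path_yields_psd_covariance(self, phantom_batch32):
        x, ages = phantom_batch32
        ext = train_feature_extractor(x, ages, width=4, epochs=1, seed=0)
        stats = extract_features(x[:5], ext)    # n < feature dim
        vals = np.linalg.eigvalsh(stats.sigma)
        assert vals.min() >= -1e-10

    def test_too_few_images_rejected(self, phantom_batch32):
        x, ages = phantom_batch32
        ext = train_feature_extractor(x, ages, width=4, epochs=1, seed=0)
        with pytest.raises(ValueError):
            extract_features(x[:1], ext)
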