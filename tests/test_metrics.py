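"""Metric identities, hand-computed oracles, and cross-checks against
independent reference implementations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focusfuse.metrics import (
    MetricUndefinedError,
    ms_ssim,
    psnr,
    rmse,
    sam,
    sam_stack,
    similarity_report,
    ssim,
    uqi,
)


class TestRMSEPSNR:
    def test_identity_zero(self, random_image):
        assert rmse(random_image, random_image) == 0.0

    def test_constant_offset_255(self):
        assert rmse(np.zeros((4, 4)), np.ones((4, 4))) == pytest.approx(255.0)

    def test_hand_computed_quarter(self):
        # 2x2 pair differing by (0,0,0,2) 8-bit levels: sqrt(4/4) = 1
        x = np.zeros((2, 2))
        y = np.array([[0.0, 0.0], [0.0, 2.0 / 255.0]])
        assert rmse(x, y) == pytest.approx(1.0)

    def test_psnr_identity_infinite(self, random_image):
        assert psnr(random_image, random_image) == math.inf

    @pytest.mark.parametrize("r,expected", [(255.0, 0.0), (2.55, 40.0)])
    def test_psnr_known_values(self, r, expected):
        x = np.zeros((8, 8))
        y = np.full((8, 8), r / 255.0)
        assert psnr(x, y) == pytest.approx(expected)

    def test_psnr_rmse_consistency(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        assert psnr(x, y) == pytest.approx(20 * math.log10(255.0 / rmse(x, y)))

    def test_cross_check_skimage(self, rng):
        from skimage.metrics import peak_signal_noise_ratio

        x, y = rng.random((32, 32)), rng.random((32, 32))
        ref = peak_signal_noise_ratio(x * 255, y * 255, data_range=255)
        assert psnr(x, y) == pytest.approx(ref, rel=1e-10)


class TestSAM:
    def test_identity_and_scale_invariance(self, random_image):
        assert sam(random_image, random_image) == pytest.approx(0.0)
        assert sam(random_image, 2.0 * random_image) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_quarter_turn(self):
        assert sam(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])) == pytest.approx(math.pi / 2)

    def test_zero_vector_rejected(self, random_image):
        with pytest.raises(MetricUndefinedError):
            sam(random_image, np.zeros_like(random_image))

    def test_stack_variant_identity(self, rng):
        s = rng.random((7, 8, 8)) + 0.1
        assert sam_stack(s, s) == pytest.approx(0.0, abs=1e-7)


class TestUQI:
    def test_identity_one(self, random_image):
        assert uqi(random_image, random_image) == pytest.approx(1.0)

    def test_anticorrelated_negative(self, rng):
        x = rng.random((32, 32))
        y = -x + x.mean() * 2  # same mean, flipped covariance
        assert uqi(x, y) < 0

    def test_hand_computed_2x2(self):
        x = np.array([[0.0, 1.0], [1.0, 0.0]])
        y = np.array([[0.0, 1.0], [1.0, 1.0]])
        mx, my = 0.5, 0.75
        vx = np.mean((x - mx) ** 2)
        vy = np.mean((y - my) ** 2)
        cov = np.mean((x - mx) * (y - my))
        expected = 4 * cov * mx * my / ((vx + vy) * (mx**2 + my**2))
        assert uqi(x, y) == pytest.approx(expected)

    def test_degenerate_rejected(self):
        z = np.zeros((4, 4))
        with pytest.raises(MetricUndefinedError):
            uqi(z, z)

    def test_windowed_identity(self, random_image):
        assert uqi(random_image, random_image, windowed=True) == pytest.approx(1.0)


class TestSSIM:
    def test_identity_one(self, random_image):
        assert ssim(random_image, random_image) == pytest.approx(1.0)
        assert ssim(random_image, random_image, c1=0.2, c2=0.4) == pytest.approx(1.0)

    def test_luminance_offset_penalized(self, random_image):
        shifted = np.clip(random_image * 0.5 + 0.25, 0, 1)  # mean moved
        assert ssim(random_image, np.clip(random_image + 0.2, 0, 1)) < 1.0
        assert ssim(random_image, shifted) < 1.0

    def test_global_mode_hand_computed(self, rng):
        x, y = rng.random((6, 6)), rng.random((6, 6))
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cov = np.mean((x - mx) * (y - my))
        expected = ((2 * mx * my + 0.01) * (2 * cov + 0.03)) / (
            (mx**2 + my**2 + 0.01) * (vx + vy + 0.03)
        )
        assert ssim(x, y, windowed=False) == pytest.approx(expected)

    def test_small_image_falls_back_to_global(self, rng):
        x, y = rng.random((6, 6)), rng.random((6, 6))
        assert ssim(x, y) == pytest.approx(ssim(x, y, windowed=False))

    def test_cross_check_skimage_equivalent_parameterization(self, rng):
        # skimage uses C = (K*L)^2; with L=1, K=sqrt(C) makes the two
        # parameterizations coincide exactly
        from skimage.metrics import structural_similarity

        x = rng.random((64, 64))
        y = np.clip(x + 0.05 * rng.standard_normal(x.shape), 0, 1)
        ref = structural_similarity(
            x, y, gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
            data_range=1.0, K1=math.sqrt(0.01), K2=math.sqrt(0.03),
        )
        assert ssim(x, y) == pytest.approx(ref, abs=1e-9)


class TestMSSSIM:
    def test_identity_one(self, rng):
        x = rng.random((256, 256))
        assert ms_ssim(x, x) == pytest.approx(1.0)

    def test_single_scale_reduces_to_ssim(self, rng):
        x = rng.random((64, 64))
        y = np.clip(x * 0.9 + 0.05, 0, 1)
        assert ms_ssim(x, y, n_scales=1) == pytest.approx(ssim(x, y), abs=1e-9)

    def test_monotone_under_blur(self, rng):
        from scipy import ndimage as ndi

        x = np.clip(ndi.gaussian_filter(rng.random((256, 256)), 1.0) * 6 % 1, 0, 1)
        vals = [ms_ssim(x, np.clip(ndi.gaussian_filter(x, s), 0, 1))
                for s in (0.5, 1, 2, 4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_too_small_rejected_with_feasible_count(self, rng):
        with pytest.raises(ValueError, match="at most"):
            ms_ssim(rng.random((32, 32)), rng.random((32, 32)), n_scales=5)


class TestReport:
    def test_identity_row(self, random_image):
        rep = similarity_report(random_image, random_image)
        assert rep.rmse == 0.0
        assert rep.sam == pytest.approx(0.0)
        assert rep.psnr == math.inf
        assert rep.uqi == pytest.approx(1.0)
        assert rep.ssim == pytest.approx(1.0)
        assert rep.ms_ssim == pytest.approx(1.0)

    def test_fields_match_individual_calls(self, rng):
        x, y = rng.random((64, 64)), rng.random((64, 64))
        rep = similarity_report(x, y)
        assert rep.rmse == rmse(x, y)
        assert rep.sam == sam(x, y)
        assert rep.psnr == psnr(x, y)
        assert rep.uqi == uqi(x, y)
        assert rep.ssim == ssim(x, y)

    def test_degenerate_metrics_reported_as_none(self):
        z = np.zeros((16, 16))
        rep = similarity_report(z, z)
        assert rep.sam is None and rep.uqi is None
        assert "sam" in rep.errors and "uqi" in rep.errors
        assert rep.rmse == 0.0

    def test_engine_outputs_all_finite(self, synthetic_stack):
        from focusfuse.pyramid import fuse_lp_stack
        from focusfuse.ecc import fuse_ecc

        lp = fuse_lp_stack(synthetic_stack.stack, n_levels=4)
        ecc = fuse_ecc(synthetic_stack.stack)
        rep = similarity_report(lp, ecc)
        for name in rep.FIELDS:
            v = getattr(rep, name)
            assert v is not None and np.isfinite(v)


class TestSymmetryAndBounds:
    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_ranges(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.random((32, 32)), r.random((32, 32))
        assert rmse(x, y) == pytest.approx(rmse(y, x))
        assert sam(x, y) == pytest.approx(sam(y, x))
        assert psnr(x, y) == pytest.approx(psnr(y, x))
        assert uqi(x, y) == pytest.approx(uqi(y, x))
        assert ssim(x, y) == pytest.approx(ssim(y, x))
        assert 0 <= sam(x, y) <= math.pi
        assert -1 <= uqi(x, y) <= 1
        assert -1 <= ssim(x, y) <= 1
        assert 0 <= ms_ssim(x, y, n_scales=2) <= 1
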