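"""Matched-filter bank and vessel segmentation."""

import math

import numpy as np
import pytest

from curvegrade.vessels import (
    VesselParams,
    base_kernel,
    build_filter_bank,
    length_filter,
    matched_filter_response,
    scaled_min_length,
    segment_vessels,
)


def _line_image(angle_deg, shape=(128, 128), sigma=2.0, contrast=0.6):
    """Bright background with one dark Gaussian-profile vessel through the
    center whose axis is ``angle_deg`` from the row axis."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    a = np.deg2rad(angle_deg)
    d = (rr - h / 2) * np.sin(a) - (cc - w / 2) * np.cos(a)
    return 1.0 - contrast * np.exp(-(d**2) / (2 * sigma**2)), np.abs(d) < 1


class TestFilterBank:
    def test_twelve_kernels_at_15_degrees(self):
        bank = build_filter_bank(step_deg=15.0)
        assert len(bank.kernels) == 12
        assert bank.angles == [15.0 * i for i in range(12)]

    def test_base_kernel_is_minus_one_on_axis(self):
        base = base_kernel(2.0, 9)
        assert base[:, base.shape[1] // 2].max() == -1.0
        assert base[:, base.shape[1] // 2].min() == -1.0

    def test_base_kernel_symmetric_in_x(self):
        base = base_kernel(2.0, 9)
        np.testing.assert_allclose(base, base[:, ::-1], atol=1e-15)

    def test_kernel_count_times_step_is_180(self):
        for step in (10.0, 15.0, 30.0, 45.0):
            bank = build_filter_bank(step_deg=step)
            assert len(bank.kernels) * step == 180.0

    def test_negative_well_integral(self):
        """Pre-subtraction well integrates to -sigma*sqrt(2 pi)*L within 2%
        for support half-width >= 3 sigma."""
        sigma, length = 2.0, 9
        total = base_kernel(sigma, length).sum()
        expected = -sigma * math.sqrt(2 * math.pi) * length
        assert abs(total - expected) / abs(expected) < 0.02

    def test_rotated_kernels_are_zero_mean(self):
        bank = build_filter_bank()
        for kern in bank.kernels:
            assert abs(kern.sum()) < 1e-9

    def test_invalid_geometry_raises(self):
        with pytest.raises(ValueError):
            build_filter_bank(sigma=-1)
        with pytest.raises(ValueError):
            build_filter_bank(length=8)
        with pytest.raises(ValueError):
            build_filter_bank(step_deg=17.0)


class TestResponse:
    def test_orientation_recovery_at_30_degrees(self):
        img, on_axis = _line_image(30.0)
        bank = build_filter_bank()
        _, ori = matched_filter_response(img, bank, return_orientation=True)
        interior = on_axis.copy()
        interior[:16] = interior[-16:] = False
        interior[:, :16] = interior[:, -16:] = False
        assert (ori[interior] == 30.0).mean() >= 0.8

    def test_constant_image_gives_flat_response(self):
        bank = build_filter_bank()
        resp = matched_filter_response(np.full((64, 64), 0.3), bank)
        assert resp.std() < 1e-6

    def test_negative_kernel_equals_positive_on_inverted(self):
        """With zero-mean kernels, correlating the negative bank with an
        image equals correlating the positive bank with its inversion."""
        from scipy.ndimage import correlate

        rng = np.random.default_rng(0)
        img = rng.random((64, 64))
        bank = build_filter_bank()
        k = bank.kernels[3]
        a = correlate(img, k, mode="nearest")
        b = correlate(1.0 - img, -k, mode="nearest")
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_rotation_consistency(self):
        img, _ = _line_image(0.0)
        bank = build_filter_bank()
        r0 = matched_filter_response(img, bank)
        r90 = matched_filter_response(np.rot90(img), bank)
        back = np.rot90(r90, k=-1)
        assert np.abs(r0[16:-16, 16:-16] - back[16:-16, 16:-16]).mean() < 0.05


class TestSegmentation:
    def test_phantom_dice(self, clean_retina, clean_vessels):
        _, _, truth = clean_retina
        mask, _ = clean_vessels
        dice = 2 * (mask & truth.vessel_mask).sum() / (
            mask.sum() + truth.vessel_mask.sum()
        )
        assert dice >= 0.70

    def test_all_dark_image_gives_empty_mask(self):
        assert segment_vessels(np.zeros((128, 128))).sum() == 0

    def test_length_filter_keeps_single_long_component(self):
        mask = np.zeros((256, 256), dtype=bool)
        mask[128, 20:220] = True  # one 200-px vessel
        rng = np.random.default_rng(2)
        for _ in range(30):  # 30 isolated 3-px specks
            r, c = rng.integers(5, 250, 2)
            if abs(int(r) - 128) < 5:
                continue
            mask[r, c : c + 3] = True
        out = length_filter(mask, 50)
        from skimage.measure import label

        assert label(out, connectivity=2).max() == 1

    def test_min_length_scales_with_diagonal(self):
        p = VesselParams()
        assert scaled_min_length((576, 720), p) == 50
        assert scaled_min_length((288, 360), p) == 25

    def test_adding_a_vessel_keeps_existing_detections(self):
        """Monotonicity: drawing an extra vessel never removes previously
        detected vessel pixels (up to 2% slack from renormalization)."""
        h, w = 576, 720
        rr, cc = np.mgrid[0:h, 0:w]

        def vessel(angle, offr, offc):
            a = np.deg2rad(angle)
            d = (rr - h / 2 - offr) * np.sin(a) - (cc - w / 2 - offc) * np.cos(a)
            return np.exp(-(d**2) / (2 * 2.0**2))

        rng = np.random.default_rng(3)
        noise = 0.01 * rng.standard_normal((h, w))
        tree = [
            vessel(20 * i + 7, (i % 5 - 2) * 90, (i % 4 - 1.5) * 130)
            for i in range(14)
        ]
        base = np.clip(0.2 + 0.5 * sum(tree) + noise, 0, 1)
        more = np.clip(0.2 + 0.5 * (sum(tree) + vessel(45, 5, 15)) + noise, 0, 1)
        m1 = segment_vessels(base)
        m2 = segment_vessels(more)
        lost = (m1 & ~m2).sum()
        assert lost <= 0.02 * max(m1.sum(), 1)
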