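"""FAZ segmentation: ROI geometry, endpoint rules, dual-path intersection."""

import numpy as np
import pytest

from curvegrade.faz import (
    FazParams,
    InsufficientEndpointsError,
    RoiOutOfBoundsError,
    RoiSpec,
    _boundary_and_variance,
    define_roi,
    filter_endpoints,
    find_endpoints,
    segment_faz,
)
from curvegrade.optic_disc import OpticDisc


def _od(center=(288.0, 100.0), radius=20.0, shape=(576, 720)):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.hypot(rr - center[0], cc - center[1]) <= radius
    return OpticDisc(center=center, radius=radius, mask=mask)


def _roi(center, radius):
    return RoiSpec(center=center, radius=radius, od_reference=_od())


class TestDefineRoi:
    def test_two_and_a_half_diameters_toward_image_center(self):
        roi = define_roi(_od((288.0, 100.0), 20.0), (576, 720))
        assert roi.center == (288.0, 100.0 + 2.5 * 40.0)

    def test_left_hint_mirrors_the_rule(self):
        roi = define_roi(_od((288.0, 600.0), 20.0), (576, 720), side_hint="left")
        assert roi.center == (288.0, 600.0 - 2.5 * 40.0)

    def test_center_tie_breaks_right(self):
        roi = define_roi(_od((288.0, 360.0), 20.0), (576, 720))
        assert roi.center[1] > 360.0

    def test_roi_fully_outside_raises(self):
        with pytest.raises(RoiOutOfBoundsError):
            define_roi(_od((288.0, 700.0), 20.0), (576, 720), side_hint="right")


class TestFindEndpoints:
    def test_horizontal_segment_has_two_tips(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[32, 30:35] = True  # 5-px skeleton segment
        roi = _roi((32.0, 32.0), 20.0)
        tips = find_endpoints(mask, roi)
        assert sorted(tips) == [(32, 30), (32, 34)]

    def test_interior_pixels_sum_to_three(self):
        # enumerated oracle for the 3x3 sums along a 1-px line
        from scipy.ndimage import correlate

        mask = np.zeros((16, 16), dtype=int)
        mask[8, 4:12] = 1
        sums = correlate(mask, np.ones((3, 3), dtype=int), mode="constant")
        assert sums[8, 4] == 2 and sums[8, 11] == 2
        assert (sums[8, 5:11] == 3).all()

    def test_isolated_pixel_is_not_a_tip(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[32, 32] = True
        assert find_endpoints(mask, _roi((32.0, 32.0), 20.0)) == []

    def test_solid_block_center_sums_to_nine(self):
        # the window rule itself: the center of a solid 3x3 block sums to 9
        # ("within vessel area"), nowhere near the tip value of 2
        from scipy.ndimage import correlate

        mask = np.zeros((9, 9), dtype=int)
        mask[3:6, 3:6] = 1
        sums = correlate(mask, np.ones((3, 3), dtype=int), mode="constant")
        assert sums[4, 4] == 9

    def test_filled_disk_has_no_tips(self):
        rr, cc = np.mgrid[0:64, 0:64]
        mask = np.hypot(rr - 32, cc - 32) <= 6
        assert find_endpoints(mask, _roi((32.0, 32.0), 20.0)) == []


class TestFilterEndpoints:
    def test_square_corners_all_retained(self):
        pts = [(0.0, 0.0), (0.0, 2.0), (2.0, 0.0), (2.0, 2.0)]
        assert len(filter_endpoints(pts)) == 4

    def test_far_outlier_removed(self):
        pts = [(1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0), (10.0, 0.0)]
        kept = filter_endpoints(pts)
        assert len(kept) == 4
        assert (10.0, 0.0) not in kept

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientEndpointsError):
            filter_endpoints([(0.0, 0.0), (1.0, 1.0)])


class TestSegmentFaz:
    def test_phantom_recovery_within_30_percent(self, faz30_retina):
        from curvegrade.optic_disc import detect_od
        from curvegrade.vessels import segment_vessels

        ffa, _, truth = faz30_retina
        vm = segment_vessels(ffa)
        od = detect_od(ffa, vm)
        result = segment_faz(vm, ffa, define_roi(od, ffa.shape))
        planted = np.pi * truth.faz_radius**2
        assert abs(result.area - planted) / planted < 0.30
        # final mask stays inside the ROI disk
        roi_mask = define_roi(od, ffa.shape).disk_mask(ffa.shape)
        assert not (result.mask & ~roi_mask).any()

    def test_circular_mask_has_tiny_normalized_variance(self):
        rr, cc = np.mgrid[0:128, 0:128]
        mask = np.hypot(rr - 64, cc - 64) <= 30
        centroid, boundary, var = _boundary_and_variance(mask, 64)
        dists = np.hypot(boundary[:, 0] - centroid[0], boundary[:, 1] - centroid[1])
        assert var / dists.mean() ** 2 < 0.05

    def test_distance_variance_scales_quadratically(self):
        rr, cc = np.mgrid[0:256, 0:256]
        # same mildly elliptical shape at scale 1 and 2
        e1 = (((rr - 128) / 20.0) ** 2 + ((cc - 128) / 28.0) ** 2) <= 1
        e2 = (((rr - 128) / 40.0) ** 2 + ((cc - 128) / 56.0) ** 2) <= 1
        _, _, v1 = _boundary_and_variance(e1, 64)
        _, _, v2 = _boundary_and_variance(e2, 64)
        assert abs(v2 / v1 - 4.0) < 0.4  # s^2 within discretization tolerance

    def test_vessels_filling_roi_give_zero_area(self):
        vm = np.ones((128, 128), dtype=bool)
        ffa = np.full((128, 128), 0.5)
        result = segment_faz(vm, ffa, _roi((64.0, 64.0), 40.0))
        assert result.area == 0

    def test_larger_planted_faz_measures_larger(self):
        """Monotone on a 3-size phantom ladder."""
        import dataclasses

        from curvegrade.optic_disc import detect_od
        from curvegrade.phantom import grade_presets, render_pair
        from curvegrade.vessels import segment_vessels

        areas = []
        for radius in (25.0, 35.0, 45.0):
            spec = dataclasses.replace(grade_presets(1, seed=21), faz_radius=radius)
            ffa, _, _ = render_pair(spec)
            vm = segment_vessels(ffa)
            od = detect_od(ffa, vm)
            areas.append(segment_faz(vm, ffa, define_roi(od, ffa.shape)).area)
        assert areas[0] < areas[1] < areas[2]
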