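"""Nematic alignment score, ellipse fitting and the coordination curve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angioquant.coordination import (AlignmentCurve, NucleusRecord,
                                     aggregate_curves, coordination_curve,
                                     fit_ellipse, nuclei_from_image,
                                     pair_alignment, segment_nuclei)
from angioquant.io_formats import CalibratedImage
from angioquant.synthetic_data import NematicFieldSpec, gen_nematic_field


def make_record(i, x, y, theta, **kw):
    defaults = dict(major_axis=18.0, minor_axis=10.0, area=140.0)
    defaults.update(kw)
    return NucleusRecord(id=i, centroid_x=x, centroid_y=y, orientation=theta,
                         **defaults)


class TestPairAlignment:
    @pytest.mark.parametrize("delta_deg,expected", [
        (0.0, 1.0), (30.0, 0.5), (45.0, 0.0), (90.0, -1.0),
    ])
    def test_anchor_values(self, delta_deg, expected):
        got = pair_alignment(0.0, np.deg2rad(delta_deg))
        assert got == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_nematic_invariance(self, t1, t2):
        s = pair_alignment(t1, t2)
        assert s == pytest.approx(pair_alignment(t2, t1), abs=1e-9)
        assert s == pytest.approx(pair_alignment(t1 + np.pi, t2), abs=1e-9)
        assert s == pytest.approx(pair_alignment(t1, t2 + np.pi), abs=1e-9)
        assert -1.0 - 1e-12 <= s <= 1.0 + 1e-12

    @given(st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_self_and_perpendicular(self, t):
        assert pair_alignment(t, t) == pytest.approx(1.0)
        assert pair_alignment(t, t + np.pi / 2) == pytest.approx(-1.0)


def render_ellipse_image(theta, major_px=24, minor_px=10, size=64,
                         pixel_size=1.0):
    rows, cols = np.mgrid[0:size, 0:size]
    c = size / 2.0
    dx, dy = cols - c, rows - c
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    inside = (u / (major_px / 2)) ** 2 + (v / (minor_px / 2)) ** 2 <= 1
    img = np.where(inside, 1000.0, 100.0)
    return CalibratedImage(img, pixel_size)


class TestFitEllipse:
    @pytest.mark.parametrize("shape,expected_theta", [
        ((6, 20), 0.0),          # wide rectangle: major axis along x
        ((20, 6), np.pi / 2),    # tall rectangle: major axis along y
    ])
    def test_axis_aligned_rectangles(self, shape, expected_theta):
        img = np.zeros((32, 32))
        img[4:4 + shape[0], 4:4 + shape[1]] = 1000.0
        regions = segment_nuclei(CalibratedImage(img, 1.0), min_area=1,
                                 max_area=10000)
        assert len(regions) == 1
        rec = fit_ellipse(regions[0], pixel_size=1.0)
        assert rec.orientation == pytest.approx(expected_theta, abs=1e-6)

    def test_render_and_refit_recovers_truth(self):
        theta_true = 0.7
        image = render_ellipse_image(theta_true, major_px=24, minor_px=10)
        regions = segment_nuclei(image, min_area=1, max_area=10000)
        assert len(regions) == 1
        rec = fit_ellipse(regions[0], pixel_size=1.0)
        assert rec.orientation == pytest.approx(theta_true, abs=0.05)
        assert rec.major_axis == pytest.approx(24.0, rel=0.1)
        assert rec.minor_axis == pytest.approx(10.0, rel=0.1)

    def test_tiny_region_rejected(self):
        class FakeRegion:
            coords = np.array([[5, 5], [5, 6], [5, 7]])

        with pytest.raises(ValueError):
            fit_ellipse(FakeRegion(), pixel_size=1.0)


class TestSegmentNuclei:
    def test_blank_image_gives_empty_list(self):
        assert segment_nuclei(CalibratedImage(np.zeros((32, 32)), 1.0)) == []

    def test_three_disjoint_ellipses(self):
        spec = NematicFieldSpec(n_nuclei=3, field_size=200,
                                correlation_length=0, seed=4)
        _, image = gen_nematic_field(spec)
        regions = segment_nuclei(image, min_area=20, max_area=1000,
                                 expected_minor_axis=10)
        assert len(regions) == 3

    def test_border_touching_nucleus_excluded(self):
        spec = NematicFieldSpec(n_nuclei=3, field_size=200,
                                correlation_length=0, seed=4)
        _, image = gen_nematic_field(spec)
        # Paint a fourth ellipse half off the left border.
        img = image.pixels.copy()
        rows, cols = np.mgrid[0:img.shape[0], 0:img.shape[1]]
        inside = ((cols - 0) / 9.0) ** 2 + ((rows - 100) / 5.0) ** 2 <= 1
        img[inside] = 1000.0
        regions = segment_nuclei(CalibratedImage(img, 1.0), min_area=20,
                                 max_area=1000, expected_minor_axis=10)
        assert len(regions) == 3

    def test_synthetic_field_recovery(self):
        spec = NematicFieldSpec(n_nuclei=200, field_size=800,
                                correlation_length=100, seed=11)
        truth, image = gen_nematic_field(spec)
        records = nuclei_from_image(image, min_area=20, max_area=1000,
                                    expected_minor_axis=spec.minor_axis)
        assert len(records) >= 190
        truth_xy = np.array([[r.centroid_x, r.centroid_y] for r in truth])
        for rec in records:
            d = np.hypot(truth_xy[:, 0] - rec.centroid_x,
                         truth_xy[:, 1] - rec.centroid_y)
            assert d.min() < 2.0  # um


class TestCoordinationCurve:
    def test_needs_two_records(self):
        with pytest.raises(ValueError):
            coordination_curve([make_record(0, 0, 0, 0.3)])

    def test_identical_orientations_score_one_everywhere(self):
        rng = np.random.default_rng(3)
        records = [make_record(i, *rng.uniform(0, 500, 2), 0.8)
                   for i in range(100)]
        curve = coordination_curve(records, bin_width=25, max_distance=500)
        occupied = curve.pair_count > 0
        assert occupied.any()
        np.testing.assert_allclose(curve.mean_alignment[occupied], 1.0,
                                   atol=1e-12)

    def test_uniform_orientations_score_near_zero(self):
        rng = np.random.default_rng(5)
        n = 1500
        records = [make_record(i, *rng.uniform(0, 1000, 2),
                               rng.uniform(0, np.pi)) for i in range(n)]
        curve = coordination_curve(records, bin_width=50, max_distance=1000)
        big = curve.pair_count >= 10000
        assert big.any()
        assert np.all(np.abs(curve.mean_alignment[big]) < 0.05)

    def test_empty_bins_are_nan_not_zero(self):
        records = [make_record(0, 0, 0, 0.1), make_record(1, 10, 0, 0.1)]
        curve = coordination_curve(records, bin_width=5, max_distance=100)
        assert curve.pair_count[2] == 1
        assert np.isnan(curve.mean_alignment[0])

    def test_pair_at_max_distance_excluded(self):
        records = [make_record(0, 0, 0, 0.1), make_record(1, 100, 0, 0.1)]
        curve = coordination_curve(records, bin_width=25, max_distance=100)
        assert curve.pair_count.sum() == 0

    def test_permutation_invariance_bit_identical(self):
        rng = np.random.default_rng(8)
        records = [make_record(i, *rng.uniform(0, 300, 2),
                               rng.uniform(0, np.pi)) for i in range(60)]
        c1 = coordination_curve(records, 25, 400)
        shuffled = list(records)
        rng.shuffle(shuffled)
        c2 = coordination_curve(shuffled, 25, 400)
        np.testing.assert_array_equal(c1.pair_count, c2.pair_count)
        np.testing.assert_array_equal(c1.mean_alignment, c2.mean_alignment)


class TestAggregateCurves:
    def edges(self):
        return np.array([0.0, 25.0, 50.0])

    def test_single_curve_is_identity(self):
        c = AlignmentCurve(self.edges(), [0.5, 0.2], [10, 20], 7)
        agg = aggregate_curves([c])
        np.testing.assert_allclose(agg.mean_alignment, c.mean_alignment)
        np.testing.assert_array_equal(agg.pair_count, c.pair_count)

    def test_opposite_curves_cancel(self):
        c1 = AlignmentCurve(self.edges(), [0.4, -0.6], [10, 20], 5)
        c2 = AlignmentCurve(self.edges(), [-0.4, 0.6], [10, 20], 5)
        agg = aggregate_curves([c1, c2])
        np.testing.assert_allclose(agg.mean_alignment, 0.0, atol=1e-12)

    def test_pair_count_weighting(self):
        c1 = AlignmentCurve(self.edges(), [1.0, np.nan], [10, 0], 5)
        c2 = AlignmentCurve(self.edges(), [0.0, np.nan], [30, 0], 8)
        agg = aggregate_curves([c1, c2])
        assert agg.mean_alignment[0] == pytest.approx(0.25)
        assert agg.pair_count[0] == 40
        assert np.isnan(agg.mean_alignment[1])

    def test_mismatched_bins_rejected(self):
        c1 = AlignmentCurve(self.edges(), [0.1, 0.1], [1, 1], 2)
        c2 = AlignmentCurve(np.array([0.0, 10.0, 20.0]), [0.1, 0.1], [1, 1], 2)
        with pytest.raises(ValueError):
            aggregate_curves([c1, c2])
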