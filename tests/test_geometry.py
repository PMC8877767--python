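"""Pinhole conversions and the radius-corrected size equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from vegsize.errors import (
    DegenerateGeometryError,
    IncompleteDetectionError,
    InvalidDepthError,
    InvalidInputError,
)
from vegsize.geometry import (
    CameraIntrinsics,
    KeypointSet,
    PixelPoint,
    active_sensor_size,
    estimate_diameter,
    estimate_length,
    measure,
    pixel_distance,
    pixel_to_sensor,
    sensor_to_world,
)
from vegsize.synth import (
    STANDARD_MODELS,
    VegetableModel,
    center_surface_depth,
    ground_truth_keypoints,
)


class TestPixelDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 0), (3, 4), 5.0),
            ((10, 7), (10, 7), 0.0),
            ((0, 0), (1, 1), math.sqrt(2)),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert pixel_distance(PixelPoint(*a), PixelPoint(*b)) == pytest.approx(expected)

    def test_symmetric(self):
        a, b = PixelPoint(3.2, -1.5), PixelPoint(10.0, 8.25)
        assert pixel_distance(a, b) == pixel_distance(b, a)

    @pytest.mark.parametrize("bad", [(float("nan"), 0), (float("inf"), 1)])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            pixel_distance(PixelPoint(*bad), PixelPoint(0, 0))


class TestSensorConversions:
    def test_full_height_maps_to_sensor_height(self, cam):
        # 480 rows span the full 1.55 mm sensor height
        assert pixel_to_sensor(480, cam) == pytest.approx(1.55)

    def test_linear(self, cam):
        assert pixel_to_sensor(0, cam) == 0.0
        assert pixel_to_sensor(240, cam) == pytest.approx(0.775)

    def test_negative_rejected(self, cam):
        with pytest.raises(InvalidInputError):
            pixel_to_sensor(-1.0, cam)

    def test_active_sensor_size_default(self, cam):
        w, h = active_sensor_size(cam)
        assert round(w, 2) == 2.07  # the 640x480 crop of the 2.73x1.55 die
        assert h == pytest.approx(1.55)

    def test_active_square_crop(self):
        c = CameraIntrinsics(1.88, 2.73, 1.55, 480, 480)
        w, h = active_sensor_size(c)
        assert w == pytest.approx(h)

    def test_active_720p(self):
        c = CameraIntrinsics(1.88, 2.76, 1.55, 1280, 720)
        w, h = active_sensor_size(c)
        assert w == pytest.approx(1.55 / 720 * 1280)
        assert h == pytest.approx(1.55)


class TestSensorToWorld:
    def test_unit_magnification_plane(self, cam):
        assert sensor_to_world(0.4, cam.focal_length_mm, cam) == pytest.approx(0.4)

    def test_zero(self, cam):
        assert sensor_to_world(0.0, 600, cam) == 0.0

    def test_similar_triangles(self, cam):
        assert sensor_to_world(0.25, 600, cam) == pytest.approx(0.25 * 600 / 1.88)

    def test_invalid_depth(self, cam):
        with pytest.raises(InvalidDepthError):
            sensor_to_world(0.25, 0.0, cam)


class TestRadiusCorrectedEquations:
    def test_zero_extent(self, cam):
        assert estimate_diameter(0.0, 600, cam) == 0.0
        assert estimate_length(0.0, 0.0, 600, cam) == 0.0

    def test_closed_form(self, cam):
        # d*Ds/(f - Ds/2) with f=1.88, d=600, Ds=0.25
        assert estimate_diameter(0.25, 600, cam) == pytest.approx(150 / 1.755)

    def test_agrees_with_numeric_solution_of_implicit_form(self, cam):
        # independent oracle: solve D/Ds = (d + D/2)/f for D numerically
        f, d, Ds = cam.focal_length_mm, 600.0, 0.25
        oracle = brentq(lambda D: D / Ds - (d + D / 2) / f, 0, 1e5, xtol=1e-10)
        assert estimate_diameter(Ds, d, cam) == pytest.approx(oracle, rel=1e-9)

    def test_length_equals_chained_form(self, cam):
        d, Ds, Ls = 600.0, 0.25, 0.60
        D = estimate_diameter(Ds, d, cam)
        expected = Ls * (d + D / 2) / cam.focal_length_mm
        assert estimate_length(Ls, Ds, d, cam) == pytest.approx(expected, rel=1e-9)
        # same formula, same inputs: Ls = Ds gives L = D
        assert estimate_length(Ds, Ds, d, cam) == pytest.approx(D, rel=1e-12)

    def test_correction_exceeds_flat_model(self, cam):
        for Ds in (0.01, 0.2, 1.0):
            assert estimate_diameter(Ds, 500, cam) >= sensor_to_world(Ds, 500, cam)

    def test_degenerate_subtense(self, cam):
        with pytest.raises(DegenerateGeometryError):
            estimate_diameter(2 * cam.focal_length_mm, 600, cam)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        f=st.floats(0.5, 50),
        d=st.floats(100, 5000),
        frac=st.floats(1e-6, 0.9),
    )
    def test_implicit_equation_satisfied(self, f, d, frac):
        # the returned D satisfies D/Ds = (d + D/2)/f to 1e-9 relative
        c = CameraIntrinsics(f, 2.73, 1.55, 640, 480)
        Ds = frac * 2 * f
        D = estimate_diameter(Ds, d, c)
        if D > 0:
            assert D / Ds == pytest.approx((d + D / 2) / f, rel=1e-9)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        d=st.floats(310, 3000),
        Ds=st.floats(1e-6, 1.0),
        Ls=st.floats(0, 1.2),
    )
    def test_length_consistency(self, cam, d, Ds, Ls):
        D = estimate_diameter(Ds, d, cam)
        L = estimate_length(Ls, Ds, d, cam)
        assert L == pytest.approx(Ls * (d + D / 2) / cam.focal_length_mm, rel=1e-9, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(ls=st.floats(0, 1.5), k=st.floats(0.01, 100))
    def test_degree_one_homogeneity(self, cam, ls, k):
        assert pixel_to_sensor(k * ls, cam) == pytest.approx(k * pixel_to_sensor(ls, cam))
        assert sensor_to_world(k * ls, 600, cam) == pytest.approx(
            k * sensor_to_world(ls, 600, cam)
        )

    def test_limit_agreement_with_flat_model(self, cam):
        # relative gap between corrected and flat estimates is bounded by
        # (Ds/2f) / (1 - Ds/2f); it vanishes as Ds/f -> 0
        d = 800.0
        for Ds in (1e-6, 1e-4, 1e-2, 0.2):
            flat = sensor_to_world(Ds, d, cam)
            corr = estimate_diameter(Ds, d, cam)
            x = Ds / (2 * cam.focal_length_mm)
            assert 0 <= (corr - flat) / corr <= x / (1 - x) + 1e-12


def _kp(left, right, top, bottom, center=(50, 50)):
    return KeypointSet(
        peduncle=PixelPoint(0, 0),
        top=PixelPoint(*top),
        left=PixelPoint(*left),
        bottom=PixelPoint(*bottom),
        right=PixelPoint(*right),
        center=PixelPoint(*center),
    )


class TestMeasure:
    def test_degenerate_object(self, cam):
        kp = _kp((50, 50), (50, 50), (50, 50), (50, 50))
        est = measure(kp, 600, cam)
        assert est.diameter_mm == 0.0
        assert est.length_mm == 0.0

    def test_swapped_left_right_same_diameter(self, cam):
        a = _kp((40, 50), (60, 50), (50, 30), (50, 70))
        b = _kp((60, 50), (40, 50), (50, 30), (50, 70))
        assert not b.is_orientation_consistent()
        assert measure(a, 600, cam).diameter_mm == measure(b, 600, cam).diameter_mm

    def test_missing_keypoint_rejected(self, cam):
        kp = _kp((40, 50), (60, 50), (50, 30), (50, 70))
        kp.visibility["left"] = 0
        with pytest.raises(IncompleteDetectionError):
            measure(kp, 600, cam)

    def test_invalid_depth_rejected(self, cam):
        kp = _kp((40, 50), (60, 50), (50, 30), (50, 70))
        with pytest.raises(InvalidDepthError):
            measure(kp, 0.0, cam)

    def test_intermediates_recorded(self, cam):
        kp = _kp((40, 50), (60, 50), (50, 30), (50, 70))
        est = measure(kp, 600, cam)
        assert est.sensor_diameter_mm == pytest.approx(pixel_to_sensor(20, cam))
        assert est.sensor_length_mm == pytest.approx(pixel_to_sensor(40, cam))
        assert est.depth_used_mm == 600

    @pytest.mark.parametrize("depth_mm", [400.0, 600.0, 800.0, 1000.0])
    def test_roundtrip_recovers_standard_models(self, cam, depth_mm):
        # synthetic ground truth is the oracle: exact keypoints and exact
        # centre-surface depth must recover the catalogued sizes
        for name, (cls, D, L) in STANDARD_MODELS.items():
            m = VegetableModel.standard(name, position=(5.0, -8.0, depth_mm), axis_angle_deg=17.0)
            est = measure(ground_truth_keypoints(m, cam), center_surface_depth(m), cam)
            assert est.diameter_mm == pytest.approx(D, rel=5e-3)
            assert est.length_mm == pytest.approx(L, rel=5e-3)


class TestIntrinsics:
    def test_positive_fields_enforced(self):
        with pytest.raises(InvalidInputError):
            CameraIntrinsics(0.0, 2.73, 1.55, 640, 480)

    def test_crop_must_fit_die(self):
        # 1000 columns at the 1.55/480 pitch would exceed the 2.73 mm die
        with pytest.raises(InvalidInputError):
            CameraIntrinsics(1.88, 2.73, 1.55, 1000, 480)

    def test_yaml_round_trip(self, cam, tmp_path):
        import yaml

        p = tmp_path / "intrinsics.yaml"
        p.write_text(yaml.safe_dump(cam.to_dict()))
        assert CameraIntrinsics.from_file(p) == cam

    def test_focal_px(self, cam):
        assert cam.focal_px == pytest.approx(1.88 / (1.55 / 480))
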