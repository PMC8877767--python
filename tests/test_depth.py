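"""Depth alignment, filtering, hole repair and lookup."""

import numpy as np
import pytest

from vegsize.depth import (
    DepthMap,
    PinholeProjection,
    RigidTransform,
    align_depth_to_color,
    deproject,
    hole_fill,
    project,
    query_depth,
    spatial_filter,
)
from vegsize.errors import (
    BehindCameraError,
    BoundsError,
    InvalidDepthError,
    InvalidInputError,
)
from vegsize.geometry import PixelPoint


@pytest.fixture()
def proj():
    return PinholeProjection(fx=400.0, fy=400.0, cx=320.0, cy=240.0)


class TestProjection:
    def test_principal_ray(self, proj):
        assert np.allclose(deproject(PixelPoint(320, 240), 500, proj), [0, 0, 500])

    def test_unit_slope_ray(self, proj):
        P = deproject(PixelPoint(320 + 400, 240), 300, proj)
        assert np.allclose(P, [300, 0, 300])
        assert project([300, 0, 300], proj) == pytest.approx((720, 240))

    def test_projective_invariance(self, proj):
        p1 = project([30, -40, 500], proj)
        p2 = project([90, -120, 1500], proj)
        assert p1 == pytest.approx(p2)

    def test_mutual_inverse(self, proj, rng):
        for _ in range(50):
            p = PixelPoint(rng.uniform(0, 639), rng.uniform(0, 479))
            d = rng.uniform(100, 4000)
            q = project(deproject(p, d, proj), proj)
            assert q.x == pytest.approx(p.x, abs=1e-9)
            assert q.y == pytest.approx(p.y, abs=1e-9)

    def test_errors(self, proj):
        with pytest.raises(InvalidDepthError):
            deproject(PixelPoint(1, 1), 0, proj)
        with pytest.raises(BehindCameraError):
            project([0, 0, -5], proj)


class TestAlign:
    def test_identity_transform_is_identity(self, proj, rng):
        grid = rng.uniform(400, 800, size=(40, 60))
        grid[rng.random((40, 60)) < 0.2] = 0.0
        out = align_depth_to_color(DepthMap(grid), proj, proj, RigidTransform.identity())
        valid = grid > 0
        assert np.allclose(out.data[valid], grid[valid])

    def test_pure_z_translation_shifts_values(self, proj):
        grid = np.full((40, 60), 600.0)
        T = RigidTransform(np.eye(3), [0.0, 0.0, 25.0])
        out = align_depth_to_color(DepthMap(grid), proj, proj, T)
        vals = out.data[out.data > 0]
        assert vals.size > 0
        assert np.allclose(vals, 625.0)

    def test_two_camera_render_oracle(self):
        # a second camera renders the same scene directly; warping the depth
        # frame into the colour frame must agree almost everywhere
        from vegsize.geometry import INTRINSICS_PROFILES
        from vegsize.synth import SceneSpec, VegetableModel, render, render_depth_frame

        cam = INTRINSICS_PROFILES["d415-vga"]
        cproj = PinholeProjection.from_intrinsics(cam)
        T = RigidTransform(np.eye(3), [25.0, 0.0, 0.0])  # stereo-like baseline
        spec = SceneSpec(
            objects=[VegetableModel("tomato", 84.36, 65.17, position=(0, 0, 600))],
            depth_camera=(cproj, T),
            n_leaves=0,
            n_shadow_blobs=0,
            seed=1,
        )
        direct = render(spec).depth.data
        aligned = align_depth_to_color(render_depth_frame(spec), cproj, cproj, T).data
        ok = 0
        total = 0
        H, W = direct.shape
        ys, xs = np.nonzero(aligned > 0)
        for y, x in zip(ys[::7], xs[::7]):  # subsample for speed
            total += 1
            nb = direct[max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2]
            if np.min(np.abs(nb - aligned[y, x])) < 5.0:  # 1 px warping tolerance
                ok += 1
        assert ok / total > 0.95


def _filter_oracle(grid, alpha, delta, iterations):
    """Literal per-pixel re-implementation of the directional recursion."""
    g = grid.astype(float).copy()

    def sweep(a):
        for i in range(a.shape[0]):
            for j in range(1, a.shape[1]):
                cur, prev = a[i, j], a[i, j - 1]
                if cur > 0 and prev > 0 and abs(prev - cur) < delta:
                    a[i, j] = alpha * cur + (1 - alpha) * prev

    for _ in range(iterations):
        sweep(g)
        sweep(g[:, ::-1])
        sweep(g.T)
        sweep(g.T[:, ::-1])
    return g


class TestSpatialFilter:
    def test_constant_map_unchanged(self):
        g = np.full((20, 30), 700.0)
        out = spatial_filter(DepthMap(g))
        assert np.array_equal(out.data, g)

    def test_step_above_delta_preserved(self):
        g = np.full((10, 20), 600.0)
        g[:, 10:] = 700.0  # 100 mm step > delta=20
        out = spatial_filter(DepthMap(g), alpha=0.5, delta=20.0, iterations=2)
        assert np.array_equal(out.data, g)

    def test_spike_reduced_plane_preserved(self):
        g = np.full((15, 15), 600.0)
        g[7, 7] = 605.0
        out = spatial_filter(DepthMap(g), alpha=0.5, delta=20.0, iterations=2)
        assert out.data[7, 7] < 605.0
        assert abs(out.data.mean() - 600.0 - 5.0 / 225) < 0.1

    def test_matches_bruteforce_oracle(self, rng):
        g = rng.uniform(500, 520, size=(12, 17))
        g[rng.random((12, 17)) < 0.15] = 0.0
        g[3, :] += 100.0  # an edge
        out = spatial_filter(DepthMap(g), alpha=0.4, delta=15.0, iterations=2)
        assert np.allclose(out.data, _filter_oracle(g, 0.4, 15.0, 2), atol=1e-10)

    def test_never_creates_or_destroys_holes(self, rng):
        g = rng.uniform(400, 900, size=(25, 25))
        g[rng.random((25, 25)) < 0.3] = 0.0
        out = spatial_filter(DepthMap(g))
        assert np.array_equal(out.data == 0, g == 0)

    def test_parameter_validation(self):
        d = DepthMap(np.ones((4, 4)))
        with pytest.raises(InvalidInputError):
            spatial_filter(d, alpha=0.0)
        with pytest.raises(InvalidInputError):
            spatial_filter(d, delta=-1)
        with pytest.raises(InvalidInputError):
            spatial_filter(d, iterations=0)


def _right_fill_oracle(row):
    out = list(row)
    for i, v in enumerate(out):
        if v == 0:
            for w in out[i + 1 :]:
                if w > 0:
                    out[i] = w
                    break
    return out


class TestHoleFill:
    def test_row_example(self):
        out = hole_fill(DepthMap(np.array([[600.0, 0.0, 0.0, 610.0]])))
        assert out.data.tolist() == [[600.0, 610.0, 610.0, 610.0]]

    def test_no_zeros_identity(self, rng):
        g = rng.uniform(300, 900, size=(10, 12))
        assert np.array_equal(hole_fill(DepthMap(g)).data, g)

    def test_all_zero_warns_and_unchanged(self):
        with pytest.warns(UserWarning):
            out = hole_fill(DepthMap(np.zeros((5, 5))))
        assert np.array_equal(out.data, np.zeros((5, 5)))
        assert out.warning is not None

    def test_no_holes_remain(self, rng):
        for _ in range(20):
            g = rng.uniform(300, 900, size=(8, 11))
            g[rng.random((8, 11)) < 0.6] = 0.0
            if not (g > 0).any():
                continue
            assert hole_fill(DepthMap(g)).hole_count == 0

    def test_matches_right_fill_oracle(self, rng):
        g = rng.uniform(300, 900, size=(6, 9))
        g[rng.random((6, 9)) < 0.4] = 0.0
        g[:, -1] = 500.0  # every hole has a valid value to its right
        out = hole_fill(DepthMap(g))
        for i in range(g.shape[0]):
            assert out.data[i].tolist() == _right_fill_oracle(g[i])


class TestQueryDepth:
    def test_integer_cell(self):
        g = np.arange(12, dtype=float).reshape(3, 4) + 1
        assert query_depth(DepthMap(g), PixelPoint(2, 1)) == g[1, 2]

    def test_nearest_cell_rule(self):
        g = np.zeros((30, 30))
        g[21, 10] = 777.0
        assert query_depth(DepthMap(g), PixelPoint(10.4, 20.6)) == 777.0

    def test_out_of_bounds(self):
        with pytest.raises(BoundsError):
            query_depth(DepthMap(np.ones((4, 4))), PixelPoint(10, 1))

    def test_always_positive_after_hole_fill(self, rng):
        for _ in range(10):
            g = rng.uniform(300, 900, size=(9, 9))
            g[rng.random((9, 9)) < 0.5] = 0.0
            if not (g > 0).any():
                continue
            filled = hole_fill(DepthMap(g))
            p = PixelPoint(rng.uniform(0, 8), rng.uniform(0, 8))
            assert query_depth(filled, p) > 0


class TestDepthMapIO:
    def test_png_round_trip(self, tmp_path, rng):
        g = np.rint(rng.uniform(0, 3000, size=(20, 20)))
        d = DepthMap(g)
        d.to_png(tmp_path / "d.png")
        assert np.array_equal(DepthMap.from_png(tmp_path / "d.png").data, g)

    def test_npy_round_trip(self, tmp_path, rng):
        g = rng.uniform(0, 3000, size=(7, 5))
        DepthMap(g).to_npy(tmp_path / "d.npy")
        assert np.array_equal(DepthMap.from_npy(tmp_path / "d.npy").data, g)

    def test_validation(self):
        with pytest.raises(InvalidInputError):
            DepthMap(np.array([[1.0, -2.0]]))
        with pytest.raises(InvalidInputError):
            DepthMap(np.array([[np.nan, 1.0]]))


class TestRigidTransform:
    def test_rejects_non_orthonormal(self):
        with pytest.raises(InvalidInputError):
            RigidTransform(np.eye(3) * 2, np.zeros(3))

    def test_rejects_reflection(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(InvalidInputError):
            RigidTransform(R, np.zeros(3))
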