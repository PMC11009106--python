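"""Thin-plate-spline and rigid alignment: analytic correctness."""

import numpy as np
import pytest

from landreg.geometry import (
    RigidTransform,
    area_change,
    load_transform,
    rigid_fit,
    rigid_transform_points,
    save_transform,
    tps_fit,
    tps_kernel,
    tps_transform_points,
    tps_warp_image,
)


def _dense_tps_solve(source, target, lam=0.0):
    """Independent dense linear-solve oracle for the augmented TPS system.

    Builds the full (K+3) x (K+3) matrix with the radial kernel
    r^2 log2 r directly in the given coordinates and solves per axis.
    """
    src = np.asarray(source, float)
    k = src.shape[0]
    d = np.linalg.norm(src[:, None] - src[None, :], axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        kern = np.where(d > 0, d**2 * np.log2(np.where(d > 0, d, 1.0)), 0.0)
    kern += lam * np.eye(k)
    p = np.hstack([np.ones((k, 1)), src])
    l = np.zeros((k + 3, k + 3))
    l[:k, :k] = kern
    l[:k, k:] = p
    l[k:, :k] = p.T
    rhs = np.vstack([np.asarray(target, float), np.zeros((3, 2))])
    return np.linalg.solve(l, rhs)


def _eval_tps_formula(coef, source, points):
    """Term-by-term evaluation of the printed mapping function."""
    src = np.asarray(source, float)
    k = src.shape[0]
    w, a = coef[:k], coef[k:]
    out = np.empty((len(points), 2))
    for i, (x, y) in enumerate(points):
        for axis in range(2):
            val = a[0, axis] + a[1, axis] * x + a[2, axis] * y
            for j in range(k):
                r = np.hypot(src[j, 0] - x, src[j, 1] - y)
                val += w[j, axis] * (r**2 * np.log2(r) if r > 0 else 0.0)
            out[i, axis] = val
    return out


class TestKernel:
    @pytest.mark.parametrize("r,expected", [(1.0, 0.0), (0.0, 0.0), (2.0, 4.0)])
    def test_values(self, r, expected):
        assert tps_kernel(r) == pytest.approx(expected, abs=1e-12)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            tps_kernel(-0.5)

    def test_vectorized(self):
        out = tps_kernel(np.array([0.0, 1.0, 2.0]))
        assert np.allclose(out, [0.0, 0.0, 4.0])


class TestTPSFit:
    def test_identity_fit(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        m = tps_fit(pts, pts, lam=0.0)
        assert np.abs(m.weights_x).max() < 1e-10
        assert np.abs(m.weights_y).max() < 1e-10
        out = tps_transform_points(m, pts)
        assert np.abs(out - pts).max() < 1e-9

    def test_affine_targets_have_zero_bending(self, rng):
        src = rng.uniform(0, 10, size=(6, 2))
        a = np.array([[1.2, 0.3], [-0.2, 0.9]])
        b = np.array([2.0, -1.0])
        tgt = src @ a.T + b
        m = tps_fit(src, tgt, lam=0.0)
        assert np.abs(m.weights_x).max() < 1e-8
        assert np.abs(m.weights_y).max() < 1e-8
        # the affine is reproduced everywhere, not just at controls
        probe = rng.uniform(0, 10, size=(20, 2))
        assert np.abs(tps_transform_points(m, probe) - (probe @ a.T + b)).max() < 1e-7

    def test_interpolation_and_oracle_agreement(self):
        gen = np.random.default_rng(7)
        src = gen.uniform(-1, 1, size=(8, 2))
        tgt = src + gen.normal(scale=0.2, size=(8, 2))
        m = tps_fit(src, tgt, lam=0.0, bounds=(-1, 1, -1, 1))
        # interpolation exactness at lambda = 0
        assert np.abs(tps_transform_points(m, src) - tgt).max() < 1e-6
        # coefficients agree with an independent dense solve (same bounds
        # normalization applied to the oracle inputs)
        coef = _dense_tps_solve(src, tgt)
        assert np.abs(np.vstack([m.weights, m.affine]) - coef).max() < 1e-8

    def test_side_conditions(self, rng):
        src = rng.uniform(0, 50, size=(10, 2))
        tgt = src + rng.normal(scale=3.0, size=(10, 2))
        m = tps_fit(src, tgt, lam=0.0)
        cp = np.asarray(m.control_points)
        for w in (m.weights_x, m.weights_y):
            assert abs(w.sum()) < 1e-8
            assert abs((w * cp[:, 0]).sum()) < 1e-8
            assert abs((w * cp[:, 1]).sum()) < 1e-8

    def test_collinear_points_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            tps_fit(src, src + 1.0, lam=0.0)

    def test_duplicate_points_named(self):
        src = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="duplicate"):
            tps_fit(src, src.copy(), lam=0.0)

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            tps_fit(np.zeros((4, 2)), np.zeros((5, 2)))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            tps_fit(np.zeros((2, 2)), np.zeros((2, 2)))


class TestTransformPoints:
    def test_formula_oracle(self, rng):
        src = rng.uniform(-1, 1, size=(7, 2))
        tgt = src + rng.normal(scale=0.15, size=(7, 2))
        m = tps_fit(src, tgt, lam=0.0, bounds=(-1, 1, -1, 1))
        probe = rng.uniform(-1, 1, size=(9, 2))
        got = tps_transform_points(m, probe)
        coef = np.vstack([m.weights, m.affine])
        want = _eval_tps_formula(coef, src, probe)
        assert np.abs(got - want).max() < 1e-10


class TestWarpImage:
    def test_identity_warp_is_exact(self, rng):
        img = rng.uniform(size=(16, 16, 3))
        pts = np.array([[2.0, 2.0], [13.0, 2.0], [2.0, 13.0], [13.0, 13.0]])
        m = tps_fit(pts, pts, lam=0.0)
        out = tps_warp_image(m, img)
        assert np.array_equal(out, img)

    def test_translation_moves_hot_pixel(self):
        img = np.zeros((24, 24))
        img[10, 8] = 1.0
        # backward model: output pixel q samples source at q + (+5, 0)
        # so content moves by (-5, 0): fit target->source translation
        pts = np.array([[2.0, 2.0], [20.0, 2.0], [2.0, 20.0], [20.0, 20.0]])
        m = tps_fit(pts, pts + [5.0, 0.0], lam=0.0)
        out = tps_warp_image(m, img)
        assert out[10, 3] == pytest.approx(1.0, abs=1e-9)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_per_pixel_oracle(self, rng):
        img = np.linspace(0, 1, 32 * 32).reshape(32, 32)
        src = rng.uniform(4, 27, size=(6, 2))
        tgt = src + rng.normal(scale=1.5, size=(6, 2))
        m = tps_fit(tgt, src, lam=0.0)
        out = tps_warp_image(m, img)
        # oracle: evaluate the scalar fields per pixel, then explicit
        # bilinear sampling with out-of-bounds taps contributing zero
        xs, ys = np.meshgrid(np.arange(32, dtype=float), np.arange(32, dtype=float))
        coords = tps_transform_points(m, np.stack([xs.ravel(), ys.ravel()], axis=1))

        def bilinear_zero(im, x, y):
            x0, y0 = int(np.floor(x)), int(np.floor(y))
            fx, fy = x - x0, y - y0
            val = 0.0
            for dy, wy in ((0, 1 - fy), (1, fy)):
                for dx, wx in ((0, 1 - fx), (1, fx)):
                    xi, yi = x0 + dx, y0 + dy
                    if 0 <= xi < im.shape[1] and 0 <= yi < im.shape[0]:
                        val += wx * wy * im[yi, xi]
            return val

        want = np.array([bilinear_zero(img, x, y) for x, y in coords]).reshape(32, 32)
        assert np.abs(out - want).max() < 1e-6

    def test_warp_point_composition(self, rng):
        """Warping an image then reading a pixel equals sampling the source
        at the point-transformed location (pixel-center agreement)."""
        img = rng.uniform(size=(20, 20))
        src = rng.uniform(3, 16, size=(5, 2))
        m = tps_fit(src, src + rng.normal(scale=1.0, size=(5, 2)), lam=0.0)
        out = tps_warp_image(m, img)
        centers = np.array([[4.0, 7.0], [11.0, 5.0], [9.0, 14.0]])
        mapped = tps_transform_points(m, centers)
        from scipy.ndimage import map_coordinates

        want = map_coordinates(
            img, [mapped[:, 1], mapped[:, 0]], order=1, mode="constant", cval=0.0
        )
        got = out[centers[:, 1].astype(int), centers[:, 0].astype(int)]
        assert np.abs(got - want).max() < 1e-9

    def test_empty_image_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        m = tps_fit(pts, pts)
        with pytest.raises(ValueError):
            tps_warp_image(m, np.zeros((0, 0)))


class TestRigid:
    def test_identity(self):
        pts = np.array([[0.0, 0.0], [2.0, 1.0], [1.0, 3.0]])
        t = rigid_fit(pts, pts)
        assert np.allclose(t.rotation, np.eye(2), atol=1e-12)
        assert np.allclose(t.translation, 0.0, atol=1e-12)
        assert t.scale == 1.0

    def test_exact_recovery(self):
        gen = np.random.default_rng(3)
        src = gen.uniform(-5, 5, size=(6, 2))
        th = np.deg2rad(30.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        tgt = src @ rot.T + [2.0, -1.0]
        t = rigid_fit(src, tgt)
        assert t.angle == pytest.approx(th, abs=1e-6)
        assert np.abs(t.translation - [2.0, -1.0]).max() < 1e-6
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-12)

    def test_scale_recovery(self):
        gen = np.random.default_rng(4)
        src = gen.uniform(-5, 5, size=(5, 2))
        tgt = 1.7 * src + [0.5, 0.5]
        t = rigid_fit(src, tgt, with_scale=True)
        assert t.scale == pytest.approx(1.7, abs=1e-9)

    def test_noisy_fit_matches_grid_search(self):
        gen = np.random.default_rng(5)
        src = gen.uniform(-3, 3, size=(8, 2))
        th = 0.3
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        tgt = src @ rot.T + [1.0, 0.5] + gen.normal(scale=0.1, size=(8, 2))
        t = rigid_fit(src, tgt)
        res = np.linalg.norm(rigid_transform_points(t, src) - tgt, axis=1)
        best = (res**2).sum()
        # brute-force grid over angle x translation
        angles = np.linspace(th - 0.1, th + 0.1, 81)
        shifts = np.linspace(-0.2, 0.2, 21)
        grid_best = np.inf
        for a in angles:
            r = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            base = src @ r.T
            for dx in shifts:
                for dy in shifts:
                    d = base + [1.0 + dx, 0.5 + dy] - tgt
                    grid_best = min(grid_best, (d**2).sum())
        assert best <= grid_best + 1e-9

    def test_optimality_against_random_transforms(self):
        gen = np.random.default_rng(6)
        src = gen.uniform(-3, 3, size=(10, 2))
        tgt = src + gen.normal(scale=0.5, size=(10, 2))
        t = rigid_fit(src, tgt)
        best = ((rigid_transform_points(t, src) - tgt) ** 2).sum()
        for _ in range(1000):
            a = gen.uniform(-np.pi, np.pi)
            r = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            tr = gen.uniform(-3, 3, size=2)
            cand = ((src @ r.T + tr - tgt) ** 2).sum()
            assert best <= cand + 1e-9

    def test_coincident_points_rejected(self):
        pts = np.zeros((4, 2))
        with pytest.raises(ValueError, match="coincide"):
            rigid_fit(pts, pts + 1.0)


class TestAreaChange:
    def test_identical_images(self, rng):
        img = rng.uniform(size=(8, 8, 3))
        assert area_change(img, img) == 0.0

    def test_doubling_clips_to_one(self):
        before = np.zeros((8, 8))
        before[:2, :2] = 1.0  # 4 px
        after = np.zeros((8, 8))
        after[:4, :4] = 1.0  # 16 px -> |16-4|/4 = 3 -> clipped
        assert area_change(before, after) == 1.0

    def test_hand_count(self):
        before = np.zeros((8, 8))
        before.ravel()[:20] = 1.0
        after = np.zeros((8, 8))
        after.ravel()[:15] = 1.0
        assert area_change(before, after) == pytest.approx(0.25)

    def test_empty_before_rejected(self):
        with pytest.raises(ValueError):
            area_change(np.zeros((4, 4)), np.ones((4, 4)))

    def test_range_property(self, rng):
        for _ in range(20):
            a = (rng.uniform(size=(10, 10)) > 0.5).astype(float)
            b = (rng.uniform(size=(10, 10)) > 0.5).astype(float)
            if (a >= 0.1).sum() == 0:
                continue
            da = area_change(a, b)
            assert 0.0 <= da <= 1.0


class TestSerialization:
    def test_tps_roundtrip(self, rng, tmp_path):
        src = rng.uniform(0, 10, size=(5, 2))
        m = tps_fit(src, src + rng.normal(size=(5, 2)), lam=1e-6)
        path = tmp_path / "tps.yaml"
        save_transform(path, m)
        m2 = load_transform(path)
        probe = rng.uniform(0, 10, size=(7, 2))
        assert np.allclose(
            tps_transform_points(m, probe), tps_transform_points(m2, probe), atol=1e-12
        )

    def test_rigid_roundtrip(self, tmp_path):
        t = RigidTransform(
            rotation=np.array([[0.0, -1.0], [1.0, 0.0]]), translation=[1.0, 2.0], scale=1.5
        )
        path = tmp_path / "rigid.yaml"
        save_transform(path, t)
        t2 = load_transform(path)
        assert np.allclose(t2.rotation, t.rotation)
        assert np.allclose(t2.translation, t.translation)
        assert t2.scale == 1.5
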