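"""Benchmark metrics: consistency, forward/backward, TRE/ATRE, kNN."""

import numpy as np
import pytest

from landreg.evaluation import (
    atre,
    backward_error,
    consistency_error,
    forward_error,
    knn_region_accuracy,
    register_to_reference,
    tre,
)
from landreg.geometry import tps_fit, tps_transform_points
from landreg.synthetic import SyntheticSpec, make_stack, make_tissue


def _affine(angle_deg=0.0, scale=1.0, shift=(0.0, 0.0), center=(31.5, 31.5)):
    th = np.deg2rad(angle_deg)
    rot = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    aff = np.eye(3)
    aff[:2, :2] = rot
    aff[:2, 2] = np.asarray(shift) + center - rot @ center
    return aff


class TestConsistency:
    def test_identity_affine_zero(self, tiny_detector, tissue_sections):
        d = consistency_error(tiny_detector, tissue_sections[0], np.eye(3))
        assert np.allclose(d, 0.0)

    def test_oracle_detector_is_equivariant(self, desk_spec):
        """A detector that reads the ground-truth landmark positions
        commutes with any affine by construction."""
        img, lms = make_tissue(desk_spec, np.random.default_rng(5))
        spec_map = {}

        def oracle(image):
            # identify the section by its affine-warped landmarks: here we
            # exploit that the ground truth transforms exactly
            key = round(float(np.asarray(image).sum()), 6)
            return spec_map.get(key, lms)

        rng = np.random.default_rng(0)
        for _ in range(5):
            aff = _affine(rng.uniform(-10, 10), rng.uniform(0.85, 0.95), rng.uniform(-2, 2, 2))
            from landreg.evaluation import _warp_affine_image
            from landreg.augment import apply_affine_to_points

            warped = _warp_affine_image(img, aff)
            spec_map[round(float(warped.sum()), 6)] = apply_affine_to_points(aff, lms)
            d = consistency_error(oracle, img, aff)
            assert np.abs(d).max() < 1e-9

    def test_constant_detector_translation(self, rng):
        img = rng.uniform(size=(32, 32, 3))
        fixed = np.array([[10.0, 10.0], [20.0, 15.0], [12.0, 25.0]])
        aff = np.eye(3)
        aff[:2, 2] = [6.0, 8.0]  # 10 px translation
        d = consistency_error(lambda im: fixed, img, aff)
        assert np.allclose(d, 10.0)


class TestForwardBackward:
    def test_identity_regression_zero(self, rng):
        pts = [rng.uniform(0, 64, size=(5, 2)) for _ in range(24)]
        assert forward_error(pts, pts) == pytest.approx(0.0, abs=1e-8)
        assert backward_error(pts, pts) == pytest.approx(0.0, abs=1e-8)

    def test_affine_relation_absorbed(self, rng):
        det = [rng.uniform(0, 64, size=(5, 2)) for _ in range(24)]
        a = np.array([[1.1, 0.2], [-0.1, 0.9]])
        ann = [d @ a.T + [3.0, -2.0] for d in det]
        assert forward_error(det, ann) == pytest.approx(0.0, abs=1e-7)
        assert backward_error(det, ann) == pytest.approx(0.0, abs=1e-7)

    def test_noisy_linear_matches_ols_theory(self):
        """Held-out error under y = x + noise stays within 3 SE of the
        closed-form expectation for an OLS residual on fresh data."""
        gen = np.random.default_rng(21)
        sigma = 0.5
        n, k = 400, 3
        det = [gen.uniform(0, 64, size=(k, 2)) for _ in range(n)]
        ann = [d + gen.normal(scale=sigma, size=d.shape) for d in det]
        err = forward_error(det, ann, seed=1)
        # per-point Euclidean error of a 2-D Gaussian residual:
        # E|N(0, s^2 I_2)| = s * sqrt(pi/2); held-out inflation ~ (1 + p/n)
        expected = sigma * np.sqrt(np.pi / 2)
        assert err == pytest.approx(expected, rel=0.1)

    def test_too_few_images_rejected(self, rng):
        with pytest.raises(ValueError):
            forward_error([rng.uniform(size=(4, 2))], [rng.uniform(size=(4, 2))])


class TestTre:
    def test_zero_on_identical(self, rng):
        pts = rng.uniform(size=(6, 2))
        assert tre(pts, pts) == 0.0

    def test_three_four_five(self):
        a = np.zeros((4, 2))
        b = np.tile([3.0, 4.0], (4, 1))
        assert tre(b, a) == pytest.approx(5.0)

    def test_hand_toy(self):
        pred = np.array([[1.0, 0.0], [2.0, 3.0]])
        act = np.array([[0.0, 0.0], [2.0, 2.0]])
        assert tre(pred, act) == pytest.approx(1.0)


class TestAtre:
    def test_exact_transforms_zero(self, rng):
        pts = [rng.uniform(0, 32, size=(4, 2)) for _ in range(4)]
        transforms = []
        for i in range(3):
            src, dst = pts[i], pts[i + 1]
            m = tps_fit(src, dst, lam=0.0)
            transforms.append(lambda p, m=m: tps_transform_points(m, p))
        assert atre(transforms, pts) == pytest.approx(0.0, abs=1e-5)

    def test_sum_convention(self):
        # 3 sections, per-section errors 1, 2, 0 under the sum convention
        pts = [np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2))]
        shift_1 = lambda p: p  # section 1 -> 2
        shift_2 = lambda p: p  # section 2 -> 3
        pts[0] = np.tile([1.0, 0.0], (2, 1))  # propagates with error 1
        pts[1] = np.tile([0.0, 2.0], (2, 1))  # error 2
        assert atre([shift_1, shift_2], pts) == pytest.approx(3.0)

    def test_matches_brute_force_chain(self):
        spec = SyntheticSpec(image_size=48, n_sections=5)
        st = make_stack(spec, np.random.default_rng(3))
        transforms = [
            (lambda p, i=i: st.pair_map(i, i + 1, p)) for i in range(4)
        ]
        got = atre(transforms, list(st.target_points))
        # brute force: propagate each section's points step by step
        want = 0.0
        for i in range(5):
            prop = st.target_points[i].copy()
            for j in range(i, 4):
                prop = st.pair_map(j, j + 1, prop)
            want += np.linalg.norm(prop - st.target_points[-1], axis=1).mean()
        assert got == pytest.approx(want, abs=1e-8)

    def test_transform_count_checked(self):
        with pytest.raises(ValueError):
            atre([lambda p: p], [np.zeros((2, 2))] * 3)


class TestKnn:
    def test_self_registration_k1(self, rng):
        pts = rng.uniform(size=(30, 2))
        labels = rng.integers(0, 3, size=30)
        assert knn_region_accuracy(pts, labels, pts, labels, k=1) == 1.0

    def test_shuffled_labels_near_chance(self):
        gen = np.random.default_rng(8)
        pts = gen.uniform(size=(2000, 2))
        labels = gen.integers(0, 2, size=2000)
        reg = gen.uniform(size=(2000, 2))
        true = gen.integers(0, 2, size=2000)
        acc = knn_region_accuracy(pts, labels, reg, true, k=5)
        assert acc == pytest.approx(0.5, abs=0.05)

    def test_hand_grid_majority(self):
        ref = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [5.0, 5.0]])
        ref_lab = np.array([0, 0, 1, 1])
        reg = np.array([[0.2, 0.2]])
        # 3 nearest: labels 0, 0, 1 -> majority 0
        assert knn_region_accuracy(ref, ref_lab, reg, [0], k=3) == 1.0
        assert knn_region_accuracy(ref, ref_lab, reg, [1], k=3) == 0.0

    def test_tie_breaks_to_smallest_label(self):
        ref = np.array([[0.0, 0.0], [1.0, 0.0]])
        ref_lab = np.array([1, 0])
        reg = np.array([[0.5, 0.0]])
        # one vote each -> smallest label (0) wins
        assert knn_region_accuracy(ref, ref_lab, reg, [0], k=2) == 1.0


class TestRegisterToReference:
    def test_reference_maps_to_itself(self, desk_spec):
        img, lms = make_tissue(desk_spec, np.random.default_rng(2))
        regs = register_to_reference([img], lambda im: lms, reference_index=0)
        assert np.abs(regs[0].image - img).max() < 1e-6
        assert np.abs(regs[0].transfer_points(lms) - lms).max() < 1e-6

    def test_ground_truth_round_trip(self, desk_spec):
        """With an oracle detector, a known deformation of the reference
        is recovered: point transfer reproduces ground truth < 0.5 px."""
        from landreg.synthetic import make_section_pair

        spec = SyntheticSpec(image_size=64, elastic_sigma=1.5)
        a, b, corr = make_section_pair(spec, np.random.default_rng(6), batch=False)
        _, lms_latent = make_tissue(spec, np.random.default_rng(6))
        lms_a = lms_latent
        lms_b = corr["map"](lms_latent)
        sections = [a, b]
        pts_by_id = [lms_a, lms_b]

        def oracle(image):
            for sec, pts in zip(sections, pts_by_id):
                if np.shares_memory(sec, image) or np.array_equal(sec, image):
                    return pts
            raise AssertionError("unknown section")

        regs = register_to_reference(sections, oracle, reference_index=0)
        probe = lms_b  # points in section B's frame
        transferred = regs[1].transfer_points(probe)
        assert np.abs(transferred - lms_a).max() < 0.5

    def test_three_landmarks_affine_only(self, desk_spec, rng):
        img, _ = make_tissue(desk_spec, np.random.default_rng(9))
        lms = np.array([[10.0, 10.0], [50.0, 12.0], [30.0, 50.0]])
        regs = register_to_reference([img, img], lambda im: lms, reference_index=0)
        assert len(regs) == 2
        assert np.abs(regs[1].transfer_points(lms) - lms).max() < 1e-6
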