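"""Intensity-flow equations, aggregation, directionality and the LK baseline."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi

import mitoflow as mf
from mitoflow.motion import MotionField, motion_activity


def gradient_oracle(d_rescaled):
    """Straight-loop central differences (one-sided at borders), y up."""
    H, W = d_rescaled.shape
    u = np.zeros((H, W))
    v = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            if 0 < c < W - 1:
                u[r, c] = (d_rescaled[r, c + 1] - d_rescaled[r, c - 1]) / 2
            elif c == 0:
                u[r, c] = d_rescaled[r, 1] - d_rescaled[r, 0]
            else:
                u[r, c] = d_rescaled[r, c] - d_rescaled[r, c - 1]
            if 0 < r < H - 1:
                gy = (d_rescaled[r + 1, c] - d_rescaled[r - 1, c]) / 2
            elif r == 0:
                gy = d_rescaled[1, c] - d_rescaled[0, c]
            else:
                gy = d_rescaled[r, c] - d_rescaled[r - 1, c]
            v[r, c] = -gy
    return u, v


class TestDifferenceImage:
    def test_identical_frames_rescale_to_half(self, rng):
        f = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        diff = mf.difference_image(f, f, 8)
        assert np.all(diff.d == 0)
        assert np.all(diff.d_rescaled == 0.5)

    def test_endpoints_of_the_rescale(self):
        a = np.array([[0, 255]], np.uint8)
        b = np.array([[255, 0]], np.uint8)
        diff = mf.difference_image(a, b, 8)
        assert diff.d_rescaled[0, 0] == 1.0
        assert diff.d_rescaled[0, 1] == 0.0

    def test_printed_formula_arithmetic(self):
        diff = mf.difference_image(np.array([[200]], np.uint8), np.array([[50]], np.uint8), 8)
        assert diff.d[0, 0] == -150
        assert diff.d_rescaled[0, 0] == pytest.approx((-150 + 255) / 510)

    def test_16_bit_rescale_uses_full_range(self):
        a = np.array([[0]], np.uint16)
        b = np.array([[65535]], np.uint16)
        diff = mf.difference_image(a, b, 16)
        assert diff.d_rescaled[0, 0] == 1.0


class TestRoi:
    def test_idempotent_union(self, rng):
        s = rng.random((12, 12)) < 0.4
        np.testing.assert_array_equal(mf.motion_roi(s, s), s)

    def test_disjoint_union_area(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:4] = True   # 40
        b[4:] = True   # 60
        assert mf.motion_roi(a, b).sum() == 100

    def test_union_contains_both_masks(self, rng):
        for _ in range(50):
            a = rng.random((8, 8)) < 0.3
            b = rng.random((8, 8)) < 0.3
            roi = mf.motion_roi(a, b)
            assert np.all(roi[a]) and np.all(roi[b])


class TestGradientField:
    def test_constant_difference_gives_zero_field(self):
        diff = mf.difference_image(np.full((8, 8), 10, np.uint8), np.full((8, 8), 10, np.uint8))
        fld = mf.gradient_field(diff, np.ones((8, 8), bool))
        assert np.all(fld.u == 0) and np.all(fld.v == 0)

    def test_linear_ramp_interior_gradient(self):
        d_resc = 0.5 + 0.01 * np.arange(16)[None, :] * np.ones((16, 1))
        diff = mf.DifferenceImage(d=d_resc * 510 - 255, d_rescaled=d_resc)
        fld = mf.gradient_field(diff, np.ones((16, 16), bool))
        assert fld.u[5, 5] == pytest.approx(0.01)
        assert fld.v[5, 5] == pytest.approx(0.0, abs=1e-15)

    def test_matches_straight_loop_oracle(self, rng):
        for _ in range(20):
            f0 = rng.integers(0, 256, (10, 12)).astype(np.uint8)
            f1 = rng.integers(0, 256, (10, 12)).astype(np.uint8)
            roi = rng.random((10, 12)) < 0.7
            diff = mf.difference_image(f0, f1, 8)
            fld = mf.gradient_field(diff, roi)
            u, v = gradient_oracle(diff.d_rescaled)
            np.testing.assert_allclose(fld.u, np.where(roi, u, 0), atol=1e-12)
            np.testing.assert_allclose(fld.v, np.where(roi, v, 0), atol=1e-12)

    def test_gradient_linearity(self, rng):
        d1 = rng.random((12, 12))
        d2 = rng.random((12, 12))
        roi = np.ones((12, 12), bool)
        mk = lambda d: mf.gradient_field(mf.DifferenceImage(d=d, d_rescaled=d), roi)
        a, b = 2.3, -0.7
        combo = mk(a * d1 + b * d2)
        f1, f2 = mk(d1), mk(d2)
        np.testing.assert_allclose(combo.u, a * f1.u + b * f2.u, atol=1e-10)
        np.testing.assert_allclose(combo.v, a * f1.v + b * f2.v, atol=1e-10)


class TestAggregation:
    def test_zero_field_sums_to_zero_with_zero_angle(self):
        fld = MotionField(u=np.zeros((5, 5)), v=np.zeros((5, 5)), roi=np.ones((5, 5), bool))
        vec = mf.aggregate_vector(fld)
        assert vec.magnitude == 0.0
        assert vec.theta_deg == 0.0

    def test_closed_form_two_vector_addition(self):
        u = np.zeros((2, 2))
        v = np.zeros((2, 2))
        u[0, 0] = 1.0   # (1, 0)
        v[0, 1] = 1.0   # (0, 1)
        vec = mf.aggregate_vector(MotionField(u=u, v=v, roi=np.ones((2, 2), bool)))
        assert vec.magnitude == pytest.approx(math.sqrt(2))
        assert vec.theta_deg == pytest.approx(45.0)

    def test_additivity_over_disjoint_partitions(self, rng):
        fld = MotionField(u=rng.normal(size=(16, 16)), v=rng.normal(size=(16, 16)),
                          roi=rng.random((16, 16)) < 0.8)
        for _ in range(50):
            part = rng.random((16, 16)) < 0.5
            whole = mf.aggregate_vector(fld, np.ones((16, 16), bool))
            a = mf.aggregate_vector(fld, part)
            b = mf.aggregate_vector(fld, ~part)
            assert whole.u_sum == pytest.approx(a.u_sum + b.u_sum)
            assert whole.v_sum == pytest.approx(a.v_sum + b.v_sum)

    def test_empty_region_gives_zero_vector(self):
        fld = MotionField(u=np.ones((4, 4)), v=np.ones((4, 4)), roi=np.ones((4, 4), bool))
        vec = mf.aggregate_vector(fld, np.zeros((4, 4), bool))
        assert vec.magnitude == 0.0 and vec.theta_deg == 0.0


class TestPerClassMotion:
    def test_single_class_mean_is_object_mean(self, rng):
        lab = np.zeros((12, 12), int)
        lab[1:4, 1:4] = 1
        lab[7:10, 7:10] = 2
        fld = MotionField(u=rng.normal(size=(12, 12)), v=rng.normal(size=(12, 12)),
                          roi=np.ones((12, 12), bool))
        out = mf.per_class_motion(fld, lab, {1: "networked", 2: "networked"})
        mags = [o["magnitude"] for o in out["networked"]["objects"]]
        assert out["networked"]["mean_magnitude"] == pytest.approx(np.mean(mags))

    def test_unassigned_label_rejected(self):
        lab = np.zeros((6, 6), int)
        lab[2:4, 2:4] = 1
        fld = MotionField(u=np.ones((6, 6)), v=np.ones((6, 6)), roi=np.ones((6, 6), bool))
        with pytest.raises(KeyError):
            mf.per_class_motion(fld, lab, {})

    def test_jittering_class_has_larger_motion(self):
        """Only the networked objects move between frames; their per-class
        mean motion magnitude must exceed the static punctate class."""
        stack, truth = mf.make_morphology_field(8, 0, 0, size=(160, 160), seed=21,
                                                read_sigma=0.0, poisson=False)
        net_stack, net_truth = mf.make_morphology_field(0, 6, 0, size=(160, 160), seed=22,
                                                        read_sigma=0.0, poisson=False)
        a = np.clip(stack.frame(0).astype(int) + net_stack.frame(0).astype(int), 0, 255).astype(np.uint8)
        moved = np.roll(net_stack.frame(0), (1, 1), axis=(0, 1))
        b = np.clip(stack.frame(0).astype(int) + moved.astype(int), 0, 255).astype(np.uint8)
        diff = mf.difference_image(a, b, 8)
        roi = (a > 0) | (b > 0)
        fld = mf.gradient_field(diff, roi)
        lab = truth.label_image.copy()
        offset = lab.max()
        lab[net_truth.label_image > 0] = net_truth.label_image[net_truth.label_image > 0] + offset
        classes = {i: "punctate" for i in truth.classes}
        classes.update({i + offset: "networked" for i in net_truth.classes})
        out = mf.per_class_motion(fld, lab, classes)
        assert out["networked"]["mean_magnitude"] > out["punctate"]["mean_magnitude"]


class TestDirectional:
    def _field_with_vector(self, pos, u, v, shape=(21, 21)):
        U = np.zeros(shape)
        V = np.zeros(shape)
        U[pos] = u
        V[pos] = v
        return MotionField(u=U, v=V, roi=np.ones(shape, bool))

    def test_radially_outward_vector_counts_positive(self):
        # pixel right of centre, vector pointing right (away)
        fld = self._field_with_vector((10, 15), 2.0, 0.0)
        val = mf.directional_component(fld, (10.0, 10.0))
        assert val == pytest.approx(2.0)

    def test_tangential_vector_contributes_zero(self):
        fld = self._field_with_vector((10, 15), 0.0, 1.5)
        val = mf.directional_component(fld, (10.0, 10.0))
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_reference_pixel_contributes_zero(self):
        fld = self._field_with_vector((10, 10), 3.0, 3.0)
        assert mf.directional_component(fld, (10.0, 10.0)) == 0.0

    def test_expanding_ring_positive_contracting_negative(self):
        """A ring brightening outward reads as net motion away from centre."""
        H = W = 64
        rr, cc = np.mgrid[0:H, 0:W].astype(float)
        d = np.hypot(rr - 32, cc - 32)
        ring = lambda r0: np.clip(200 * np.exp(-((d - r0) ** 2) / 8), 0, 255).astype(np.uint8)
        a, b = ring(12), ring(16)
        roi = (a > 10) | (b > 10)
        fields = [mf.gradient_field(mf.difference_image(a, b, 8), roi)]
        series, net = mf.directional_series(fields, (32.0, 32.0))
        assert series[0] > 0 and net > 0
        fields = [mf.gradient_field(mf.difference_image(b, a, 8), roi)]
        series, net = mf.directional_series(fields, (32.0, 32.0))
        assert series[0] < 0 and net < 0

    def test_reference_outside_frame_rejected(self):
        fld = self._field_with_vector((0, 0), 1.0, 0.0)
        with pytest.raises(ValueError, match="reference"):
            mf.directional_series([fld], (100.0, 5.0))


class TestLucasKanade:
    def test_translated_texture_recovers_direction(self, rng):
        base = ndi.gaussian_filter(rng.random((64, 64)) * 255, 2)
        a = base.astype(np.uint8)
        b = np.roll(a, 2, axis=1)  # move right by 2 px
        inner = np.zeros((64, 64), bool)
        inner[10:54, 10:54] = True
        vec = mf.lucas_kanade_baseline(a, b, region=inner)
        assert abs(vec.theta_deg) < 5.0

    def test_uniform_region_is_ill_conditioned(self):
        a = np.full((32, 32), 90, np.uint8)
        b = np.full((32, 32), 90, np.uint8)
        vec = mf.lucas_kanade_baseline(a, b)
        assert vec.magnitude == pytest.approx(0.0, abs=1e-9)

    def test_static_scene_gives_near_zero(self, rng):
        a = ndi.gaussian_filter(rng.random((48, 48)) * 255, 2).astype(np.uint8)
        vec = mf.lucas_kanade_baseline(a, a)
        assert vec.magnitude == pytest.approx(0.0, abs=1e-9)


class TestAccuracyMetrics:
    @pytest.mark.parametrize("err,acc", [(0.0, 100.0), (180.0, 0.0), (45.0, 75.0)])
    def test_angle_accuracy_formula(self, err, acc):
        assert mf.angle_accuracy(30.0 + err, 30.0) == pytest.approx(acc)

    def test_wrapping(self):
        assert mf.wrapped_angle_error_deg(-170.0, 170.0) == pytest.approx(20.0)

    def test_zero_displacement_truth_reports_missing(self):
        scene = mf.make_motion_scene("solid_dot", (0.0, 0.0))
        vec = mf.SummedVector(u_sum=1.0, v_sum=0.0)
        angle_acc, _ = mf.motion_accuracy(vec, scene)
        assert angle_acc is None

    def test_magnitude_accuracy_is_self_referenced(self):
        assert mf.magnitude_accuracy(8.0, 10.0) == pytest.approx(80.0)
        assert mf.magnitude_accuracy(25.0, 10.0) == 0.0  # clamped at zero


class TestEstimatorProperties:
    def test_zero_motion_identity(self, rng):
        f = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        diff = mf.difference_image(f, f, 8)
        fld = mf.gradient_field(diff, np.ones((32, 32), bool))
        assert mf.aggregate_vector(fld).magnitude == 0.0

    @staticmethod
    def _summed_vector(scene):
        from mitoflow.segment import binary_segmentation

        s_a = binary_segmentation(scene.frame_a, mode="global_otsu")
        s_b = binary_segmentation(scene.frame_b, mode="global_otsu")
        fld = mf.gradient_field(
            mf.difference_image(scene.frame_a, scene.frame_b, 8), mf.motion_roi(s_a, s_b)
        )
        return fld

    @pytest.mark.parametrize(
        "case,mag",
        [("solid_dot", 2.0), ("solid_dot", 4.0), ("solid_dot", 8.0),
         ("solid_rect", 4.0), ("solid_rect", 8.0)],
    )
    def test_translation_angle_recovery_constant_brightness(self, case, mag):
        scene = mf.make_motion_scene(case, mf.displacement_from_polar(mag, 30.0))
        vec = mf.aggregate_vector(self._summed_vector(scene))
        assert mf.wrapped_angle_error_deg(vec.theta_deg, scene.truth_angle_deg) <= 15.0

    def test_rectangle_axis_bias_at_small_displacement(self):
        """Flat edges bias the summed vector towards the axes when the
        displacement is small relative to the edge length: exact on-axis,
        bounded off-axis, and shrinking as the displacement grows."""
        on_axis = mf.make_motion_scene("solid_rect", mf.displacement_from_polar(2.0, 0.0))
        vec = mf.aggregate_vector(self._summed_vector(on_axis))
        assert mf.wrapped_angle_error_deg(vec.theta_deg, 0.0) <= 2.0
        errs = {}
        for d in (2.0, 8.0):
            scene = mf.make_motion_scene("solid_rect", mf.displacement_from_polar(d, 30.0))
            vec = mf.aggregate_vector(self._summed_vector(scene))
            errs[d] = mf.wrapped_angle_error_deg(vec.theta_deg, scene.truth_angle_deg)
        assert errs[2.0] <= 25.0
        assert errs[8.0] < errs[2.0]

    def test_motion_grows_with_displacement(self):
        """Per-pixel motion activity rises strictly with translation
        distance; the summed resultant rises through the sub-stencil regime
        and then saturates (its magnitude is a boundary effect of the ROI,
        not a speed estimate)."""
        mags, acts = [], []
        for d in (0.0, 1.0, 2.0, 4.0):
            per_m, per_a = [], []
            for seed in range(20):
                ang = 17.0 * seed % 360
                scene = mf.make_motion_scene(
                    "solid_dot", mf.displacement_from_polar(d, ang), seed=seed
                )
                fld = self._summed_vector(scene)
                per_m.append(mf.aggregate_vector(fld).magnitude)
                per_a.append(motion_activity(fld))
            mags.append(np.mean(per_m))
            acts.append(np.mean(per_a))
        assert acts[0] < acts[1] < acts[2] < acts[3]
        assert mags[0] < mags[1] < mags[2]
        assert mags[3] > mags[1]

    def test_motion_activity_zero_on_empty_roi(self):
        fld = MotionField(u=np.ones((4, 4)), v=np.ones((4, 4)), roi=np.zeros((4, 4), bool))
        assert motion_activity(fld) == 0.0
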