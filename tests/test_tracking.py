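import numpy as np
import pytest
from scipy import ndimage

import thermoflow as tf


class TestDetectKeypoints:
    def test_constant_region_yields_no_points(self):
        frame = np.full((40, 40), 0.5)
        roi = tf.RegionOfInterest(5, 5, 30, 30)
        assert len(tf.detect_keypoints(frame, roi, 10)) == 0

    def test_single_bright_pixel_detected(self):
        frame = np.zeros((40, 40))
        frame[20, 22] = 1.0
        roi = tf.RegionOfInterest(5, 5, 30, 30)
        pts = tf.detect_keypoints(frame, roi, 5)
        assert len(pts) >= 1
        d = np.hypot(pts[:, 0] - 20, pts[:, 1] - 22).min()
        assert d <= 1.5

    def test_face_texture_found_not_background(self, sim_small):
        cfg, seq, gt = sim_small
        params = tf.tracking_norm_params(seq, gt)
        norm = tf.normalize(seq.frames[0], params, "tracking")
        pts = tf.detect_keypoints(norm, gt.initial_roi, 20)
        assert len(pts) >= 5
        r0, r1, c0, c1 = gt.face_box
        # all corners sit on the face (plus a small dilation margin), none in
        # the pure-noise background to the right
        assert np.all(pts[:, 1] <= c1 + gt.face_trajectory[0][1] + 3)
        assert np.all((pts[:, 0] >= r0 - 3) & (pts[:, 0] <= r1 + 3))


class TestEstimateShift:
    def test_static_scene(self, smooth_texture):
        roi = tf.RegionOfInterest(20, 20, 40, 40)
        kps = tf.detect_keypoints(smooth_texture, roi, 10)
        shift, low = tf.estimate_shift(smooth_texture, smooth_texture, kps)
        assert shift == (0, 0) and not low

    def test_integer_translation_matches_ssd_oracle(self, smooth_texture):
        prev = smooth_texture
        cur = np.roll(prev, 3, axis=1)
        roi = tf.RegionOfInterest(20, 20, 40, 40)
        kps = tf.detect_keypoints(prev, roi, 10)
        shift, _ = tf.estimate_shift(prev, cur, kps)
        # exhaustive integer-shift SSD oracle over the ROI interior
        crop = roi.crop(prev)
        best = min(
            (
                (np.sum((np.roll(cur, (-dr, -dc), axis=(0, 1))[20:60, 20:60] - crop) ** 2), (dr, dc))
                for dr in range(-4, 5)
                for dc in range(-4, 5)
            )
        )[1]
        assert best == (0, 3)
        assert shift == best

    def test_subpixel_motion_absorbed_by_deadband(self, smooth_texture):
        cur = ndimage.shift(smooth_texture, (0, 0.4), order=3)
        roi = tf.RegionOfInterest(20, 20, 40, 40)
        kps = tf.detect_keypoints(smooth_texture, roi, 10)
        shift, _ = tf.estimate_shift(smooth_texture, cur, kps)
        assert shift == (0, 0)

    def test_no_keypoints_flags_low_confidence(self, smooth_texture):
        shift, low = tf.estimate_shift(smooth_texture, smooth_texture, np.zeros((0, 2)))
        assert shift == (0, 0) and low


class TestTrackSequence:
    def test_static_scene_all_rois_equal(self):
        cfg = tf.SimulationConfig(duration_s=2.0, seed=5, drift_speed=0.0)
        seq, gt = tf.simulate_sequence(cfg)
        params = tf.tracking_norm_params(seq, gt)
        rois, state = tf.track_sequence(seq, gt.initial_roi, params)
        assert len(rois) == len(seq)
        assert all(r == gt.initial_roi for r in rois)
        assert all(s == (0, 0) for s in state.shift_history)

    def test_roi_size_invariant_and_history_length(self, sim_small, tracked_small):
        cfg, seq, gt = sim_small
        rois, state, _ = tracked_small
        assert len(state.shift_history) == len(seq) - 1
        assert all(
            (r.height, r.width) == (gt.initial_roi.height, gt.initial_roi.width)
            for r in rois
        )

    def test_follows_drifting_face(self):
        cfg = tf.SimulationConfig(
            duration_s=0.44, seed=9, drift_speed=0.0, drift_velocity=(0.0, 1.0)
        )
        seq, gt = tf.simulate_sequence(cfg)  # 11 frames: +1 px/frame rightward
        params = tf.tracking_norm_params(seq, gt)
        rois, _ = tf.track_sequence(seq, gt.initial_roi, params)
        moved = rois[-1].col0 - rois[0].col0
        assert abs(moved - 10) <= 1

    def test_tracking_error_within_two_px_over_200_frames(self, sim_small, tracked_small):
        cfg, seq, gt = sim_small
        rois, _, _ = tracked_small
        drift = gt.face_trajectory - gt.face_trajectory[0]
        pos = np.array([(r.row0, r.col0) for r in rois], float)
        err = np.abs((pos - pos[0]) - drift).mean(axis=0)
        assert len(seq) >= 200
        assert np.all(err <= 2.0)

    def test_roi_clamped_at_border_and_flagged(self):
        # a face drifting +1 px/frame for 4 s pushes the tracked ROI past the
        # right image edge: it must stop at the border and set the flag
        cfg = tf.SimulationConfig(
            duration_s=4.0, seed=9, drift_speed=0.0, drift_velocity=(0.0, 1.0)
        )
        seq, gt = tf.simulate_sequence(cfg)
        params = tf.tracking_norm_params(seq, gt)
        rois, state = tf.track_sequence(seq, gt.initial_roi, params)
        assert all(r.col0 + r.width <= cfg.w for r in rois)
        assert rois[-1].col0 == cfg.w - gt.initial_roi.width
        assert any(state.flags)


class TestCompensateShift:
    def test_zero_shift_identity(self, rng):
        field = rng.normal(size=(8, 8, 2))
        assert tf.compensate_shift(field, (0, 0)) is field

    def test_exact_cancellation(self):
        field = np.zeros((6, 6, 2))
        field[..., 0] = 1.0  # uniform v_x
        out = tf.compensate_shift(field, (0, 1))
        assert np.allclose(out, 0.0)

    def test_linear_inverse(self, rng):
        field = rng.normal(size=(6, 6, 2))
        out = tf.compensate_shift(tf.compensate_shift(field, (2, -3)), (-2, 3))
        assert np.allclose(out, field, atol=1e-12)

    def test_static_scene_crops_compensated(self):
        # the apparent motion of a static scene seen through a moved window
        # is the inverse of the window displacement; removing it shrinks the field
        from scipy import ndimage

        gen = np.random.default_rng(99)
        tex = ndimage.gaussian_filter(gen.standard_normal((80, 100)), 2.0)
        tex = 0.5 + 0.5 * tex / np.abs(tex).max()
        a = tex[20:60, 20:60]
        b = tex[20:60, 21:61]  # ROI moved +1 col
        field = tf.horn_schunck(a, b, tf.FlowParams(n_iter=400))
        induced = (0, -1)
        comp = tf.compensate_shift(field, induced)
        mag = lambda f: np.hypot(f[..., 0], f[..., 1]).mean()
        assert mag(comp) < mag(field)


def test_face_mask_marks_face(sim_small):
    cfg, seq, gt = sim_small
    params = tf.tracking_norm_params(seq, gt)
    mask = tf.face_mask(seq.frames[0], gt.initial_roi, params)
    assert mask.shape == (gt.initial_roi.height, gt.initial_roi.width)
    r0, r1, c0, c1 = gt.face_box
    face_cols = int(c1 - gt.initial_roi.col0)  # columns of the ROI on the face
    assert mask[:, : max(face_cols - 4, 1)].mean() > 0.5
    assert mask[:, face_cols + 8 :].mean() < 0.1
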