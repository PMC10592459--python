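"""Single-animal detection on rendered frames with known ground truth."""

import numpy as np
import pytest

from pitchnav.detect import (
    DetectorThresholds,
    detect_animal,
    estimate_background,
    orientation_from_parts,
    split_parts,
    subtract_background,
)
from pitchnav.render import Pose, make_background, render_frame, render_with_truth


@pytest.fixture(scope="module")
def background():
    return make_background((220, 220))


@pytest.fixture(scope="module")
def thresholds(background):
    return DetectorThresholds(background=background)


class TestSubtractBackground:
    def test_identical_frames_give_zero(self, background):
        assert np.all(subtract_background(background, background) == 0)

    def test_constant_offset_gives_constant(self, background):
        diff = subtract_background(background + 7.5, background)
        assert np.allclose(diff, 7.5)

    def test_shape_mismatch_raises(self, background):
        with pytest.raises(ValueError):
            subtract_background(background[:-1], background)

    def test_difference_confined_to_fish_mask(self, background):
        frame, truth = render_with_truth(Pose(110, 110, 20.0), background)
        diff = subtract_background(frame, background)
        assert np.all(diff[~truth["mask"]] == 0)
        assert diff[truth["mask"]].max() > 100


class TestOrientationFromParts:
    def test_head_directly_above_is_plus_90(self):
        assert orientation_from_parts((0, 0), (0, 5)) == pytest.approx(90.0)

    @pytest.mark.parametrize("dx", [1.0, -1.0])
    def test_heading_invariance_at_45(self, dx):
        assert orientation_from_parts((0, 0), (dx, 1.0)) == pytest.approx(45.0)

    def test_coincident_centroids_raise(self):
        with pytest.raises(ValueError):
            orientation_from_parts((3, 4), (3, 4))


class TestSplitParts:
    def test_brighter_head_disc_is_found(self, background):
        frame, truth = render_with_truth(Pose(110, 110, 0.0), background)
        diff = subtract_background(frame, background)
        rows, cols = np.nonzero(truth["mask"])
        H = background.shape[0]
        xz = np.column_stack([cols.astype(float), (H - 1.0) - rows])
        body_i, head_i = split_parts(xz, diff[rows, cols])
        w = diff[rows, cols][head_i]
        head_c = (xz[head_i] * w[:, None]).sum(axis=0) / w.sum()
        assert np.hypot(*(head_c - np.array(truth["head"]))) < 2.0

    def test_uniform_circular_blob_is_unresolved(self):
        yy, xx = np.mgrid[-10:11, -10:11]
        inside = xx**2 + yy**2 <= 100
        xz = np.column_stack([xx[inside], yy[inside]]).astype(float)
        assert split_parts(xz, np.full(len(xz), 50.0)) is None

    def test_dumbbell_brighter_lobe_is_head(self):
        pts, w = [], []
        for cx, amp in [(-8.0, 40.0), (8.0, 80.0)]:
            yy, xx = np.mgrid[-4:5, -4:5]
            inside = xx**2 + yy**2 <= 16
            pts.append(np.column_stack([xx[inside] + cx, yy[inside]]).astype(float))
            w.append(np.full(inside.sum(), amp))
        xz = np.vstack(pts)
        w = np.concatenate(w)
        body_i, head_i = split_parts(xz, w)
        assert xz[head_i][:, 0].mean() > 4  # the 2x brighter lobe at x=+8
        assert xz[body_i][:, 0].mean() < -4


class TestDetectAnimal:
    def test_background_only_frame_rejected_no_animal(self, background, thresholds):
        res = detect_animal(background.copy(), thresholds)
        assert not res.accepted and res.rejection_reason == "no_animal"

    def test_two_animals_always_rejected(self, background, thresholds):
        for dzx in [(60, 0), (0, 60), (50, 50)]:
            f1 = render_frame(Pose(80, 80, 10.0), background)
            f2 = render_frame(Pose(80 + dzx[0], 80 + dzx[1], -30.0), background)
            frame = np.maximum(f1, f2)
            res = detect_animal(frame, thresholds)
            assert not res.accepted
            assert res.rejection_reason == "multiple_animals"

    def test_pitch_30_recovered_within_1_degree(self, background, thresholds, rng):
        frame = render_frame(Pose(110, 110, 30.0), background, noise_sd=2.0, rng=rng)
        res = detect_animal(frame, thresholds)
        assert res.accepted
        assert res.pitch == pytest.approx(30.0, abs=1.0)

    @pytest.mark.parametrize("heading", [1, -1])
    def test_pitch_sweep_within_1_degree(self, background, thresholds, heading):
        """Rotation consistency over [-80, 80] deg, both headings."""
        for pitch in np.linspace(-80, 80, 17):
            frame = render_frame(Pose(110.3, 109.7, pitch, heading=heading), background)
            res = detect_animal(frame, thresholds)
            assert res.accepted, f"pitch {pitch} rejected: {res.rejection_reason}"
            assert res.pitch == pytest.approx(pitch, abs=1.0), f"at pitch {pitch}"

    def test_heading_invariance(self, background, thresholds):
        for pitch in (-35.0, 20.0):
            r1 = detect_animal(render_frame(Pose(110, 110, pitch, 1), background), thresholds)
            r2 = detect_animal(render_frame(Pose(110, 110, pitch, -1), background), thresholds)
            assert r1.pitch == pytest.approx(r2.pitch, abs=0.5)

    def test_detector_is_pure(self, background, thresholds, rng):
        frame = render_frame(Pose(90, 120, -15.0), background, noise_sd=2.0, rng=rng)
        r1 = detect_animal(frame, thresholds)
        r2 = detect_animal(frame, thresholds)
        assert r1 == r2


class TestRenderer:
    def test_same_seed_gives_identical_frames(self, background):
        f1 = render_frame(Pose(100, 100, 12.0), background, 3.0, np.random.default_rng(5))
        f2 = render_frame(Pose(100, 100, 12.0), background, 3.0, np.random.default_rng(5))
        assert np.array_equal(f1, f2)

    def test_out_of_bounds_pose_raises(self, background):
        with pytest.raises(ValueError):
            render_frame(Pose(5, 110, 0.0), background)

    def test_horizontal_fish_is_axis_symmetric(self, background):
        frame, truth = render_with_truth(Pose(110, 110.0, 0.0), background)
        paint = frame - background
        rows = np.nonzero(paint.any(axis=1))[0]
        mid = (rows.min() + rows.max()) / 2
        assert mid == pytest.approx(220 - 1 - 110.0, abs=0.5)
        top = paint[int(np.floor(mid)) - 8 : int(np.floor(mid)), :]
        bot = paint[int(np.ceil(mid)) + 1 : int(np.ceil(mid)) + 9, :][::-1]
        assert np.allclose(top, bot, atol=1e-9)

    def test_trajectory_detection_rate_and_centroid_rmse(self, background, thresholds):
        """Rendered trajectory: >=99% accepted, centroid RMSE < 1 px."""
        rng = np.random.default_rng(7)
        t = np.linspace(0, 2 * np.pi, 300)
        xs = 110 + 55 * np.cos(t)
        zs = 110 + 55 * np.sin(2 * t) / 2
        pitches = 40 * np.sin(t + 1.0)
        accepted = 0
        errs = []
        for x, z, pitch in zip(xs, zs, pitches):
            frame, truth = render_with_truth(
                Pose(x, z, pitch), background, noise_sd=2.0, rng=rng
            )
            res = detect_animal(frame, thresholds)
            if not res.accepted:
                continue
            accepted += 1
            # whole-blob intensity-weighted centroid vs the noise-free truth
            diff = subtract_background(frame, thresholds.background)
            mask = diff > thresholds.noise_threshold
            rr, cc = np.nonzero(mask)
            w = diff[rr, cc]
            cx = (cc * w).sum() / w.sum()
            cz = ((220 - 1 - rr) * w).sum() / w.sum()
            tx, tz = truth["centroid"]
            errs.append((cx - tx) ** 2 + (cz - tz) ** 2)
        assert accepted >= 0.99 * len(t)
        assert np.sqrt(np.mean(errs)) < 1.0

    def test_detection_results_feed_estimated_background(self, background, rng):
        """Median background over a trajectory recovers the true background."""
        t = np.linspace(0, 2 * np.pi, 31)
        frames = np.stack(
            [
                render_frame(Pose(110 + 50 * np.cos(a), 110 + 40 * np.sin(a), 0.0),
                             background, noise_sd=1.0, rng=rng)
                for a in t
            ]
        )
        est = estimate_background(frames)
        assert np.median(np.abs(est - background)) < 1.0
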