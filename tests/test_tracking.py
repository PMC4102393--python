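import numpy as np
import pytest

from nemaswim.geometry import Centerline, body_length, resample_centerline
from nemaswim.synthgen import SwimScenario, generate_track, render_scene
from nemaswim.tracking import (
    FLAG_OK,
    FLAG_QUALITY,
    AnimalTrack,
    TrackingParams,
    handle_contacts,
    orient_head_tail,
    quality_check,
    segment_frame,
    std_filter,
    track_step,
    track_video,
)


def mean_deviation(tracked: Centerline, truth: Centerline) -> float:
    fine = resample_centerline(truth, 300).points
    d = np.linalg.norm(tracked.points[:, None, :] - fine[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


@pytest.fixture(scope="module")
def short_clip():
    scn = SwimScenario(
        seed=3, duration_s=3.0, L_px=100.0, start=(128, 128), drift_v=0.05,
        noise_sigma=3.0,
    )
    gt, cmap, _ = generate_track(scn)
    frames = render_scene([gt], (256, 256), noise_sigma=3.0, seed=3)
    return frames, gt


class TestSegmentation:
    def test_blank_noise_image_zero_animals(self):
        rng = np.random.default_rng(0)
        img = np.clip(200 + rng.normal(0, 5, (256, 256)), 0, 255).astype(np.uint8)
        seg = segment_frame(img)
        assert seg.centerlines == [] and seg.outlines == []

    def test_single_worm_within_one_pixel(self, short_clip):
        frames, gt = short_clip
        seg = segment_frame(frames[0])
        assert len(seg.centerlines) == 1
        c = seg.centerlines[0]
        assert mean_deviation(c, gt[0]) <= 1.0
        # half-widths come from the distance transform: positive, plausible
        assert c.half_widths.max() > 2.0
        assert (c.half_widths >= 0).all()

    def test_five_separated_worms_found(self):
        starts = [(60, 60), (200, 60), (128, 128), (60, 200), (200, 200)]
        gts = []
        for i, s in enumerate(starts):
            scn = SwimScenario(
                seed=20 + i, duration_s=0.2, L_px=70.0, start=s, heading=i, noise_sigma=3.0
            )
            gts.append(generate_track(scn)[0])
        frames = render_scene(gts, (256, 256), noise_sigma=3.0, seed=9)
        seg = segment_frame(frames[0])
        assert len(seg.centerlines) == 5
        # match each to its ground truth by centroid
        for c in seg.centerlines:
            dists = [
                np.linalg.norm(c.points.mean(axis=0) - g[0].points.mean(axis=0))
                for g in gts
            ]
            assert min(dists) < 20.0

    def test_std_filter_highlights_edges(self):
        img = np.full((64, 64), 100.0)
        img[30:34, 10:54] = 20.0
        s = std_filter(img, 5)
        assert s[28, 30] > 10 * s[5, 5] + 1e-9


class TestTrackStep:
    def test_static_worm_identity(self, short_clip):
        frames, gt = short_clip
        seg = segment_frame(frames[0])
        prev = seg.centerlines[0]
        c, flag = track_step(prev, frames[0], frames[0])
        assert flag == FLAG_OK
        assert mean_deviation(c, gt[0]) <= 1.0

    def test_one_step_tracks_within_one_pixel(self, short_clip):
        frames, gt = short_clip
        seg = segment_frame(frames[0])
        c, flag = track_step(seg.centerlines[0], frames[0], frames[1])
        assert flag == FLAG_OK
        assert mean_deviation(c, gt[1]) <= 1.0

    def test_full_clip_accuracy(self, short_clip):
        frames, gt = short_clip
        tracks = track_video(frames)
        assert len(tracks) == 1
        tr = tracks[0]
        devs = np.array([mean_deviation(c, gt[t]) for t, c in enumerate(tr.frames)])
        assert (devs <= 1.0).mean() >= 0.95
        assert not tr.rejected

    def test_determinism(self, short_clip):
        frames, _ = short_clip
        a = track_video(frames[:30])
        b = track_video(frames[:30])
        for ta, tb in zip(a, b):
            for ca, cb in zip(ta.frames, tb.frames):
                assert np.array_equal(ca.points, cb.points)
            assert ta.flags == tb.flags


class TestContacts:
    def _straight(self, y, x0=40, L=100.0, n=25):
        pts = np.column_stack([np.linspace(x0, x0 + L, n), np.full(n, float(y))])
        return Centerline(pts, np.full(n, 3.0))

    def test_distant_worms_unflagged(self):
        flags = handle_contacts([self._straight(40), self._straight(200)])
        assert flags == [False, False]

    def test_crossing_worms_flagged(self):
        a = self._straight(100)
        pts = np.column_stack([np.full(25, 90.0), np.linspace(50, 150, 25)])
        b = Centerline(pts, np.full(25, 3.0))
        flags = handle_contacts([a, b])
        assert flags == [True, True]

    def test_self_overlapping_curl_flagged(self):
        from nemaswim.synthgen import CURL_O_KAPPA, integrate_posture

        c = integrate_posture(np.full(12, CURL_O_KAPPA), 100.0, center=(128, 128))
        flags = handle_contacts([c])
        assert flags == [True]

    def test_rendered_crossing_flags_frames(self):
        # two worms driven through the same region for part of the clip
        scn_a = SwimScenario(seed=30, duration_s=2.0, L_px=80.0, start=(90, 128),
                             drift_v=0.6, drift_direction=(1.0, 0.0), noise_sigma=3.0)
        scn_b = SwimScenario(seed=31, duration_s=2.0, L_px=80.0, start=(166, 128),
                             drift_v=0.6, drift_direction=(-1.0, 0.0), heading=2.0,
                             noise_sigma=3.0)
        ga = generate_track(scn_a)[0]
        gb = generate_track(scn_b)[0]
        frames = render_scene([ga, gb], (256, 256), noise_sigma=3.0, seed=12)
        tracks = track_video(frames)
        assert len(tracks) == 2
        assert any("contact" in tr.flags for tr in tracks)


class TestQualityCheck:
    def _track(self, lengths):
        frames, flags = [], []
        for t, L in enumerate(lengths):
            pts = np.column_stack([np.linspace(0, L, 25), np.zeros(25)])
            frames.append(Centerline(pts, np.ones(25), frame_index=t))
            flags.append(FLAG_OK)
        return AnimalTrack(animal_id=0, frames=frames, flags=flags)

    def test_constant_length_accepted(self):
        tr = quality_check(self._track([100.0] * 50))
        assert tr.flagged_fraction == 0.0 and not tr.rejected

    def test_thirty_percent_collapsed_rejected(self):
        lengths = [100.0] * 70 + [50.0] * 30
        tr = quality_check(self._track(lengths))
        assert tr.flagged_fraction == pytest.approx(0.30)
        assert tr.rejected

    def test_ten_percent_flagged_accepted(self):
        lengths = [100.0] * 90 + [50.0] * 10
        tr = quality_check(self._track(lengths))
        assert tr.flagged_fraction == pytest.approx(0.10)
        assert not tr.rejected

    def test_flagged_frames_marked_invalid(self):
        lengths = [100.0] * 90 + [50.0] * 10
        tr = quality_check(self._track(lengths))
        assert not any(c.valid for c in tr.frames[90:])
        assert all(c.valid for c in tr.frames[:90])

    def test_manual_override(self):
        lengths = [100.0] * 70 + [50.0] * 30
        tr = quality_check(self._track(lengths))
        tr.apply_overrides({95: True})
        assert tr.frames[95].valid


class TestOrientHeadTail:
    def _track(self):
        pts = np.column_stack([np.linspace(0, 100, 25), np.zeros(25)])
        frames = [Centerline(pts.copy(), np.ones(25), frame_index=t) for t in range(5)]
        return AnimalTrack(0, frames, [FLAG_OK] * 5)

    def test_low_fraction_unchanged(self):
        tr = orient_head_tail(self._track(), 10.0)
        assert not tr.head_tail_swapped

    def test_high_fraction_swapped(self):
        tr = self._track()
        first = tr.frames[0].points[0].copy()
        tr = orient_head_tail(tr, 90.0)
        assert tr.head_tail_swapped
        assert np.allclose(tr.frames[0].points[-1], first)

    def test_exactly_fifty_percent_unchanged(self):
        tr = orient_head_tail(self._track(), 50.0)
        assert not tr.head_tail_swapped


class TestKeyframeMerge:
    def test_accurate_track_is_noop_and_drift_corrected(self, short_clip):
        from nemaswim.tracking import keyframe_merge, segment_frame

        frames, gt = short_clip
        seg = segment_frame(frames[20], frame_index=20)
        assert seg.centerlines
        good = seg.centerlines[0]

        merged, flag = keyframe_merge(good, seg, frames[20])
        assert flag == FLAG_OK
        assert mean_deviation(merged, gt[20]) <= 1.0

        # a tracker drifted 3 px sideways is pulled back by the merge
        drifted = Centerline(
            good.points + np.array([3.0, 0.0]), good.half_widths, 20
        )
        merged, flag = keyframe_merge(drifted, seg, frames[20])
        assert mean_deviation(merged, gt[20]) < mean_deviation(drifted, gt[20])
        assert mean_deviation(merged, gt[20]) <= 1.0

    def test_no_segmentation_match_flags(self, short_clip):
        from nemaswim.tracking import FLAG_QUALITY, FrameSegmentation, keyframe_merge, segment_frame

        frames, _ = short_clip
        seg = segment_frame(frames[20], frame_index=20)
        far = Centerline(
            seg.centerlines[0].points + 400.0, seg.centerlines[0].half_widths, 20
        )
        merged, flag = keyframe_merge(far, FrameSegmentation([], [], 20), frames[20])
        assert flag == FLAG_QUALITY
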