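import numpy as np
import pytest

from nemaswim.geometry import Centerline, CurvatureMap, SEGMENT_MIDPOINTS
from nemaswim.measures import (
    MEASURE_NAMES,
    MeasureSeries,
    activity_index,
    asymmetry,
    attenuation,
    body_wave_number,
    brush_stroke,
    curl_percentage,
    curling,
    reverse_percentage,
    reverse_swimming,
    stretch,
    summarize_trial,
    travel_speed,
    wave_initiation_rate,
)
from nemaswim.spectral import ModeTrack, StrokeClock, compute_modes, stroke_clock
from nemaswim.synthgen import (
    CURL_O_KAPPA,
    CURL_SIX_KAPPA,
    SwimScenario,
    generate_track,
    integrate_posture,
)

from conftest import make_wave_map


def const_modes(f_t, T, f_s=1.5, fps=18.0):
    return ModeTrack(
        f_s=np.full(T, f_s),
        f_t=np.full(T, float(f_t)),
        magnitude=np.ones(T),
        defined=np.ones(T, bool),
        frame_rate=fps,
    )


def const_clock(D, T, fps=18.0):
    return StrokeClock(np.full(T, float(D)), np.ones(T, bool), fps)


def undefined_modes(T, fps=18.0):
    return ModeTrack(
        np.full(T, np.nan), np.full(T, np.nan), np.zeros(T), np.zeros(T, bool), fps
    )


class TestRateMeasures:
    def test_wir_from_two_hz(self):
        s = wave_initiation_rate(const_modes(2.0, 50))
        assert np.allclose(s.values, 120.0)

    def test_wir_ignores_direction(self):
        s = wave_initiation_rate(const_modes(-1.0, 50))
        assert np.allclose(s.values, 60.0)

    def test_quiescent_trial_empty(self):
        s = wave_initiation_rate(undefined_modes(50))
        assert np.isnan(s.values).all() and np.isnan(s.median)

    def test_wave_number_abs_fs(self):
        s = body_wave_number(const_modes(1.0, 50, f_s=1.5))
        assert np.allclose(s.values, 1.5)

    def test_sub_unit_wave_number_recovered(self):
        # a single wave traversing the whole body before the next starts
        m = make_wave_map(f=1.5, n=0.7, T=360)
        modes = compute_modes(m)
        med = body_wave_number(modes).median
        assert 0 < med < 1
        assert med == pytest.approx(0.7, abs=0.1)


class TestAsymmetry:
    def test_unbiased_sinusoid_near_zero(self):
        m = make_wave_map(T=360)
        clock = const_clock(12, 360)
        assert abs(asymmetry(m, clock).median) < 0.05

    def test_constant_bias_survives(self):
        m = make_wave_map(T=360, bias=0.8)
        clock = const_clock(12, 360)
        assert asymmetry(m, clock).median == pytest.approx(0.8, rel=0.1)

    def test_frozen_clockwise_arc(self):
        m = CurvatureMap(
            np.full((12, 60), 2.0), 18.0, np.ones(60, bool), np.full(60, 100.0)
        )
        clock = const_clock(9, 60)
        assert np.allclose(asymmetry(m, clock).values, 2.0)


class TestStretch:
    def test_constant_amplitude_wave(self):
        m = make_wave_map(A=3.0, T=360)
        clock = stroke_clock(compute_modes(m), 18.0)
        assert stretch(m, clock).median == pytest.approx(6.0, rel=0.1)

    def test_frozen_posture_zero(self):
        m = CurvatureMap(
            np.full((12, 60), 2.0), 18.0, np.ones(60, bool), np.full(60, 100.0)
        )
        assert stretch(m, const_clock(9, 60)).median == pytest.approx(0.0, abs=1e-9)

    def test_max_over_body_parts(self):
        # mid-body envelope 4, elsewhere 2 -> stretch tracks the maximum
        T = 360
        t = np.arange(T) / 18.0
        env = np.where((SEGMENT_MIDPOINTS > 0.4) & (SEGMENT_MIDPOINTS < 0.6), 4.0, 2.0)
        vals = env[:, None] * np.sin(2 * np.pi * (1.5 * SEGMENT_MIDPOINTS[:, None] + 1.5 * t))
        m = CurvatureMap(vals, 18.0, np.ones(T, bool), np.full(T, 100.0))
        clock = stroke_clock(compute_modes(m), 18.0)
        assert stretch(m, clock).median == pytest.approx(8.0, rel=0.1)


class TestAttenuation:
    def test_equal_amplitudes_zero_percent(self):
        m = make_wave_map(alpha=0.0, T=360)
        clock = stroke_clock(compute_modes(m), 18.0)
        assert attenuation(m, clock).median == pytest.approx(0.0, abs=1.0)

    def test_motionless_tail_hundred_percent(self):
        m = make_wave_map(alpha=1.0, T=360)
        clock = stroke_clock(compute_modes(m), 18.0)
        assert attenuation(m, clock).median == pytest.approx(100.0, abs=1.0)

    def test_tail_twice_head_minus_hundred(self):
        T = 360
        t = np.arange(T) / 18.0
        env = np.where(SEGMENT_MIDPOINTS < 0.5, 4.0, 2.0)  # tail range 2x head
        vals = env[:, None] * np.sin(2 * np.pi * (1.5 * SEGMENT_MIDPOINTS[:, None] + 1.5 * t))
        m = CurvatureMap(vals, 18.0, np.ones(T, bool), np.full(T, 100.0))
        clock = stroke_clock(compute_modes(m), 18.0)
        assert attenuation(m, clock).median == pytest.approx(-100.0, abs=5.0)

    def test_motionless_head_undefined(self):
        m = CurvatureMap(
            np.zeros((12, 60)), 18.0, np.ones(60, bool), np.full(60, 100.0)
        )
        s = attenuation(m, const_clock(9, 60))
        assert np.isnan(s.values).all()


class TestReverse:
    def test_forward_only_zero(self):
        assert reverse_percentage(const_modes(1.5, 100)) == 0.0

    def test_constructed_fraction(self):
        T = 540
        f = np.full(T, 1.5)
        f[200:290] = -1.5
        modes = ModeTrack(np.full(T, 1.5), f, np.ones(T), np.ones(T, bool), 18.0)
        assert reverse_percentage(modes) == pytest.approx(100 * 90 / 540, abs=0.01)

    def test_fully_reversed(self):
        assert reverse_percentage(const_modes(-2.0, 100)) == 100.0

    def test_no_defined_frames_nan(self):
        assert np.isnan(reverse_percentage(undefined_modes(50)))


class TestCurling:
    def _track(self, kappa, T=5, L=100.0):
        return [
            integrate_posture(kappa, L, frame_index=t) for t in range(T)
        ]

    def test_straight_worm_not_curled(self):
        track = self._track(np.zeros(12))
        s = curling(track)
        assert curl_percentage(s) == 0.0

    def test_closed_O_curled(self):
        track = self._track(np.full(12, CURL_O_KAPPA))
        assert curl_percentage(curling(track)) == 100.0

    def test_six_shape_curled(self):
        kappa = np.where(SEGMENT_MIDPOINTS < 0.5, 0.0, CURL_SIX_KAPPA)
        track = self._track(kappa)
        assert curl_percentage(curling(track)) == 100.0

    def test_gentle_arc_not_curled(self):
        track = self._track(np.full(12, 2.0))
        assert curl_percentage(curling(track)) == 0.0


class TestTravelSpeed:
    def test_undulating_in_place_near_zero(self):
        scn = SwimScenario(seed=2, drift_v=0.0, duration_s=10.0)
        track, cmap, _ = generate_track(scn)
        clock = stroke_clock(compute_modes(cmap), 18.0)
        assert travel_speed(track, cmap, clock).median < 0.02

    def test_pure_drift_recovered(self):
        scn = SwimScenario(seed=2, A=0.8, drift_v=0.15, duration_s=10.0)
        track, cmap, _ = generate_track(scn)
        clock = stroke_clock(compute_modes(cmap), 18.0)
        assert travel_speed(track, cmap, clock).median == pytest.approx(0.15, rel=0.05)

    def test_lateral_cancellation_with_undulation(self):
        scn = SwimScenario(seed=2, drift_v=0.15, duration_s=10.0)
        track, cmap, _ = generate_track(scn)
        clock = stroke_clock(compute_modes(cmap), 18.0)
        assert travel_speed(track, cmap, clock).median == pytest.approx(0.15, rel=0.05)


class TestBrushStroke:
    def test_frozen_worm_zero(self):
        track = [
            integrate_posture(np.full(12, 1.5), 100.0, frame_index=t) for t in range(60)
        ]
        m = CurvatureMap(
            np.full((12, 60), 1.5), 18.0, np.ones(60, bool), np.full(60, 100.0)
        )
        s = brush_stroke(track, m, const_clock(9, 60))
        assert s.median == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance_of_normalized_raster(self):
        scn = SwimScenario(seed=4, duration_s=6.0)
        track, cmap, _ = generate_track(scn)
        clock = stroke_clock(compute_modes(cmap), 18.0)
        v1 = brush_stroke(track, cmap, clock).median
        track2 = [
            Centerline(c.points * 2.0, c.half_widths * 2.0, c.frame_index, c.valid)
            for c in track
        ]
        cmap2 = CurvatureMap(
            cmap.values, 18.0, cmap.valid_frames, cmap.body_length_px * 2.0
        )
        v2 = brush_stroke(track2, cmap2, clock).median
        assert v2 == pytest.approx(v1, rel=0.02)

    def test_swept_half_disc_vs_geometric_union_oracle(self):
        # a straight rigid worm pivoting about its tail sweeps (roughly) a
        # half disc; oracle = exact union area of buffered segments (shapely)
        from shapely.geometry import LineString
        from shapely.ops import unary_union

        L, T = 100.0, 37
        hw = 3.0
        off = 0.3  # keep postures off the pixel axes (no grid alignment)
        track = []
        for t in range(T):
            ang = off + np.pi * t / (T - 1)
            u = np.linspace(0, 1, 25)
            pts = np.column_stack([u * L * np.cos(ang), u * L * np.sin(ang)])
            track.append(Centerline(pts, np.full(25, hw), frame_index=t))
        m = CurvatureMap(np.zeros((12, T)), 18.0, np.ones(T, bool), np.full(T, L))
        clock = const_clock(T / 2.0, T)
        s = brush_stroke(track, m, clock, smooth=False)

        tubes = [
            LineString([(0, 0), (L * np.cos(a), L * np.sin(a))]).buffer(hw)
            for a in np.linspace(off, off + np.pi, 200)
        ]
        expect = unary_union(tubes).area / tubes[0].area - 1.0
        # sanity: close to the ideal half-disc over rectangle ratio
        assert expect == pytest.approx(np.pi * L**2 / 2 / (2 * hw * L) - 1, rel=0.15)
        assert s.values[T // 2] == pytest.approx(expect, rel=0.05)


class TestActivityIndex:
    def test_arithmetic(self):
        T = 60
        brush = MeasureSeries("brush_stroke", np.full(T, 1.0), "body areas")
        s = activity_index(brush, const_clock(9, T), 18.0)
        assert np.allclose(s.values, 1.0)  # 1.0 / (2*9/18)

    def test_doubling_frequency_doubles_index(self):
        T = 60
        brush = MeasureSeries("brush_stroke", np.full(T, 1.0), "body areas")
        a = activity_index(brush, const_clock(9, T), 18.0)
        b = activity_index(brush, const_clock(4.5, T), 18.0)
        assert np.allclose(b.values, 2 * a.values)


class TestSummaries:
    def test_constant_series_collapses(self):
        s = MeasureSeries("x", np.full(50, 3.3), "u")
        assert s.median == s.p10 == s.p90 == pytest.approx(3.3)

    def test_median_robust_to_outliers(self):
        rng = np.random.default_rng(0)
        base = np.full(100, 60.0)
        base[:10] = 600.0  # 10% outliers at 10x
        s = MeasureSeries("x", rng.permutation(base), "u")
        assert s.median == 60.0
        assert base.mean() > 100.0  # the mean would have shifted

    def test_percentile_order(self):
        rng = np.random.default_rng(1)
        s = MeasureSeries("x", rng.normal(size=500), "u")
        assert s.p10 <= s.median <= s.p90

    def test_summarize_all_invalid_raises(self):
        m = CurvatureMap(
            np.full((12, 20), np.nan), 18.0, np.zeros(20, bool), np.full(20, np.nan)
        )
        with pytest.raises(ValueError, match="invalid"):
            summarize_trial([], m, undefined_modes(20), const_clock(9, 20))

    def test_summarize_no_mode_raises(self):
        m = CurvatureMap(
            np.zeros((12, 20)), 18.0, np.ones(20, bool), np.full(20, 100.0)
        )
        clock = StrokeClock(np.full(20, np.nan), np.zeros(20, bool), 18.0)
        with pytest.raises(ValueError, match="mode"):
            summarize_trial([], m, undefined_modes(20), clock)

    def test_invalid_frames_never_enter_summaries(self):
        m = make_wave_map(T=200)
        # poison frames 50..80, then invalidate them
        m.values[:, 50:80] = 1e6
        m.valid_frames[50:80] = False
        m.values[:, 50:80] = np.nan
        modes = compute_modes(m)
        clock = stroke_clock(modes, 18.0)
        st = stretch(m, clock)
        assert st.median == pytest.approx(6.0, rel=0.1)


class TestHeadTailRelabeling:
    def test_reverse_percentage_complements(self):
        scn = SwimScenario(seed=6, reverse_episodes=((100, 208),), duration_s=30.0)
        _, cmap, _ = generate_track(scn)
        p = reverse_percentage(compute_modes(cmap))
        p_rev = reverse_percentage(compute_modes(cmap.reversed()))
        assert p + p_rev == pytest.approx(100.0, abs=2.0)

    def test_asymmetry_sign_flips(self):
        m = make_wave_map(T=270, bias=0.7)
        clock = stroke_clock(compute_modes(m), 18.0)
        a = asymmetry(m, clock).median
        a_rev = asymmetry(m.reversed(), clock).median
        assert a_rev == pytest.approx(-a, abs=0.02)

    def test_attenuation_quarters_swap(self):
        m = make_wave_map(T=270, alpha=0.5)
        clock = stroke_clock(compute_modes(m), 18.0)
        a = attenuation(m, clock).median  # 1 - tail/head = 50%
        a_rev = attenuation(m.reversed(), clock).median  # 1 - head/tail
        assert a == pytest.approx(50.0, abs=2.0)
        assert a_rev == pytest.approx(100.0 * (1.0 - 1.0 / 0.5), abs=5.0)
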