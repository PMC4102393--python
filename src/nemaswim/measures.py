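"""The ten swim measures, per-frame series and robust trial summaries.

Eight measures are continuous per-frame series summarized by the temporal
median and the 10-90 percentile range (medians because dynamic changes
within a trial skew means away from the typical behavior); Reverse swimming
and Curling are binary per-frame states summarized as the percentage of time
in the state.

Most measures integrate over a *two-stroke window*: the half-open frame
interval ``[t - D, t + D)`` where ``D`` is the current stroke duration from
the spectral clock.  A window is usable when at least half of its frames are
valid.  Frames flagged invalid never contribute to any statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .geometry import (
    N_SEGMENTS,
    Centerline,
    CurvatureMap,
    body_center,
    body_length,
    resample_centerline,
)
from .spectral import ModeTrack, StrokeClock

__all__ = [
    "MEASURE_NAMES",
    "MeasureSeries",
    "TrialSummary",
    "wave_initiation_rate",
    "body_wave_number",
    "asymmetry",
    "stretch",
    "attenuation",
    "reverse_swimming",
    "curling",
    "travel_speed",
    "brush_stroke",
    "activity_index",
    "summarize_trial",
]

MEASURE_NAMES = (
    "wave_initiation_rate",
    "body_wave_number",
    "asymmetry",
    "stretch",
    "attenuation",
    "reverse_swimming",
    "curling",
    "travel_speed",
    "brush_stroke",
    "activity_index",
)

#: Minimum head-quarter curvature range (dimensionless) below which the
#: attenuation ratio is undefined (guards against a motionless head).
DEFAULT_RANGE_EPS = 0.1

#: Body length in raster units for brush-stroke rasterization; a fixed
#: normalized scale makes the measure resolution-independent.
BRUSH_RASTER_UNITS = 128

#: Tail quarter = segment rows 0-2, head quarter = rows 9-11.
_TAIL_ROWS = slice(0, 3)
_HEAD_ROWS = slice(9, 12)

_MIN_WINDOW_VALID_FRACTION = 0.5


@dataclass
class MeasureSeries:
    """One measure's per-frame values with robust trial summary."""

    name: str
    values: np.ndarray  # (T,), NaN where undefined
    units: str

    @property
    def _finite(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.values).sum())

    @property
    def median(self) -> float:
        v = self._finite
        return float(np.median(v)) if v.size else np.nan

    @property
    def p10(self) -> float:
        v = self._finite
        return float(np.percentile(v, 10)) if v.size else np.nan

    @property
    def p90(self) -> float:
        v = self._finite
        return float(np.percentile(v, 90)) if v.size else np.nan


@dataclass
class TrialSummary:
    """Per-animal trial summary: ten measures plus binary-state percentages."""

    series: Dict[str, MeasureSeries]
    reverse_fraction: float  # % of defined time spent in reverse
    curl_fraction: float  # % of valid time spent curled
    n_valid_frames: int
    frame_rate: float
    animal_id: int = 0

    def medians(self) -> Dict[str, float]:
        out = {name: s.median for name, s in self.series.items()}
        out["reverse_swimming"] = self.reverse_fraction
        out["curling"] = self.curl_fraction
        return out


def _usable_window(valid: np.ndarray, lo: int, hi: int) -> bool:
    if hi <= lo:
        return False
    return valid[lo:hi].mean() >= _MIN_WINDOW_VALID_FRACTION


def wave_initiation_rate(modes: ModeTrack) -> MeasureSeries:
    """Body waves initiated per minute: 60 * |f_t*|, ignoring direction."""
    vals = np.where(modes.defined, 60.0 * np.abs(modes.f_t), np.nan)
    return MeasureSeries("wave_initiation_rate", vals, "waves/min")


def body_wave_number(modes: ModeTrack) -> MeasureSeries:
    """Wave cycles present on the body at each instant: |f_s*|."""
    vals = np.where(modes.defined, np.abs(modes.f_s), np.nan)
    return MeasureSeries("body_wave_number", vals, "cycles/body")


def asymmetry(cmap: CurvatureMap, clock: StrokeClock) -> MeasureSeries:
    """Mean signed curvature over the body across the two-stroke window.

    Positive = bent clockwise from tail to head (on screen, y down).  Zero
    for a perfectly balanced swimmer.  Group statistics should use the
    absolute value of the per-animal median so left/right preferences do not
    cancel across animals.
    """
    T = cmap.n_frames
    vals = np.full(T, np.nan)
    for t in range(T):
        lo, hi = clock.two_stroke_window(t)
        if not _usable_window(cmap.valid_frames, lo, hi):
            continue
        block = cmap.values[:, lo:hi][:, cmap.valid_frames[lo:hi]]
        vals[t] = block.mean()
    return MeasureSeries("asymmetry", vals, "curvature")


def _segment_ranges(
    cmap: CurvatureMap,
    lo: int,
    hi: int,
    omega: float = np.nan,
) -> Optional[np.ndarray]:
    """Per-segment (max - min) curvature over the valid frames of [lo, hi).

    When the window's stroke (angular) frequency ``omega`` is known, the
    range is taken on a harmonic reconstruction of each segment's series
    (constant + first + second harmonic at the stroke frequency, least
    squares): undulation is single-mode, so the reconstruction preserves the
    true range while per-frame estimation noise - to which a raw max - min
    is maximally sensitive - averages out.  Without a defined stroke
    frequency the raw range is used.
    """
    sel = cmap.valid_frames[lo:hi]
    if not sel.any():
        return None
    block = cmap.values[:, lo:hi][:, sel]
    n = block.shape[1]
    if np.isfinite(omega) and omega > 0 and n >= 8:
        t = np.flatnonzero(sel).astype(float)
        X = np.column_stack(
            [
                np.ones(n),
                np.sin(omega * t),
                np.cos(omega * t),
                np.sin(2 * omega * t),
                np.cos(2 * omega * t),
            ]
        )
        coef, *_ = np.linalg.lstsq(X, block.T, rcond=None)
        fitted = X @ coef  # (n, 12)
        return fitted.max(axis=0) - fitted.min(axis=0)
    return block.max(axis=1) - block.min(axis=1)


def _window_omega(clock: StrokeClock, t: int) -> float:
    """Stroke angular frequency (rad/frame) at frame t, NaN if unknown."""
    D = clock.duration_frames[t]
    if not np.isfinite(D) or D <= 0:
        return np.nan
    return 2.0 * np.pi / D


def stretch(cmap: CurvatureMap, clock: StrokeClock) -> MeasureSeries:
    """Largest curvature range reached by any one body part over two strokes."""
    T = cmap.n_frames
    vals = np.full(T, np.nan)
    for t in range(T):
        lo, hi = clock.two_stroke_window(t)
        if not _usable_window(cmap.valid_frames, lo, hi):
            continue
        r = _segment_ranges(cmap, lo, hi, _window_omega(clock, t))
        if r is not None:
            vals[t] = r.max()
    return MeasureSeries("stretch", vals, "curvature")


def attenuation(
    cmap: CurvatureMap, clock: StrokeClock, range_eps: float = DEFAULT_RANGE_EPS
) -> MeasureSeries:
    """Percent deficit of tail-quarter vs head-quarter curvature range.

    ``100 * (1 - R_tail / R_head)`` over the two-stroke window, where each R
    is the largest per-segment curvature range within the body quarter
    (tail = lowest quarter, rows 0-2; head = upper quarter, rows 9-11).
    0% = equal amplitudes; 100% = active head, motionless tail; negative =
    amplification (seen during reverse swimming).  Undefined when the head
    quarter is essentially motionless (R_head < range_eps).
    """
    T = cmap.n_frames
    vals = np.full(T, np.nan)
    for t in range(T):
        lo, hi = clock.two_stroke_window(t)
        if not _usable_window(cmap.valid_frames, lo, hi):
            continue
        r = _segment_ranges(cmap, lo, hi, _window_omega(clock, t))
        if r is None:
            continue
        r_head = r[_HEAD_ROWS].max()
        r_tail = r[_TAIL_ROWS].max()
        if r_head < range_eps:
            continue
        vals[t] = 100.0 * (1.0 - r_tail / r_head)
    return MeasureSeries("attenuation", vals, "%")


def reverse_swimming(modes: ModeTrack) -> MeasureSeries:
    """Binary per-frame reverse state: 1 where the dominant temporal
    frequency is negative (tail-initiated wave), 0 forward, NaN undefined.
    The trial statistic is the percentage of defined frames in reverse."""
    vals = np.where(modes.defined, (modes.f_t < 0).astype(float), np.nan)
    return MeasureSeries("reverse_swimming", vals, "reverse (0/1)")


def reverse_percentage(modes: ModeTrack) -> float:
    d = modes.defined
    if not d.any():
        return np.nan
    return float(100.0 * np.mean(modes.f_t[d] < 0))


def curling(
    track: Sequence[Centerline], n_dense: int = 101
) -> MeasureSeries:
    """Binary per-frame curl state from posture.

    The curl score is the smaller, over the two body extremities, of the
    distance from the extremity tip to the nearest centerline point at arc
    separation >= L/2; a frame is curled when the score is <= L/3
    (inclusive), which fires on closed "O" shapes, "6" shapes, and postures
    in between.
    """
    T = len(track)
    vals = np.full(T, np.nan)
    for t, c in enumerate(track):
        if not c.valid:
            continue
        try:
            fine = resample_centerline(c, n_dense)
            L = body_length(fine)
        except Exception:
            continue
        pts = fine.points
        u = np.linspace(0.0, 1.0, n_dense)
        d_tail = np.linalg.norm(pts[u >= 0.5] - pts[0], axis=1).min()
        d_head = np.linalg.norm(pts[u <= 0.5] - pts[-1], axis=1).min()
        score = min(d_tail, d_head)
        vals[t] = float(score <= L / 3.0)
    return MeasureSeries("curling", vals, "curled (0/1)")


def curl_percentage(curl_series: MeasureSeries) -> float:
    v = curl_series._finite
    if v.size == 0:
        return np.nan
    return float(100.0 * v.mean())


def travel_speed(
    track: Sequence[Centerline],
    cmap: CurvatureMap,
    clock: StrokeClock,
) -> MeasureSeries:
    """Directed displacement of the stroke-averaged body center, in body
    lengths per second.

    The body center is averaged over one stroke on each side of the current
    frame; the speed is the distance between those two averaged centers per
    stroke duration.  Averaging over a full stroke cancels the lateral
    back-and-forth wobble of undulation, leaving directional travel.
    """
    T = len(track)
    vals = np.full(T, np.nan)
    centers = np.full((T, 2), np.nan)
    for t, c in enumerate(track):
        if c.valid and cmap.valid_frames[t]:
            centers[t] = body_center(c)

    def stroke_mean(tau: float):
        lo, hi = clock.one_stroke_window(tau)
        if hi <= lo:
            return None, np.nan
        block = centers[lo:hi]
        ok = np.isfinite(block[:, 0])
        if ok.mean() < _MIN_WINDOW_VALID_FRACTION:
            return None, np.nan
        used = np.arange(lo, hi)[ok]
        return block[ok].mean(axis=0), float(used.mean())

    for t in range(T):
        D = clock.duration_frames[t]
        if not np.isfinite(D) or not cmap.valid_frames[t]:
            continue
        a, ta = stroke_mean(t - D / 2.0)
        b, tb = stroke_mean(t + D / 2.0)
        if a is None or b is None or not (tb > ta):
            continue
        L = cmap.body_length_px[t]
        if not np.isfinite(L) or L <= 0:
            continue
        # normalize by the actual mean-frame separation of the two windows:
        # integer-frame clipping otherwise biases short strokes
        vals[t] = np.linalg.norm(b - a) * cmap.frame_rate / ((tb - ta) * L)
    return MeasureSeries("travel_speed", vals, "body lengths/s")


# ---------------------------------------------------------------------------
# brush stroke: normalized-raster painting


def _stamp_tube(canvas: np.ndarray, pts: np.ndarray, hw: np.ndarray) -> None:
    """Paint one round-capped tube (raster coordinates) onto a bool canvas."""
    H, W = canvas.shape
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n_steps = max(int(arc[-1] / 0.5), 2)
    targ = np.linspace(0.0, arc[-1], n_steps)
    xs = np.interp(targ, arc, pts[:, 0])
    ys = np.interp(targ, arc, pts[:, 1])
    rs = np.interp(targ, arc, hw)
    rmax = int(np.ceil(rs.max())) + 1
    offs = np.arange(-rmax, rmax + 1)
    ox, oy = np.meshgrid(offs, offs)
    for x, y, r in zip(xs, ys, rs):
        cx, cy = int(round(x)), int(round(y))
        fx, fy = x - cx, y - cy
        # fractional center: unbiased coverage for thin tubes
        m = (ox - fx) ** 2 + (oy - fy) ** 2 <= r * r
        canvas[cy - rmax : cy + rmax + 1, cx - rmax : cx + rmax + 1] |= m


def _raster_footprints(
    track: Sequence[Centerline], cmap: CurvatureMap
) -> tuple:
    """Rasterize body tubes on a shared normalized canvas (body length =
    BRUSH_RASTER_UNITS).

    Returns (swept, static_sizes, canvas_shape): ``swept[t]`` is a flat int
    array of canvas pixels covered while moving from posture t toward
    posture t+1 (sub-frame interpolated, so the union of swept footprints is
    the true painted area independent of frame rate); ``static_sizes[t]`` is
    the pixel count of the stationary body at t (the denominator).
    """
    T = len(track)
    L_ref = np.nanmean(cmap.body_length_px)
    if not np.isfinite(L_ref) or L_ref <= 0:
        return [None] * T, np.zeros(T), (1, 1)
    scale = BRUSH_RASTER_UNITS / L_ref
    mins = np.full(2, np.inf)
    maxs = np.full(2, -np.inf)
    margin = 0.0
    ok = np.zeros(T, dtype=bool)
    for t, c in enumerate(track):
        if not (c.valid and cmap.valid_frames[t]):
            continue
        ok[t] = True
        mins = np.minimum(mins, c.points.min(axis=0))
        maxs = np.maximum(maxs, c.points.max(axis=0))
        margin = max(margin, c.half_widths.max())
    if not np.isfinite(mins).all():
        return [None] * T, np.zeros(T), (1, 1)
    pad = (margin + 2.0 / scale) * scale
    origin = mins * scale - pad
    W = int(np.ceil((maxs[0] - mins[0]) * scale + 2 * pad)) + 2
    H = int(np.ceil((maxs[1] - mins[1]) * scale + 2 * pad)) + 2

    swept: List[Optional[np.ndarray]] = [None] * T
    static_sizes = np.zeros(T)
    for t in range(T):
        if not ok[t]:
            continue
        c = track[t]
        pts = c.points * scale - origin
        hw = np.maximum(c.half_widths * scale, 1.0)
        canvas = np.zeros((H, W), dtype=bool)
        _stamp_tube(canvas, pts, hw)
        static_sizes[t] = int(canvas.sum())
        # sub-frame interpolation toward the next valid posture: the painted
        # area is the continuously swept region, not discrete snapshots
        if t + 1 < T and ok[t + 1] and track[t + 1].n_points == c.n_points:
            nxt = track[t + 1].points * scale - origin
            disp = np.linalg.norm(nxt - pts, axis=1).max()
            n_sub = int(np.ceil(disp / 1.5))
            for k in range(1, n_sub + 1):
                w = k / (n_sub + 1)
                _stamp_tube(canvas, pts * (1 - w) + nxt * w, hw)
        swept[t] = np.flatnonzero(canvas)
    return swept, static_sizes, (H, W)


def brush_stroke(
    track: Sequence[Centerline],
    cmap: CurvatureMap,
    clock: StrokeClock,
    smooth: bool = True,
) -> MeasureSeries:
    """Area painted by the body over two strokes, in units of body area.

    The body tube is rasterized on a normalized canvas (body length = 128
    raster units, round tube caps); the value at frame t is

        (pixels covered during [t - D, t + D)) / (pixels of the body at t) - 1

    i.e. 0 for a frozen, non-translating animal.  The series is smoothed by
    a two-stroke moving average (successive stroke pairs).
    """
    T = len(track)
    vals = np.full(T, np.nan)
    footprints, static_sizes, (H, W) = _raster_footprints(track, cmap)
    counts = np.zeros(H * W, dtype=np.int32)
    nnz = 0
    lo_cur, hi_cur = 0, 0

    def add(t):
        nonlocal nnz
        fp = footprints[t]
        if fp is None:
            return
        c = counts[fp]
        nnz += int((c == 0).sum())
        counts[fp] = c + 1

    def remove(t):
        nonlocal nnz
        fp = footprints[t]
        if fp is None:
            return
        c = counts[fp] - 1
        nnz -= int((c == 0).sum())
        counts[fp] = c

    for t in range(T):
        lo, hi = clock.two_stroke_window(t)
        if not _usable_window(cmap.valid_frames, lo, hi) or footprints[t] is None:
            continue
        # slide the union window incrementally
        while lo_cur < lo:
            remove(lo_cur)
            lo_cur += 1
        while lo_cur > lo:
            lo_cur -= 1
            add(lo_cur)
        while hi_cur < hi:
            add(hi_cur)
            hi_cur += 1
        while hi_cur > hi:
            hi_cur -= 1
            remove(hi_cur)
        body = static_sizes[t]
        if body > 0:
            vals[t] = nnz / body - 1.0
    if smooth:
        sm = np.full(T, np.nan)
        for t in range(T):
            lo, hi = clock.two_stroke_window(t)
            if hi <= lo:
                continue
            block = vals[lo:hi]
            ok = np.isfinite(block)
            if ok.any() and np.isfinite(vals[t]):
                sm[t] = block[ok].mean()
        vals = sm
    return MeasureSeries("brush_stroke", vals, "body areas")


def activity_index(
    brush: MeasureSeries, clock: StrokeClock, frame_rate: float
) -> MeasureSeries:
    """Brush stroke per unit time: value / (2 * D / frame_rate), in body
    areas per second - the vigor of bending effort."""
    D = clock.duration_frames
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = brush.values / (2.0 * D / frame_rate)
    return MeasureSeries("activity_index", vals, "body areas/s")


def summarize_trial(
    track: Sequence[Centerline],
    cmap: CurvatureMap,
    modes: ModeTrack,
    clock: StrokeClock,
    animal_id: int = 0,
    measures: Optional[Sequence[str]] = None,
    range_eps: float = DEFAULT_RANGE_EPS,
) -> TrialSummary:
    """Compute the requested measures (default: all ten) and summarize.

    Raises ValueError naming the cause when nothing can be summarized
    (all frames invalid, or no dominant mode anywhere in the trial).
    """
    if measures is None:
        measures = MEASURE_NAMES
    n_valid = int(cmap.valid_frames.sum())
    if n_valid == 0:
        raise ValueError("cannot summarize trial: all frames are invalid")
    if not clock.any_defined and not modes.defined.any():
        raise ValueError(
            "cannot summarize trial: no frame has a dominant spectral mode"
        )
    series: Dict[str, MeasureSeries] = {}
    if "wave_initiation_rate" in measures:
        series["wave_initiation_rate"] = wave_initiation_rate(modes)
    if "body_wave_number" in measures:
        series["body_wave_number"] = body_wave_number(modes)
    if "asymmetry" in measures:
        series["asymmetry"] = asymmetry(cmap, clock)
    if "stretch" in measures:
        series["stretch"] = stretch(cmap, clock)
    if "attenuation" in measures:
        series["attenuation"] = attenuation(cmap, clock, range_eps)
    if "reverse_swimming" in measures:
        series["reverse_swimming"] = reverse_swimming(modes)
    if "curling" in measures:
        series["curling"] = curling(track) if len(track) else MeasureSeries(
            "curling", np.full(cmap.n_frames, np.nan), "curled (0/1)"
        )
    if "travel_speed" in measures:
        series["travel_speed"] = travel_speed(track, cmap, clock)
    brush = None
    if "brush_stroke" in measures or "activity_index" in measures:
        brush = brush_stroke(track, cmap, clock)
    if "brush_stroke" in measures:
        series["brush_stroke"] = brush
    if "activity_index" in measures:
        series["activity_index"] = activity_index(brush, clock, cmap.frame_rate)
    rev = reverse_percentage(modes) if "reverse_swimming" in measures else np.nan
    curl = (
        curl_percentage(series["curling"]) if "curling" in series else np.nan
    )
    return TrialSummary(
        series=series,
        reverse_fraction=rev,
        curl_fraction=curl,
        n_valid_frames=n_valid,
        frame_rate=cmap.frame_rate,
        animal_id=animal_id,
    )
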