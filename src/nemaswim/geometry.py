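"""Centerline geometry and the curvature kymograph.

A swimming nematode is represented at each video frame by its *centerline*
(the mid-body line of lateral symmetry), parameterized by the curvilinear
coordinate ``s`` from tail (``s = 0``) to head (``s = 1``), together with the
body half-width at each point.  All downstream behavioral measures read a
single derived object: the :class:`CurvatureMap`, a 12-segment x T-frame
matrix of signed, dimensionless curvature ``k_hat = kappa * L`` (curvature
times body length).  Normalizing by body length makes every curvature-based
measure independent of image resolution and animal size.

Sign convention: image coordinates with the y axis pointing down; positive
``k_hat`` means the tangent turns clockwise as seen on screen when traversing
the body tail-to-head.  An animal bent clockwise from tail to head therefore
scores positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "Centerline",
    "CurvatureMap",
    "InvalidGeometryError",
    "N_SEGMENTS",
    "N_CANONICAL_POINTS",
    "SEGMENT_MIDPOINTS",
    "resample_centerline",
    "body_length",
    "compute_curvature",
    "build_curvature_map",
    "body_center",
]

#: Number of equally long body segments the curvilinear coordinate is
#: discretized into; one curvature score per segment per frame.
N_SEGMENTS = 12

#: Canonical polyline point count (segment boundaries, tail to head).
N_CANONICAL_POINTS = N_SEGMENTS + 1

#: Arc-length positions of segment midpoints, s in (0, 1).
SEGMENT_MIDPOINTS = (np.arange(N_SEGMENTS) + 0.5) / N_SEGMENTS

# Points closer than this (pixels) are treated as duplicates.
_DUP_TOL = 1e-9

# Internal fine sampling used for curvature fitting and arc integrals.
_N_FINE = 121


class InvalidGeometryError(ValueError):
    """Raised for degenerate centerline geometry (zero length, single point...)."""


@dataclass
class Centerline:
    """One animal's centerline at one time frame.

    Parameters
    ----------
    points : (N, 2) array
        Ordered image coordinates in pixels, tail first, head last.
    half_widths : (N,) array
        Body half-width (pixels) at each point.
    frame_index : int
        Time stamp (frame number within the trial).
    valid : bool
        Frame-quality flag; invalid frames are excluded from all statistics.
    """

    points: np.ndarray
    half_widths: np.ndarray
    frame_index: int = 0
    valid: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.half_widths = np.asarray(self.half_widths, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidGeometryError("points must be an (N, 2) array")
        if self.points.shape[0] < 2:
            raise InvalidGeometryError("a centerline needs at least 2 points")
        if self.half_widths.shape != (self.points.shape[0],):
            raise InvalidGeometryError("half_widths must match points")
        if np.any(self.half_widths < 0):
            raise InvalidGeometryError("half_widths must be non-negative")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def reversed(self) -> "Centerline":
        """Head-tail relabeled copy (point order reversed)."""
        return replace(
            self,
            points=self.points[::-1].copy(),
            half_widths=self.half_widths[::-1].copy(),
        )


def _dedupe(points: np.ndarray, half_widths: np.ndarray):
    """Collapse consecutive (near-)duplicate vertices."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], seg > _DUP_TOL])
    return points[keep], half_widths[keep]


def _arc_positions(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def body_length(c: Centerline) -> float:
    """Total arc length of the centerline polyline, in pixels."""
    pts, _ = _dedupe(c.points, c.half_widths)
    if pts.shape[0] < 2:
        raise InvalidGeometryError("centerline has zero length")
    return float(_arc_positions(pts)[-1])


def _fine_curve(c: Centerline, n_fine: int = _N_FINE):
    """Resample onto a fine, arc-length-uniform grid via a parametric cubic
    spline.  Returns (points, half_widths, arc_positions, total_length)."""
    pts, hw = _dedupe(c.points, c.half_widths)
    if pts.shape[0] < 2:
        raise InvalidGeometryError("centerline has zero length")
    u = _arc_positions(pts)
    if u[-1] <= 0:
        raise InvalidGeometryError("centerline has zero length")
    if pts.shape[0] < 4:
        # too few points for a cubic; fall back to linear interpolation
        dense_u = np.linspace(0.0, u[-1], 8 * n_fine)
        dense = np.column_stack(
            [np.interp(dense_u, u, pts[:, 0]), np.interp(dense_u, u, pts[:, 1])]
        )
    else:
        spl = CubicSpline(u, pts, axis=0, bc_type="not-a-knot")
        dense_u = np.linspace(0.0, u[-1], 8 * n_fine)
        dense = spl(dense_u)
    # reparameterize the dense curve by its own arc length
    s_dense = _arc_positions(dense)
    total = s_dense[-1]
    targets = np.linspace(0.0, total, n_fine)
    fine = np.column_stack(
        [np.interp(targets, s_dense, dense[:, 0]), np.interp(targets, s_dense, dense[:, 1])]
    )
    # half-widths: interpolate on the original chord-length parameter
    hw_fine = np.interp(targets * (u[-1] / total), u, hw)
    return fine, hw_fine, targets, float(total)


def resample_centerline(raw: Centerline, n_points: int) -> Centerline:
    """Resample a centerline to ``n_points`` points equally spaced in arc length.

    Duplicate vertices are collapsed first.  A parametric cubic spline is used
    so that coarsely sampled smooth bodies (e.g. a few points on a circular
    arc) are reconstructed faithfully; half-widths are interpolated along arc
    length.
    """
    if raw.n_points < 2:
        raise InvalidGeometryError("need at least 2 points to resample")
    if n_points < 2:
        raise InvalidGeometryError("n_points must be >= 2")
    fine, hw_fine, s_fine, total = _fine_curve(raw, n_fine=max(8 * n_points, _N_FINE))
    targets = np.linspace(0.0, total, n_points)
    pts = np.column_stack(
        [np.interp(targets, s_fine, fine[:, 0]), np.interp(targets, s_fine, fine[:, 1])]
    )
    hw = np.interp(targets, s_fine, hw_fine)
    return replace(raw, points=pts, half_widths=hw)


def body_center(c: Centerline) -> np.ndarray:
    """Arc-length-weighted centroid of the centerline (2-vector, pixels)."""
    fine, _, _, _ = _fine_curve(c)
    mids = 0.5 * (fine[1:] + fine[:-1])
    seg = np.linalg.norm(np.diff(fine, axis=0), axis=1)
    w = seg / seg.sum()
    return mids.T @ w


def _circle_fit_kappa(pts: np.ndarray) -> float:
    """Unsigned curvature (1/R) of the least-squares (Kasa) circle through pts.

    Returns 0.0 for collinear windows.
    """
    ctr = pts.mean(axis=0)
    q = pts - ctr
    x, y = q[:, 0], q[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return 0.0
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx * cx + cy * cy
    if r2 <= 0:
        return 0.0
    return float(1.0 / np.sqrt(r2))


def compute_curvature(c: Centerline, window_fraction: float = 1.0 / N_SEGMENTS) -> np.ndarray:
    """Signed dimensionless curvature at the 12 segment midpoints.

    Curvature is the derivative of the tangent direction with respect to the
    curvilinear coordinate.  At each segment midpoint it is estimated as the
    least-squares slope of the unwrapped tangent angle against arc length
    over the surrounding arc of length ``window_fraction * L`` (default: one
    body segment, L/12) - equivalently, the inverse radius of the best-fit
    circle through that arc, signed by turning direction, but immune to the
    algebraic circle fit's collapse at inflection points.  The sign is
    positive for clockwise turning on screen (image y axis down); the result
    is multiplied by the body length L, so a body lying on a circle of
    radius L/2 scores magnitude 2 everywhere.  Straight windows score 0.
    """
    if not (0.0 < window_fraction <= 0.5):
        raise ValueError("window_fraction must be in (0, 0.5]")
    fine, _, s_fine, total = _fine_curve(c)
    if total <= 0:
        raise InvalidGeometryError("centerline has zero length")
    u = s_fine / total  # normalized arc position in [0, 1]
    half_w = window_fraction / 2.0
    tangents = np.diff(fine, axis=0)
    theta = np.unwrap(np.arctan2(tangents[:, 1], tangents[:, 0]))
    s_mid = 0.5 * (s_fine[1:] + s_fine[:-1])  # tangent sample positions
    u_mid = s_mid / total
    out = np.empty(N_SEGMENTS)
    for k, m in enumerate(SEGMENT_MIDPOINTS):
        sel = (u_mid >= m - half_w) & (u_mid <= m + half_w)
        idx = np.flatnonzero(sel)
        if idx.size < 2:  # widen degenerate windows
            center = np.argmin(np.abs(u_mid - m))
            idx = np.arange(max(0, center - 2), min(len(u_mid), center + 3))
        s_w = s_mid[idx] - s_mid[idx].mean()
        th_w = theta[idx]
        denom = np.dot(s_w, s_w)
        slope = np.dot(s_w, th_w - th_w.mean()) / denom if denom > 0 else 0.0
        out[k] = slope * total
    return out


@dataclass
class CurvatureMap:
    """Curvature kymograph: 12 segments x T frames of dimensionless curvature.

    Row 0 is the tail-most segment, row 11 the head-most.  Columns of invalid
    frames are NaN and masked out of every downstream statistic.  The posture
    at any time is reconstructible from its column up to rigid motion.
    """

    values: np.ndarray  # (12, T)
    frame_rate: float
    valid_frames: np.ndarray  # (T,) bool
    body_length_px: np.ndarray  # (T,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != N_SEGMENTS:
            raise ValueError(f"values must have exactly {N_SEGMENTS} rows")
        self.valid_frames = np.asarray(self.valid_frames, dtype=bool)
        self.body_length_px = np.asarray(self.body_length_px, dtype=float)
        if self.valid_frames.shape != (self.n_frames,):
            raise ValueError("valid_frames length mismatch")
        if self.body_length_px.shape != (self.n_frames,):
            raise ValueError("body_length_px length mismatch")
        if not np.all(np.isfinite(self.values[:, self.valid_frames])):
            raise ValueError("curvature must be finite on valid frames")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def reversed(self) -> "CurvatureMap":
        """Head-tail relabeled map: rows flipped and curvature sign negated."""
        return CurvatureMap(
            values=-self.values[::-1].copy(),
            frame_rate=self.frame_rate,
            valid_frames=self.valid_frames.copy(),
            body_length_px=self.body_length_px.copy(),
        )


def build_curvature_map(
    track,
    frame_rate: float,
    window_fraction: float = 1.0 / N_SEGMENTS,
) -> CurvatureMap:
    """Build the curvature kymograph from one animal's chronological track.

    Parameters
    ----------
    track : sequence of Centerline
        All frames of one animal, in chronological order.
    frame_rate : float
        Frames per second.
    """
    track = list(track)
    if not track:
        raise ValueError("empty track")
    T = len(track)
    values = np.full((N_SEGMENTS, T), np.nan)
    valid = np.zeros(T, dtype=bool)
    lengths = np.full(T, np.nan)
    for t, c in enumerate(track):
        if not c.valid:
            continue
        try:
            lengths[t] = body_length(c)
            values[:, t] = compute_curvature(c, window_fraction=window_fraction)
            valid[t] = True
        except InvalidGeometryError:
            valid[t] = False
    return CurvatureMap(
        values=values, frame_rate=frame_rate, valid_frames=valid, body_length_px=lengths
    )
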