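"""Synthetic swimmer generator: ground-truth tracks and rendered videos.

Synthesis happens in curvature space: the behavioral measures are defined on
the curvature kymograph, so generating the kymograph directly makes every
ground-truth value exact by construction (hydrodynamics is deliberately out
of scope).  A scenario specifies the traveling-wave parameters

    k_hat(s, t) = A * e(s) * sin(2*pi*n*s + phi(t)) + c

with temporal phase ``phi`` advancing at ``+2*pi*f`` per second during
forward swimming and ``-2*pi*f`` inside reverse episodes (phase-continuous
across switches, so reversals do not splatter the spectrum).  The amplitude
envelope ``e(s) = 1 - alpha*g(s)`` uses a plateau-ramp profile: ``g = 1``
over the tail quarter, ``0`` over the head quarter, linear in between, so
the tail-quarter/head-quarter amplitude ratio is exactly ``1 - alpha`` and
the measured attenuation is exactly ``100*alpha`` %.

Curl episodes override the wave with a closed "O" (constant ``k_hat = 2*pi``)
or a "6" (straight tail half, head half curled nearly closed).  Postures are
reconstructed from each kymograph column by integrating the tangent angle,
and can be rendered into noisy grayscale video (dark worms on a light
background) for tracking benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .geometry import (
    N_SEGMENTS,
    SEGMENT_MIDPOINTS,
    Centerline,
    CurvatureMap,
)

__all__ = [
    "SwimScenario",
    "generate_curvature",
    "integrate_posture",
    "generate_track",
    "render_video",
    "render_scene",
    "write_tiff",
]

#: Constant dimensionless curvature of the closed "O" curl posture.
CURL_O_KAPPA = 2.0 * np.pi
#: Head-half curvature of the "6" curl posture: the head half (length L/2)
#: turns through 1.8*pi, leaving the tip within L/3 of the mid-body.
CURL_SIX_KAPPA = 3.6 * np.pi


def default_half_width_profile(s: np.ndarray) -> np.ndarray:
    """Tapered body radius in units of body length (max ~4% of L mid-body)."""
    return 0.04 * np.sqrt(np.clip(1.0 - (2.0 * s - 1.0) ** 2, 0.0, 1.0)) + 0.004


@dataclass
class SwimScenario:
    """Parameters of one synthetic swim trial.

    Defaults describe a vigorous young-adult swimmer: 1.5 Hz stroke
    frequency, 1.5 wave cycles on the body, deep bends (amplitude 3 in
    curvature-per-body-length units), 30 s at 18 frames/s, body 100 px long
    at the nominal 0.02 mm/px magnification.
    """

    f: float = 1.5  # wave temporal frequency, Hz
    n: float = 1.5  # body wave number, cycles per body length
    A: float = 3.0  # curvature amplitude, per body length
    bias_c: float = 0.0  # constant curvature offset (side bias)
    attenuation_alpha: float = 0.0  # tail amplitude deficit fraction [0, 1]
    reverse_episodes: Tuple[Tuple[int, int], ...] = ()  # half-open frame intervals
    curl_episodes: Tuple[Tuple[Tuple[int, int], str], ...] = ()  # (interval, "O"|"six")
    drift_v: float = 0.0  # translation speed, body lengths / s
    drift_direction: Tuple[float, float] = (1.0, 0.0)
    L_px: float = 100.0  # body length in pixels
    half_width_profile: Callable[[np.ndarray], np.ndarray] = default_half_width_profile
    fps: float = 18.0
    duration_s: float = 30.0
    noise_sigma: float = 5.0  # additive Gaussian noise (8-bit gray levels)
    seed: int = 0
    phase0: float = 0.0  # initial wave phase, radians
    start: Tuple[float, float] = (0.0, 0.0)  # initial body center, px
    heading: float = 0.0  # initial tail tangent angle, radians

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def validate(self) -> None:
        T = self.n_frames
        episodes = [iv for iv in self.reverse_episodes] + [
            iv for iv, _ in self.curl_episodes
        ]
        for lo, hi in episodes:
            if not (0 <= lo < hi <= T):
                raise ValueError(f"episode ({lo}, {hi}) outside trial of {T} frames")
        for shape_iv, shape in self.curl_episodes:
            if shape not in ("O", "six"):
                raise ValueError(f"unknown curl shape {shape!r}")
        spans = sorted(episodes)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
            if b_lo < a_hi:
                raise ValueError("episodes overlap")
        if not np.isfinite(
            [self.f, self.n, self.A, self.bias_c, self.attenuation_alpha, self.drift_v]
        ).all():
            raise ValueError("scenario parameters must be finite")


def amplitude_envelope(s: np.ndarray, alpha: float) -> np.ndarray:
    """Plateau-ramp envelope: tail quarter scaled by (1 - alpha), head quarter
    unscaled, linear ramp between the quarters."""
    g = np.clip((0.75 - np.asarray(s)) / 0.5, 0.0, 1.0)
    return 1.0 - alpha * g


def _direction_sign(scn: SwimScenario) -> np.ndarray:
    sigma = np.ones(scn.n_frames)
    for lo, hi in scn.reverse_episodes:
        sigma[lo:hi] = -1.0
    return sigma


def _curl_frames(scn: SwimScenario) -> dict:
    out = {}
    for (lo, hi), shape in scn.curl_episodes:
        for t in range(lo, hi):
            out[t] = shape
    return out


def generate_curvature(scn: SwimScenario) -> Tuple[CurvatureMap, dict]:
    """Ground-truth curvature kymograph plus the exact measure values.

    Returns (CurvatureMap, truth) where truth holds the values the measures
    should recover: wave_initiation_rate = 60*f, body_wave_number = n,
    asymmetry = bias_c, stretch = 2*A, attenuation = 100*alpha,
    reverse_pct / curl_pct = episode fractions, travel_speed = |drift_v|.
    """
    scn.validate()
    T = scn.n_frames
    sigma = _direction_sign(scn)
    # phase-continuous temporal phase: phi(t) = phase0 + 2*pi*f*sum(sigma)/fps
    dphi = 2.0 * np.pi * scn.f * sigma / scn.fps
    phi = scn.phase0 + np.concatenate([[0.0], np.cumsum(dphi[:-1])])
    s = SEGMENT_MIDPOINTS
    env = amplitude_envelope(s, scn.attenuation_alpha)
    vals = (
        scn.A * env[:, None] * np.sin(2.0 * np.pi * scn.n * s[:, None] + phi[None, :])
        + scn.bias_c
    )
    curls = _curl_frames(scn)
    for t, shape in curls.items():
        if shape == "O":
            vals[:, t] = CURL_O_KAPPA
        else:  # "6": straight tail half, tightly curled head half
            vals[:, t] = np.where(s < 0.5, 0.0, CURL_SIX_KAPPA)
    cmap = CurvatureMap(
        values=vals,
        frame_rate=scn.fps,
        valid_frames=np.ones(T, dtype=bool),
        body_length_px=np.full(T, scn.L_px),
    )
    n_rev = sum(hi - lo for lo, hi in scn.reverse_episodes)
    n_curl = len(curls)
    truth = {
        "wave_initiation_rate": 60.0 * abs(scn.f),
        "body_wave_number": abs(scn.n),
        "asymmetry": scn.bias_c,
        "stretch": 2.0 * scn.A,
        "attenuation": 100.0 * scn.attenuation_alpha,
        "reverse_pct": 100.0 * n_rev / T,
        "curl_pct": 100.0 * n_curl / T,
        "travel_speed": abs(scn.drift_v),
    }
    return cmap, truth


def integrate_posture(
    kappa_hat: np.ndarray,
    L_px: float,
    center: Tuple[float, float] = (0.0, 0.0),
    heading: float = 0.0,
    half_width_profile: Callable[[np.ndarray], np.ndarray] = default_half_width_profile,
    n_points: int = 49,
    frame_index: int = 0,
) -> Centerline:
    """Reconstruct a posture from the 12 segment-midpoint curvatures.

    The tangent angle is the cumulative integral of ``kappa_hat`` over the
    normalized arc coordinate (midpoint values interpolated linearly,
    extended flat at the ends); positions are the cumulative integral of the
    tangent, scaled to ``L_px`` and placed with the requested arc-length
    centroid and initial heading.
    """
    kappa_hat = np.asarray(kappa_hat, dtype=float)
    if kappa_hat.shape != (N_SEGMENTS,):
        raise ValueError(f"expected {N_SEGMENTS} curvature values")
    u = np.linspace(0.0, 1.0, 8 * n_points + 1)
    if np.ptp(kappa_hat) > 0 and np.all(np.isfinite(kappa_hat)):
        # smooth (spline) reconstruction between the 12 midpoint samples;
        # falls back to linear for postures with curvature discontinuities
        from scipy.interpolate import CubicSpline

        jumps = np.abs(np.diff(kappa_hat))
        if jumps.max() < 4.0 * max(np.median(jumps), 1e-12):
            # interior spline, flat extension beyond the end midpoints
            spl = CubicSpline(SEGMENT_MIDPOINTS, kappa_hat, bc_type="not-a-knot")
            k_u = spl(np.clip(u, SEGMENT_MIDPOINTS[0], SEGMENT_MIDPOINTS[-1]))
        else:
            k_u = np.interp(u, SEGMENT_MIDPOINTS, kappa_hat)
    else:
        k_u = np.interp(u, SEGMENT_MIDPOINTS, kappa_hat)
    # theta(u) = heading + integral of kappa_hat du   (d theta/ds = kappa, s = u*L)
    du = u[1] - u[0]
    theta = heading + np.concatenate(
        [[0.0], np.cumsum(0.5 * (k_u[1:] + k_u[:-1]) * du)]
    )
    tx, ty = np.cos(theta), np.sin(theta)
    x = np.concatenate([[0.0], np.cumsum(0.5 * (tx[1:] + tx[:-1]) * du)]) * L_px
    y = np.concatenate([[0.0], np.cumsum(0.5 * (ty[1:] + ty[:-1]) * du)]) * L_px
    pts = np.column_stack([x, y])
    # place the arc-length centroid at the requested center
    mids = 0.5 * (pts[1:] + pts[:-1])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    centroid = mids.T @ (seg / seg.sum())
    pts = pts - centroid + np.asarray(center, dtype=float)
    sel = np.linspace(0, len(u) - 1, n_points).round().astype(int)
    hw = half_width_profile(u[sel]) * L_px
    return Centerline(points=pts[sel], half_widths=hw, frame_index=frame_index)


def generate_track(
    scn: SwimScenario, n_points: int = 49
) -> Tuple[List[Centerline], CurvatureMap, dict]:
    """Ground-truth centerline track + kymograph + truth record for a scenario."""
    cmap, truth = generate_curvature(scn)
    d = np.asarray(scn.drift_direction, dtype=float)
    d = d / np.linalg.norm(d)
    start = np.asarray(scn.start, dtype=float)
    track = []
    for t in range(scn.n_frames):
        center = start + d * (scn.drift_v * scn.L_px * t / scn.fps)
        track.append(
            integrate_posture(
                cmap.values[:, t],
                scn.L_px,
                center=tuple(center),
                heading=scn.heading,
                half_width_profile=scn.half_width_profile,
                n_points=n_points,
                frame_index=t,
            )
        )
    return track, cmap, truth


# ---------------------------------------------------------------------------
# rendering


def _stamp_worm(canvas: np.ndarray, c: Centerline, value: float, scale: int) -> None:
    """Paint the body tube (centerline +/- half-width, round caps) onto a
    supersampled canvas by disc stamping along a finely resampled polyline."""
    H, W = canvas.shape
    pts = c.points * scale
    hw = c.half_widths * scale
    # resample the polyline to ~0.5 px steps on the supersampled grid
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n_steps = max(int(arc[-1] / 0.5), 2)
    targets = np.linspace(0.0, arc[-1], n_steps)
    xs = np.interp(targets, arc, pts[:, 0])
    ys = np.interp(targets, arc, pts[:, 1])
    rs = np.interp(targets, arc, hw)
    rmax = int(np.ceil(rs.max())) + 1
    offs = np.arange(-rmax, rmax + 1)
    ox, oy = np.meshgrid(offs, offs)
    dist2 = ox**2 + oy**2
    for x, y, r in zip(xs, ys, rs):
        mask = dist2 <= r * r
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = cx - rmax, cx + rmax + 1
        y0, y1 = cy - rmax, cy + rmax + 1
        if x0 < 0 or y0 < 0 or x1 > W or y1 > H:
            raise ValueError("worm out of rendering bounds")
        region = canvas[y0:y1, x0:x1]
        region[mask] = value


def render_scene(
    tracks: Sequence[Sequence[Centerline]],
    shape: Tuple[int, int],
    noise_sigma: float = 5.0,
    seed: int = 0,
    background: float = 200.0,
    worm_value: float = 60.0,
    supersample: int = 2,
    blur_px: float = 1.0,
) -> np.ndarray:
    """Render one or more ground-truth tracks into a (T, H, W) uint8 video.

    Worms are dark tubes on a light background, anti-aliased by supersampled
    stamping, blurred by ~1 px, with seeded additive Gaussian noise.
    """
    T = len(tracks[0])
    if any(len(tr) != T for tr in tracks):
        raise ValueError("all tracks must have the same number of frames")
    H, W = shape
    rng = np.random.default_rng(seed)
    out = np.empty((T, H, W), dtype=np.uint8)
    ss = supersample
    for t in range(T):
        canvas = np.full((H * ss, W * ss), background, dtype=float)
        for tr in tracks:
            _stamp_worm(canvas, tr[t], worm_value, ss)
        img = canvas.reshape(H, ss, W, ss).mean(axis=(1, 3))
        img = gaussian_filter(img, blur_px)
        img = img + rng.normal(0.0, noise_sigma, img.shape)
        out[t] = np.clip(img, 0, 255).astype(np.uint8)
    return out


def render_video(scn: SwimScenario, shape: Tuple[int, int] = (512, 512)):
    """Render a single-scenario video; returns (frames, track, cmap, truth)."""
    track, cmap, truth = generate_track(scn)
    frames = render_scene(
        [track], shape, noise_sigma=scn.noise_sigma, seed=scn.seed
    )
    return frames, track, cmap, truth


def write_tiff(path, frames: np.ndarray) -> None:
    tifffile.imwrite(path, frames, photometric="minisblack")
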