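"""Short-time 2D Fourier analysis of the curvature kymograph.

Undulatory swimming produces a traveling curvature wave
``k_hat(s, t) ~ A sin(2*pi*(f_s*s + f_t*t))`` whose magnitude spectrum has a
single dominant mode.  Because swimmers alter frequency over seconds, a whole
trial static transform is unsuitable; instead a short-time 2D transform is
computed at every frame over five time windows (32, 40, 48, 56, 64 frames),
resampled onto a common zero-padded frequency raster, and averaged.  The
per-frame dominant mode ``(f_s*, f_t*)`` drives most behavioral measures:

* ``|f_t*|`` (Hz) — wave initiation rate / stroke frequency,
* sign of ``f_t*`` — swimming direction (negative = reverse, tail-initiated),
* ``f_s*`` (cycles per body length) — body wave number.

Conventions: ``s`` runs tail to head, so a head-initiated, head-to-tail wave
gives ``f_t* > 0`` (forward swimming).  The transform of a real map is
centro-symmetric, so only the ``f_s >= 0`` half-plane is retained; the
``f_s = 0`` line carries the postural bias (asymmetry/DC), not the traveling
wave, and is excluded from mode search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal.windows import hann

from .geometry import N_SEGMENTS, CurvatureMap

__all__ = [
    "SPATIAL_BINS",
    "TEMPORAL_BINS",
    "DEFAULT_WINDOWS",
    "SpectralMode",
    "ModeTrack",
    "StrokeClock",
    "spatial_frequencies",
    "temporal_frequencies",
    "stft2d",
    "averaged_stft",
    "find_mode",
    "compute_modes",
    "stroke_clock",
]

#: Zero-padded spatial grid (12 body samples -> 64 bins; bins 0..32 kept).
SPATIAL_BINS = 64
#: Zero-padded temporal grid shared by all window lengths.
TEMPORAL_BINS = 256
#: Short-time window lengths in frames.
DEFAULT_WINDOWS = (32, 40, 48, 56, 64)

#: Fraction of total (non-DC) spectral energy the peak bin must carry for the
#: mode to count as defined; below this the frame has no dominant traveling
#: wave (noise-only / quiescent).  On the zero-padded averaged spectrum a
#: clean wave concentrates >= ~0.015 of the energy in the peak bin even when
#: the wave is fully attenuated along the body, while spatio-temporal white
#: noise stays near 0.001; 0.005 separates the two with margin on both sides.
DEFAULT_MODE_ENERGY_EPS = 0.005

_MIN_VALID_IN_WINDOW = 8
_MIN_VALID_FRACTION = 0.25


def spatial_frequencies() -> np.ndarray:
    """Spatial raster: cycles per body length for bins 0..SPATIAL_BINS/2."""
    return np.arange(SPATIAL_BINS // 2 + 1) * N_SEGMENTS / SPATIAL_BINS


def temporal_frequencies(frame_rate: float) -> np.ndarray:
    """Signed temporal raster in Hz (fftshifted)."""
    return np.fft.fftshift(np.fft.fftfreq(TEMPORAL_BINS, d=1.0 / frame_rate))


@dataclass
class SpectralMode:
    """Dominant mode of one frame's averaged spectrum."""

    f_s_star: float  # cycles per body length, >= 0
    f_t_star: float  # Hz, signed (negative = reverse swimming)
    magnitude: float
    defined: bool

    @classmethod
    def undefined(cls) -> "SpectralMode":
        return cls(np.nan, np.nan, 0.0, False)


@dataclass
class ModeTrack:
    """Per-frame dominant modes for a whole trial (vectorized SpectralMode)."""

    f_s: np.ndarray  # (T,), NaN where undefined
    f_t: np.ndarray  # (T,), signed, NaN where undefined
    magnitude: np.ndarray  # (T,)
    defined: np.ndarray  # (T,) bool
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.f_s.size

    def __getitem__(self, t: int) -> SpectralMode:
        if not self.defined[t]:
            return SpectralMode.undefined()
        return SpectralMode(self.f_s[t], self.f_t[t], self.magnitude[t], True)


def _window_bounds(t: int, window: int, n_frames: int) -> Tuple[int, int]:
    lo = t - window // 2
    hi = lo + window
    return max(0, lo), min(n_frames, hi)


def stft2d(
    cmap: CurvatureMap, t: int, window: int
) -> Optional[np.ndarray]:
    """Magnitude spectrum of the 12 x ``window`` curvature patch centered at ``t``.

    The patch is Hann-tapered along time (no taper along the 12-sample body
    axis), zero-padded to the fixed SPATIAL_BINS x TEMPORAL_BINS raster, and
    only the ``f_s >= 0`` half-plane is returned, with the temporal axis
    fftshifted to signed frequencies.  Invalid frames are zero-filled; the
    spectrum is undefined (None) when fewer than 8 frames, or under 25% of
    the window, are valid.
    """
    lo, hi = _window_bounds(t, window, cmap.n_frames)
    if hi <= lo:
        return None
    valid = cmap.valid_frames[lo:hi]
    n_valid = int(valid.sum())
    if n_valid < _MIN_VALID_IN_WINDOW or n_valid < _MIN_VALID_FRACTION * window:
        return None
    patch = np.where(valid, np.nan_to_num(cmap.values[:, lo:hi]), 0.0)
    taper = hann(hi - lo, sym=False)
    patch = patch * taper
    spec = np.fft.rfft(patch, n=SPATIAL_BINS, axis=0)  # f_s >= 0 half-plane
    spec = np.fft.fft(spec, n=TEMPORAL_BINS, axis=1)
    spec = np.fft.fftshift(spec, axes=1)
    return np.abs(spec)


def averaged_stft(
    cmap: CurvatureMap, t: int, windows: Tuple[int, ...] = DEFAULT_WINDOWS
) -> Optional[np.ndarray]:
    """Pointwise mean of the five window spectra on the shared raster.

    Windows falling off the trial edge contribute their valid truncation.
    Returns None when every window is undefined.
    """
    acc = None
    n = 0
    for w in windows:
        s = stft2d(cmap, t, w)
        if s is None:
            continue
        acc = s if acc is None else acc + s
        n += 1
    if acc is None:
        return None
    return acc / n


def dump_spectra_hdf5(
    cmap: CurvatureMap,
    path,
    windows: Tuple[int, ...] = DEFAULT_WINDOWS,
    stride: int = 1,
) -> None:
    """Debug dump: per-frame averaged spectra to an HDF5 file.

    Dataset ``spectra`` has shape (n_frames, 33, 256) with NaN planes for
    undefined frames; ``f_s`` and ``f_t`` carry the frequency rasters.
    """
    import h5py

    frames = range(0, cmap.n_frames, stride)
    out = np.full((len(frames), SPATIAL_BINS // 2 + 1, TEMPORAL_BINS), np.nan)
    for k, t in enumerate(frames):
        spec = averaged_stft(cmap, t, windows)
        if spec is not None:
            out[k] = spec
    with h5py.File(path, "w") as f:
        f.create_dataset("spectra", data=out, compression="gzip")
        f.create_dataset("frame_index", data=np.asarray(list(frames)))
        f.create_dataset("f_s", data=spatial_frequencies())
        f.create_dataset("f_t", data=temporal_frequencies(cmap.frame_rate))


def _parabolic_offset(a: float, b: float, c: float) -> float:
    """Sub-bin offset of the vertex of a parabola through (-1,a),(0,b),(1,c)."""
    denom = a - 2.0 * b + c
    if denom == 0:
        return 0.0
    off = 0.5 * (a - c) / denom
    return float(np.clip(off, -0.5, 0.5))


def find_mode(
    spectrum: np.ndarray,
    frame_rate: float,
    energy_eps: float = DEFAULT_MODE_ENERGY_EPS,
) -> SpectralMode:
    """Locate the dominant mode of a half-plane magnitude spectrum.

    The argmax is taken over ``f_s > 0`` (the DC line is postural bias) and
    refined by 2D parabolic interpolation.  When the peak carries less than
    ``energy_eps`` of the total non-DC spectral energy the mode is undefined
    (quiescent or curled posture) rather than a junk frequency.
    """
    sub = spectrum[1:, :]
    total_energy = float(np.sum(sub**2))
    if total_energy <= 0:
        return SpectralMode.undefined()
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    peak = sub[i, j]
    if peak**2 < energy_eps * total_energy:
        return SpectralMode.undefined()
    # parabolic refinement along each axis
    di = dj = 0.0
    if 0 < i < sub.shape[0] - 1:
        di = _parabolic_offset(sub[i - 1, j], sub[i, j], sub[i + 1, j])
    if 0 < j < sub.shape[1] - 1:
        dj = _parabolic_offset(sub[i, j - 1], sub[i, j], sub[i, j + 1])
    f_s = (i + 1 + di) * N_SEGMENTS / SPATIAL_BINS
    f_t_axis_origin = -(TEMPORAL_BINS // 2)
    f_t = (f_t_axis_origin + j + dj) * frame_rate / TEMPORAL_BINS
    return SpectralMode(float(f_s), float(f_t), float(peak), True)


def compute_modes(
    cmap: CurvatureMap,
    windows: Tuple[int, ...] = DEFAULT_WINDOWS,
    energy_eps: float = DEFAULT_MODE_ENERGY_EPS,
) -> ModeTrack:
    """Per-frame dominant modes from the averaged multi-window transform."""
    T = cmap.n_frames
    f_s = np.full(T, np.nan)
    f_t = np.full(T, np.nan)
    mag = np.zeros(T)
    defined = np.zeros(T, dtype=bool)
    for t in range(T):
        if not cmap.valid_frames[t]:
            continue
        spec = averaged_stft(cmap, t, windows)
        if spec is None:
            continue
        mode = find_mode(spec, cmap.frame_rate, energy_eps)
        if mode.defined:
            f_s[t], f_t[t], mag[t] = mode.f_s_star, mode.f_t_star, mode.magnitude
            defined[t] = True
    return ModeTrack(f_s, f_t, mag, defined, cmap.frame_rate)


@dataclass
class StrokeClock:
    """Per-frame stroke duration D(t) and the derived two-stroke windows.

    ``D(t) = frame_rate / |f_t*(t)|`` frames.  Frames with no defined mode
    inherit the nearest defined duration (gap-fill), so measures retain a
    window across brief undefined runs; such frames stay excluded from
    summaries.  The two-stroke window is the half-open interval
    ``[t - D, t + D)`` clipped to the trial.
    """

    duration_frames: np.ndarray  # (T,), NaN when no frame defines a mode
    defined: np.ndarray  # (T,) bool: True where the underlying mode is defined
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.duration_frames.size

    @property
    def any_defined(self) -> bool:
        return bool(self.defined.any())

    def two_stroke_window(self, t: int) -> Tuple[int, int]:
        """Half-open frame interval [t - D, t + D), clipped to the trial."""
        D = self.duration_frames[t]
        if not np.isfinite(D):
            return t, t
        lo = int(np.ceil(t - D))
        hi = int(np.ceil(t + D))
        return max(0, lo), min(self.n_frames, hi)

    def one_stroke_window(self, tau: float) -> Tuple[int, int]:
        """Half-open one-stroke interval [tau - D/2, tau + D/2)."""
        t = int(np.clip(round(tau), 0, self.n_frames - 1))
        D = self.duration_frames[t]
        if not np.isfinite(D):
            return t, t
        lo = int(np.ceil(tau - D / 2.0))
        hi = int(np.ceil(tau + D / 2.0))
        return max(0, lo), min(self.n_frames, hi)


def stroke_clock(modes: ModeTrack, frame_rate: float) -> StrokeClock:
    """Derive the stroke clock from per-frame dominant modes."""
    D = np.full(modes.n_frames, np.nan)
    ok = modes.defined & np.isfinite(modes.f_t) & (np.abs(modes.f_t) > 0)
    D[ok] = frame_rate / np.abs(modes.f_t[ok])
    if ok.any():
        # nearest-neighbor gap fill
        idx = np.flatnonzero(ok)
        all_t = np.arange(modes.n_frames)
        nearest = idx[np.argmin(np.abs(all_t[:, None] - idx[None, :]), axis=1)]
        D = D[nearest]
    return StrokeClock(duration_frames=D, defined=ok, frame_rate=frame_rate)
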