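"""Swim-trial model: the package's central fitting object.

``SwimTrial`` bundles one animal's trial data (centerline track and/or
curvature kymograph) with analysis configuration; ``fit()`` runs the
spectral analysis and the ten measures and returns a ``SwimTrialResults``
carrying per-frame series, robust summaries, head-tail orientation
diagnostics, a ``summary()`` table, and plotting helpers.

Head-tail orientation: the tracker's initial tail/head labeling is
arbitrary.  If the first measures pass reports reverse swimming more than
50% of the time, the labeling is swapped (point order reversed on every
frame, kymograph rows flipped with curvature sign negated) and all measures
are recomputed; the results object records the swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import Centerline, CurvatureMap, build_curvature_map
from .measures import (
    DEFAULT_RANGE_EPS,
    MEASURE_NAMES,
    MeasureSeries,
    TrialSummary,
    reverse_percentage,
    summarize_trial,
)
from .spectral import (
    DEFAULT_MODE_ENERGY_EPS,
    DEFAULT_WINDOWS,
    ModeTrack,
    StrokeClock,
    compute_modes,
    stroke_clock,
)

__all__ = ["TrialConfig", "SwimTrial", "SwimTrialResults"]


@dataclass
class TrialConfig:
    """Analysis knobs shared across the pipeline (all dimensionless or in
    frames; defaults are the standard operating point)."""

    windows: tuple = DEFAULT_WINDOWS
    mode_energy_eps: float = DEFAULT_MODE_ENERGY_EPS
    range_eps: float = DEFAULT_RANGE_EPS
    curvature_window_fraction: float = 1.0 / 12.0
    auto_orient: bool = True


class SwimTrial:
    """One animal's swim trial, ready to fit.

    Parameters
    ----------
    track : sequence of Centerline, optional
        Chronological centerlines (required for the postural measures:
        curling, travel speed, brush stroke, activity index).
    cmap : CurvatureMap, optional
        Precomputed kymograph; derived from ``track`` when omitted.
    frame_rate : float
        Frames per second (required when only a track is given).
    """

    def __init__(
        self,
        track: Optional[Sequence[Centerline]] = None,
        cmap: Optional[CurvatureMap] = None,
        frame_rate: Optional[float] = None,
        animal_id: int = 0,
        config: Optional[TrialConfig] = None,
    ):
        if track is None and cmap is None:
            raise ValueError("provide a centerline track and/or a curvature map")
        self.config = config or TrialConfig()
        self.animal_id = animal_id
        self.track = list(track) if track is not None else []
        if cmap is None:
            if frame_rate is None:
                raise ValueError("frame_rate is required when building from a track")
            cmap = build_curvature_map(
                self.track,
                frame_rate,
                window_fraction=self.config.curvature_window_fraction,
            )
        self.cmap = cmap
        self.frame_rate = cmap.frame_rate

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        frame_rate: float,
        animal: Optional[int] = None,
        config: Optional[TrialConfig] = None,
    ) -> "SwimTrial":
        """Build from a centerline exchange table (see :mod:`nemaswim.io`)."""
        from .io import frame_to_tracks

        tracks = frame_to_tracks(df)
        if animal is None:
            if len(tracks) != 1:
                raise ValueError(
                    f"table holds {len(tracks)} animals; pass animal=<id>"
                )
            animal = next(iter(tracks))
        return cls(
            track=tracks[animal],
            frame_rate=frame_rate,
            animal_id=animal,
            config=config,
        )

    @classmethod
    def from_scenario(cls, scn, config: Optional[TrialConfig] = None) -> "SwimTrial":
        """Build from a synthetic scenario (ground-truth centerlines and map)."""
        from .synthgen import generate_track

        track, cmap, _ = generate_track(scn)
        return cls(track=track, cmap=cmap, config=config)

    # -- fitting ----------------------------------------------------------

    def fit(self, measures: Optional[Sequence[str]] = None) -> "SwimTrialResults":
        """Run spectral analysis + measures; auto-orients head/tail."""
        cfg = self.config
        track, cmap = self.track, self.cmap
        swapped = False
        modes = compute_modes(cmap, cfg.windows, cfg.mode_energy_eps)
        if cfg.auto_orient:
            rev = reverse_percentage(modes)
            if np.isfinite(rev) and rev > 50.0:
                track = [c.reversed() for c in track]
                cmap = cmap.reversed()
                modes = compute_modes(cmap, cfg.windows, cfg.mode_energy_eps)
                swapped = True
        clock = stroke_clock(modes, cmap.frame_rate)
        summary = summarize_trial(
            track,
            cmap,
            modes,
            clock,
            animal_id=self.animal_id,
            measures=measures,
            range_eps=cfg.range_eps,
        )
        return SwimTrialResults(
            model=self,
            cmap=cmap,
            modes=modes,
            clock=clock,
            trial_summary=summary,
            head_tail_swapped=swapped,
            oriented_track=track,
        )


@dataclass
class SwimTrialResults:
    """Fitted results for one swim trial."""

    model: SwimTrial
    cmap: CurvatureMap
    modes: ModeTrack
    clock: StrokeClock
    trial_summary: TrialSummary
    head_tail_swapped: bool
    oriented_track: list

    @property
    def series(self) -> Dict[str, MeasureSeries]:
        return self.trial_summary.series

    @property
    def reverse_fraction(self) -> float:
        return self.trial_summary.reverse_fraction

    @property
    def curl_fraction(self) -> float:
        return self.trial_summary.curl_fraction

    def medians(self) -> Dict[str, float]:
        return self.trial_summary.medians()

    def to_frame(self) -> pd.DataFrame:
        """Per-frame series as a tidy DataFrame (one column per measure)."""
        data = {name: s.values for name, s in self.series.items()}
        df = pd.DataFrame(data)
        df.insert(0, "frame", np.arange(self.cmap.n_frames))
        df.insert(1, "valid", self.cmap.valid_frames)
        return df

    def kymograph_to_csv(self, path) -> None:
        """Write the 12 x T curvature kymograph (rows tail to head)."""
        pd.DataFrame(self.cmap.values).to_csv(path, index=False, header=False)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in self.series.items():
            if name in ("reverse_swimming", "curling"):
                continue
            rows.append(
                {
                    "measure": name,
                    "median": s.median,
                    "p10": s.p10,
                    "p90": s.p90,
                    "units": s.units,
                    "n_frames": s.n_defined,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable trial report."""
        ts = self.trial_summary
        lines = [
            "Swim trial summary",
            "==================",
            f"animal id:        {ts.animal_id}",
            f"frame rate:       {ts.frame_rate:g} fps",
            f"valid frames:     {ts.n_valid_frames}/{self.cmap.n_frames}",
            f"head-tail swap:   {'yes' if self.head_tail_swapped else 'no'}",
            "",
            f"{'measure':<22}{'median':>10}{'p10':>10}{'p90':>10}  units",
            "-" * 66,
        ]
        for name, s in self.series.items():
            if name in ("reverse_swimming", "curling"):
                continue
            lines.append(
                f"{name:<22}{s.median:>10.3f}{s.p10:>10.3f}{s.p90:>10.3f}  {s.units}"
            )
        if np.isfinite(ts.reverse_fraction):
            lines.append(f"{'reverse swimming':<22}{ts.reverse_fraction:>10.1f}  % of time")
        if np.isfinite(ts.curl_fraction):
            lines.append(f"{'curling':<22}{ts.curl_fraction:>10.1f}  % of time")
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------

    def plot_kymograph(self, ax=None):
        """Curvature heat map (body position vs time, head at the top)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        v = self.cmap.values
        lim = np.nanmax(np.abs(v)) or 1.0
        im = ax.imshow(
            v,
            aspect="auto",
            origin="lower",
            cmap="RdBu_r",
            vmin=-lim,
            vmax=lim,
            extent=[0, v.shape[1] / self.cmap.frame_rate, 0, 1],
        )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("body position (tail → head)")
        plt.colorbar(im, ax=ax, label="curvature × body length")
        return ax

    def plot_measure(self, name: str, ax=None):
        """One measure vs time with median (red) and 10-90 percentile band."""
        import matplotlib.pyplot as plt

        s = self.series[name]
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 2.5))
        t = np.arange(s.values.size) / self.cmap.frame_rate
        ax.axhspan(s.p10, s.p90, color="0.85")
        ax.plot(t, s.values, "k-", lw=0.8)
        ax.axhline(s.median, color="r")
        ax.set_xlabel("time (s)")
        ax.set_ylabel(f"{name} ({s.units})")
        return ax
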