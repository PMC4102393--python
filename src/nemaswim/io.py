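"""Centerline table I/O.

The measures stage is deliberately decoupled from the bundled tracker: any
tracking method that provides body coordinates and widths can feed it.  The
exchange format is a flat table with columns

    animal, frame, point_index, x, y, half_width, valid

with 1-based frame numbering and 0-based point indices, points ordered tail
first.  A CSV file and an HDF5 mirror (one dataset per animal) are supported.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import h5py
import numpy as np
import pandas as pd

from .geometry import Centerline

CSV_COLUMNS = ["animal", "frame", "point_index", "x", "y", "half_width", "valid"]


def track_to_frame(track: Sequence[Centerline], animal: int = 0) -> pd.DataFrame:
    """Flatten one animal's track into the exchange table."""
    rows = []
    for c in track:
        n = c.n_points
        rows.append(
            pd.DataFrame(
                {
                    "animal": animal,
                    "frame": c.frame_index + 1,  # 1-based on disk
                    "point_index": np.arange(n),
                    "x": c.points[:, 0],
                    "y": c.points[:, 1],
                    "half_width": c.half_widths,
                    "valid": int(c.valid),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[CSV_COLUMNS]


def frame_to_tracks(df: pd.DataFrame) -> Dict[int, List[Centerline]]:
    """Rebuild per-animal Centerline sequences from an exchange table."""
    tracks: Dict[int, List[Centerline]] = {}
    if "animal" not in df.columns:
        df = df.assign(animal=0)
    for animal, adf in df.groupby("animal", sort=True):
        frames = []
        for frame, fdf in adf.groupby("frame", sort=True):
            fdf = fdf.sort_values("point_index")
            frames.append(
                Centerline(
                    points=fdf[["x", "y"]].to_numpy(),
                    half_widths=fdf["half_width"].to_numpy(),
                    frame_index=int(frame) - 1,
                    valid=bool(fdf["valid"].iloc[0]),
                )
            )
        tracks[int(animal)] = frames
    return tracks


def write_centerlines_csv(path, tracks: Dict[int, Sequence[Centerline]]) -> None:
    df = pd.concat(
        [track_to_frame(track, animal=a) for a, track in sorted(tracks.items())],
        ignore_index=True,
    )
    df.to_csv(path, index=False)


def read_centerlines_csv(path) -> Dict[int, List[Centerline]]:
    return frame_to_tracks(pd.read_csv(path))


def write_centerlines_hdf5(path, tracks: Dict[int, Sequence[Centerline]]) -> None:
    """HDF5 mirror: one ``animal_<id>`` dataset of shape (rows, 6) per animal,
    columns frame, point_index, x, y, half_width, valid."""
    with h5py.File(path, "w") as f:
        for a, track in sorted(tracks.items()):
            df = track_to_frame(track, animal=a)
            f.create_dataset(
                f"animal_{a}",
                data=df[CSV_COLUMNS[1:]].to_numpy(dtype=float),
            )


def read_centerlines_hdf5(path) -> Dict[int, List[Centerline]]:
    tracks: Dict[int, List[Centerline]] = {}
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            a = int(name.split("_")[1])
            arr = f[name][()]
            df = pd.DataFrame(arr, columns=CSV_COLUMNS[1:]).assign(animal=a)
            tracks[a] = frame_to_tracks(df)[a]
    return tracks
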