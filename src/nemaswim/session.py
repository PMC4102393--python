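"""Trial registry, grouped statistics, and comparison plots.

A flat-file registry (CSV) records each video with identifying tags (sample
number, date, investigator, experiment, trial number, strain, animal age,
animal count, duration); arbitrary extra tags may be added at any time.
Per-animal summary scores (the ten measure medians plus the binary-state
percentages) join to those tags for population-level comparison: group
means +/- SEM, integer-binned median histograms, two-measure scatter plots
with principal-direction covariance ellipses, and pairwise significance.

Asymmetry is aggregated as the absolute value of each animal's median before
group statistics, so animals that happen to favor the left or the right do
not cancel each other out.

Significance uses the two-sided Mann-Whitney U test with Holm correction by
default (trial scores are medians of skewed series, so a rank test is the
safer default); Welch's t is available.  Stars: * p<0.05, ** p<0.01,
*** p<0.001, **** p<0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .measures import MEASURE_NAMES

__all__ = [
    "VideoMeta",
    "Registry",
    "GroupComparison",
    "compare_groups",
    "covariance_ellipse",
    "significance_stars",
    "export_results",
    "read_results",
    "records_from_summaries",
]

REGISTRY_COLUMNS = [
    "sample_number",
    "date_recorded",
    "investigator",
    "experiment",
    "trial_number",
    "strain",
    "animal_age",
    "n_animals",
    "duration_s",
    "path",
]


@dataclass
class VideoMeta:
    """Identifying tags for one registered video."""

    sample_number: int
    date_recorded: str = ""
    investigator: str = ""
    experiment: str = ""
    trial_number: int = 0
    strain: str = ""
    animal_age: int = 0
    n_animals: int = 0
    duration_s: float = 0.0
    path: str = ""
    extra: Dict[str, object] = field(default_factory=dict)

    def to_row(self) -> Dict[str, object]:
        row = {k: getattr(self, k) for k in REGISTRY_COLUMNS}
        row.update(self.extra)
        return row


class Registry:
    """Flat-file (CSV) registry of videos, queryable by any tag."""

    def __init__(self, path):
        self.path = Path(path)
        if self.path.exists():
            self._df = pd.read_csv(self.path)
        else:
            self._df = pd.DataFrame(columns=REGISTRY_COLUMNS)

    def __len__(self) -> int:
        return len(self._df)

    def register(self, meta: VideoMeta) -> None:
        if meta.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if (self._df["sample_number"] == meta.sample_number).any():
            raise ValueError(f"sample_number {meta.sample_number} already registered")
        row = pd.DataFrame([meta.to_row()])
        if self._df.empty:
            self._df = row
        else:
            self._df = pd.concat([self._df, row], ignore_index=True)
        self._df.to_csv(self.path, index=False)

    def query(self, **tags) -> pd.DataFrame:
        df = self._df
        for k, v in tags.items():
            df = df[df[k] == v]
        return df.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()


# ---------------------------------------------------------------------------
# group statistics


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return "n/a"
    for thr, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < thr:
            return stars
    return "ns"


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def covariance_ellipse(xy: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal directions and 1-SD semi-axes of a 2D point cloud.

    Returns (center, axes_lengths, axes_directions): axes_directions columns
    are the covariance eigenvectors, axes_lengths the standard deviation
    along each.
    """
    xy = np.asarray(xy, dtype=float)
    center = xy.mean(axis=0)
    cov = np.cov(xy.T) if xy.shape[0] > 1 else np.zeros((2, 2))
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    evals = np.clip(evals, 0.0, None)
    return center, np.sqrt(evals), evecs


@dataclass
class GroupComparison:
    """Grouped comparison of per-animal summary scores."""

    group_by: List[str]
    measures: List[str]
    stats: pd.DataFrame  # group x measure: n, mean, sem, median
    pairwise: pd.DataFrame  # measure, group_a, group_b, p, p_adj, stars
    test: str

    def summary(self) -> str:
        lines = ["Group comparison", "================", ""]
        lines.append(self.stats.to_string(index=False))
        lines.append("")
        lines.append(f"pairwise test: {self.test} (Holm-adjusted)")
        lines.append(self.pairwise.to_string(index=False))
        return "\n".join(lines)


def _group_values(records: pd.DataFrame, group_by, measure: str):
    vals = records[measure].astype(float)
    if measure == "asymmetry":
        vals = vals.abs()
    out = []
    for key, idx in records.groupby(group_by, sort=True).groups.items():
        v = vals.loc[idx].dropna().to_numpy()
        out.append((key, v))
    return out


def compare_groups(
    records: pd.DataFrame,
    group_by,
    measures: Optional[Sequence[str]] = None,
    test: str = "mannwhitney",
) -> GroupComparison:
    """Compare per-animal summary scores across groups.

    ``records`` holds one row per animal: measure columns (medians; reverse
    and curl as percentages) plus grouping tags.  Raises if a requested
    measure is missing.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    if measures is None:
        measures = [m for m in MEASURE_NAMES if m in records.columns]
    for m in measures:
        if m not in records.columns:
            raise ValueError(f"measure {m!r} missing from records")
    if records.empty:
        raise ValueError("no records")

    stat_rows = []
    pair_rows = []
    for m in measures:
        groups = _group_values(records, group_by, m)
        for key, v in groups:
            label = key if isinstance(key, str) else "/".join(map(str, np.atleast_1d(key)))
            stat_rows.append(
                {
                    "measure": m,
                    "group": label,
                    "n": v.size,
                    "mean": v.mean() if v.size else np.nan,
                    "sem": stats.sem(v) if v.size > 1 else np.nan,
                    "median": np.median(v) if v.size else np.nan,
                }
            )
        ps = []
        pairs = list(combinations(range(len(groups)), 2))
        for i, j in pairs:
            a, b = groups[i][1], groups[j][1]
            if a.size < 2 or b.size < 2 or (np.ptp(np.concatenate([a, b])) == 0):
                p = np.nan
            elif test == "mannwhitney":
                p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            elif test == "welch":
                p = stats.ttest_ind(a, b, equal_var=False).pvalue
            else:
                raise ValueError(f"unknown test {test!r}")
            ps.append(p)
        finite = np.isfinite(ps)
        adj = np.full(len(ps), np.nan)
        if finite.any():
            adj[finite] = _holm(np.asarray(ps)[finite])
        for (i, j), p, pa in zip(pairs, ps, adj):
            ka = groups[i][0]
            kb = groups[j][0]
            pair_rows.append(
                {
                    "measure": m,
                    "group_a": str(ka),
                    "group_b": str(kb),
                    "p": p,
                    "p_adj": pa,
                    "stars": significance_stars(pa),
                }
            )
    return GroupComparison(
        group_by=list(group_by),
        measures=list(measures),
        stats=pd.DataFrame(stat_rows),
        pairwise=pd.DataFrame(pair_rows),
        test=test,
    )


# ---------------------------------------------------------------------------
# plots


def plot_dot(records: pd.DataFrame, group_by: str, measure: str, ax=None):
    """Per-animal dots by group with mean +/- SEM overlay."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vals = records[measure].abs() if measure == "asymmetry" else records[measure]
    groups = sorted(records[group_by].unique())
    for x, g in enumerate(groups):
        v = vals[records[group_by] == g].dropna().to_numpy()
        jitter = (np.arange(v.size) % 7 - 3) * 0.02
        ax.plot(np.full(v.size, x) + jitter, v, "o", ms=3, alpha=0.6)
        if v.size:
            sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
            ax.errorbar([x], [v.mean()], yerr=[sem], fmt="_", color="k", capsize=4, ms=18)
    ax.set_xticks(range(len(groups)), [str(g) for g in groups])
    ax.set_ylabel(measure)
    ax.set_xlabel(group_by)
    return ax


def plot_histogram(records: pd.DataFrame, group_by: str, measure: str, ax=None):
    """Contour-line histogram of per-animal medians binned to integers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for g in sorted(records[group_by].unique()):
        v = records.loc[records[group_by] == g, measure].dropna().to_numpy()
        if v.size == 0:
            continue
        binned = np.round(v).astype(int)
        lo, hi = binned.min(), binned.max()
        edges = np.arange(lo - 0.5, hi + 1.5)
        counts, _ = np.histogram(binned, bins=edges)
        ax.step(np.arange(lo, hi + 1), counts, where="mid", label=str(g))
    ax.set_xlabel(f"median {measure} (integer bins)")
    ax.set_ylabel("number of animals")
    ax.legend(title=group_by)
    return ax


def plot_scatter2d(
    records: pd.DataFrame, group_by: str, measure_x: str, measure_y: str, ax=None
):
    """Two-measure scatter with per-group principal-direction 1-SD ellipses."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots()
    for g in sorted(records[group_by].unique()):
        sub = records[records[group_by] == g]
        x = sub[measure_x].abs() if measure_x == "asymmetry" else sub[measure_x]
        y = sub[measure_y].abs() if measure_y == "asymmetry" else sub[measure_y]
        xy = np.column_stack([x.to_numpy(float), y.to_numpy(float)])
        xy = xy[np.isfinite(xy).all(axis=1)]
        if xy.shape[0] == 0:
            continue
        pts = ax.plot(xy[:, 0], xy[:, 1], "o", ms=3, alpha=0.6, label=str(g))
        if xy.shape[0] > 2:
            center, axes, dirs = covariance_ellipse(xy)
            angle = np.degrees(np.arctan2(dirs[1, 1], dirs[0, 1]))
            ax.add_patch(
                Ellipse(
                    center,
                    2 * axes[1],
                    2 * axes[0],
                    angle=angle,
                    fill=False,
                    color=pts[0].get_color(),
                )
            )
    ax.set_xlabel(measure_x)
    ax.set_ylabel(measure_y)
    ax.legend(title=group_by)
    return ax


# ---------------------------------------------------------------------------
# export


def records_from_summaries(summaries, meta: Optional[dict] = None) -> pd.DataFrame:
    """One row per animal from TrialSummary objects, joined to metadata."""
    rows = []
    for ts in summaries:
        row = {"animal_id": ts.animal_id, "n_valid_frames": ts.n_valid_frames}
        row.update(ts.medians())
        for name, s in ts.series.items():
            if name in ("reverse_swimming", "curling"):
                continue
            row[f"{name}_p10"] = s.p10
            row[f"{name}_p90"] = s.p90
        if meta:
            row.update(meta)
        rows.append(row)
    return pd.DataFrame(rows)


def export_results(records: pd.DataFrame, out_dir, stem: str = "results") -> dict:
    """Write wide (one row per animal) and tidy (one row per animal-measure)
    CSVs with a stable column order; round-trips exactly."""
    if records.empty:
        raise ValueError("no records to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wide_path = out_dir / f"{stem}_wide.csv"
    records.to_csv(wide_path, index=False)
    measure_cols = [m for m in MEASURE_NAMES if m in records.columns]
    id_cols = [c for c in records.columns if c not in measure_cols]
    tidy = records.melt(
        id_vars=id_cols, value_vars=measure_cols, var_name="measure", value_name="value"
    )
    tidy_path = out_dir / f"{stem}_tidy.csv"
    tidy.to_csv(tidy_path, index=False)
    return {"wide": wide_path, "tidy": tidy_path}


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
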