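"""Tilt-binned profiles, 2D tilt-rotation density, moments, convergence.

Errors of tilt-binned means follow the five-subset design: the trajectories
are split into five subsets, and the error of a bin mean is the standard
deviation of the five subset means divided by sqrt(5).  Analyses of an
"equilibrated" ensemble must only consume frames with time > 0.5 us; the
gate is an explicit filter with an override flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .geometry import OrientationRecord
from .structure_io import Ensemble

DEFAULT_BIN_WIDTH = 5.0  # degrees
DEFAULT_N_SUBSETS = 5
EQUILIBRATION_GATE_US = 0.5


class StatsError(ValueError):
    pass


def orientation_table(records: list[OrientationRecord]) -> pd.DataFrame:
    """Per-frame orientation records as a long-friendly wide table."""
    rows = []
    for r in records:
        row = {
            "trajectory": r.source.trajectory_id if r.source else np.nan,
            "time_us": r.source.time_us if r.source else np.nan,
            "tilt": r.tilt,
            "rotation": r.rotation,
            "inter_axis_angle": r.inter_axis_angle,
        }
        for chain, inc in sorted(r.helix_inclinations.items()):
            row[f"incl_{chain}"] = inc
        rows.append(row)
    return pd.DataFrame(rows)


def filter_equilibrated(
    df: pd.DataFrame,
    gate_us: float = EQUILIBRATION_GATE_US,
    override: bool = False,
    time_col: str = "time_us",
) -> pd.DataFrame:
    """Keep frames with time strictly beyond the equilibration gate."""
    if override:
        return df
    return df[df[time_col] > gate_us].reset_index(drop=True)


def filter_equilibrated_ensemble(
    ensemble: Ensemble,
    gate_us: float = EQUILIBRATION_GATE_US,
    override: bool = False,
) -> Ensemble:
    if override:
        return ensemble
    kept = [c for c in ensemble if c.source is not None and c.source.time_us > gate_us]
    if not kept:
        raise StatsError("equilibration gate removed every frame")
    return Ensemble(kept, metadata=dict(ensemble.metadata, gate_us=gate_us))


# ---------------------------------------------------------------------------
# tilt-binned profiles
# ---------------------------------------------------------------------------


@dataclass
class TiltBinnedProfile:
    edges: np.ndarray  # bin edges, degrees
    mean: np.ndarray  # per-bin mean (NaN where empty)
    error: np.ndarray  # five-subset error of the mean (NaN where undefined)
    count: np.ndarray  # per-bin frame count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.edges[:-1],
                "bin_right": self.edges[1:],
                "mean": self.mean,
                "error": self.error,
                "n": self.count,
            }
        )


def _subset_ids(trajectories: np.ndarray, n_subsets: int, scheme: str) -> np.ndarray:
    """Map each frame's trajectory id to a subset label 0..n_subsets-1."""
    unique = np.sort(np.unique(trajectories))
    if len(unique) < n_subsets:
        raise StatsError(
            f"need >= {n_subsets} distinct trajectories, got {len(unique)}"
        )
    if scheme == "contiguous":
        blocks = np.array_split(unique, n_subsets)
        lookup = {tid: s for s, block in enumerate(blocks) for tid in block}
    elif scheme == "round_robin":
        lookup = {tid: i % n_subsets for i, tid in enumerate(unique)}
    else:
        raise ValueError(f"unknown subset scheme {scheme!r}")
    return np.array([lookup[t] for t in trajectories])


def bin_by_tilt(
    tilt: np.ndarray,
    value: np.ndarray,
    trajectory: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_subsets: int = DEFAULT_N_SUBSETS,
    scheme: str = "contiguous",
) -> TiltBinnedProfile:
    """Bin a per-frame quantity by tilt with subset-based errors.

    Frames fall into bins [edge, edge + width); the per-bin mean runs over
    all frames, the error is SD(subset means)/sqrt(k) over the k subsets
    with data in the bin (NaN when k < 2, as for a single subset).
    """
    tilt = np.asarray(tilt, float)
    value = np.asarray(value, float)
    trajectory = np.asarray(trajectory)
    subs = _subset_ids(trajectory, n_subsets, scheme)

    # [edge, edge + width) bins: a sample exactly at a multiple of the width
    # opens a new bin rather than being folded into the previous one
    lo = np.floor(tilt.min() / bin_width) * bin_width
    hi = np.floor(tilt.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    nbins = len(edges) - 1
    which = np.floor((tilt - lo) / bin_width).astype(int)

    mean = np.full(nbins, np.nan)
    err = np.full(nbins, np.nan)
    count = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        in_bin = which == b
        count[b] = in_bin.sum()
        if not count[b]:
            continue
        mean[b] = value[in_bin].mean()
        sub_means = [
            value[in_bin & (subs == s)].mean()
            for s in range(n_subsets)
            if (in_bin & (subs == s)).any()
        ]
        if len(sub_means) >= 2:
            err[b] = float(np.std(sub_means, ddof=0) / np.sqrt(len(sub_means)))
    return TiltBinnedProfile(edges=edges, mean=mean, error=err, count=count)


# ---------------------------------------------------------------------------
# 2D density
# ---------------------------------------------------------------------------


@dataclass
class TiltRotationDensity:
    tilt_edges: np.ndarray
    rotation_edges: np.ndarray
    density: np.ndarray  # integrates to 1 over the grid
    smoothed: bool = False

    def integral(self) -> float:
        area = np.outer(np.diff(self.tilt_edges), np.diff(self.rotation_edges))
        return float((self.density * area).sum())


def density_2d(
    tilt: np.ndarray,
    rotation: np.ndarray,
    bin_width: tuple[float, float] = (2.5, 2.5),
    smoothing_sigma_bins: float | None = None,
) -> TiltRotationDensity:
    """Normalized 2D histogram density over (tilt, rotation).

    Gaussian smoothing (in units of bins) is a labelled, off-by-default
    post-process; the result is renormalized after smoothing.
    """
    tilt = np.asarray(tilt, float)
    rotation = np.asarray(rotation, float)
    if tilt.size == 0:
        raise StatsError("density_2d needs at least one record")
    wt, wr = bin_width

    def _edges(x, w):
        lo = np.floor(x.min() / w) * w
        hi = np.ceil(x.max() / w) * w
        if hi <= lo:
            hi = lo + w
        return np.arange(lo, hi + w / 2, w)

    te, re = _edges(tilt, wt), _edges(rotation, wr)
    h, _, _ = np.histogram2d(tilt, rotation, bins=(te, re), density=True)
    smoothed = False
    if smoothing_sigma_bins:
        h = ndimage.gaussian_filter(h, sigma=smoothing_sigma_bins)
        area = np.outer(np.diff(te), np.diff(re))
        h = h / (h * area).sum()
        smoothed = True
    return TiltRotationDensity(te, re, h, smoothed=smoothed)


# ---------------------------------------------------------------------------
# moments / mode
# ---------------------------------------------------------------------------


def distribution_summary(
    samples: np.ndarray, mode_grid_step: float = 0.1
) -> tuple[float, float, float]:
    """(mean, sample SD, KDE mode) of an angular sample, in degrees.

    The mode is the argmax of a Gaussian KDE (Silverman bandwidth) evaluated
    on a fine grid, avoiding histogram bin-width artifacts.
    """
    x = np.asarray(samples, float)
    if x.size < 2:
        raise StatsError("need at least two samples for an SD")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return mean, sd, mean
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.arange(x.min() - 3 * sd, x.max() + 3 * sd, mode_grid_step)
    mode = float(grid[np.argmax(kde(grid))])
    return mean, sd, mode


# ---------------------------------------------------------------------------
# equilibration time series
# ---------------------------------------------------------------------------


def time_convergence(
    df: pd.DataFrame,
    quantities: list[str],
    traj_col: str = "trajectory",
    time_col: str = "time_us",
) -> pd.DataFrame:
    """Cross-trajectory mean +- SEM of quantities at each time point.

    Every trajectory must have exactly one frame at every requested time;
    missing frames raise, naming the trajectory and time.
    """
    trajectories = np.sort(df[traj_col].unique())
    times = np.sort(df[time_col].unique())
    counts = df.groupby([traj_col, time_col], sort=False).size()
    for t in trajectories:
        for tm in times:
            if counts.get((t, tm), 0) != 1:
                raise StatsError(
                    f"trajectory {t} has no unique frame at time {tm} us"
                )
    rows = []
    n = len(trajectories)
    for q in quantities:
        g = df.groupby(time_col)[q]
        means = g.mean()
        sems = g.std(ddof=1) / np.sqrt(n)
        for tm in times:
            rows.append(
                {"quantity": q, "time_us": tm,
                 "mean": means.loc[tm], "sem": sems.loc[tm]}
            )
    return pd.DataFrame(rows)
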