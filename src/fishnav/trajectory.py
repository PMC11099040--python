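"""Trajectory data model, I/O, cropping, and distance scoring.

Observed paths are 1 Hz click-digitised head positions.  Every comparison
between an observed path and a model path runs through the same recipe:
truncate both to a common arc length, resample each to 1000 points at
equal arc-length spacing with a modified-Akima (shape-preserving) scheme,
then average the 1000 pairwise Euclidean distances.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import Akima1DInterpolator

from .errors import ContractError, DegenerateTrajectoryError, ValidationError

#: Number of equal arc-length stations used for every path comparison.
N_INTERP = 1000

REQUIRED_COLUMNS = ("trial_id", "fish_id", "t_s", "x_cm", "y_cm")


@dataclass
class Trajectory:
    """Time-stamped 2-D path of one trial (cm, nominal 1 s spacing).

    ``crop_index`` records where :func:`crop_at_turnback` cut the path
    (index of the last retained sample in the pre-crop trajectory), or
    ``None`` if no turn-back was detected.
    """

    trial_id: str
    fish_id: str
    t: np.ndarray
    xy: np.ndarray
    crop_index: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.xy = np.asarray(self.xy, float)
        if self.t.ndim != 1 or self.xy.shape != (self.t.size, 2):
            raise ValidationError(f"trial {self.trial_id}: t/xy shape mismatch")
        if self.t.size < 2:
            raise ValidationError(f"trial {self.trial_id}: fewer than 2 samples")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xy)):
            raise ValidationError(f"trial {self.trial_id}: non-finite sample values")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError(f"trial {self.trial_id}: time not strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def points(self) -> np.ndarray:
        return self.xy

    def path_length(self) -> float:
        return arc_length(self.xy)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "fish_id": self.fish_id,
                "t_s": self.t,
                "x_cm": self.xy[:, 0],
                "y_cm": self.xy[:, 1],
            }
        )
        if self.crop_index is not None:
            df["crop_index"] = self.crop_index
        return df


@dataclass(frozen=True)
class InterpolatedPath:
    """Exactly ``N_INTERP`` points at equal arc-length spacing."""

    points: np.ndarray
    source_length: float

    def __post_init__(self) -> None:
        if self.points.shape != (N_INTERP, 2):
            raise ContractError(f"interpolated path must have {N_INTERP} points")


def read_trajectories(
    path: str | Path | io.IOBase, tank_side: float | None = None
) -> list[Trajectory]:
    """Read a trajectory CSV into one :class:`Trajectory` per trial.

    The file must carry the header ``trial_id,fish_id,t_s,x_cm,y_cm``.
    Rows are grouped by trial and time-sorted.  Malformed rows are
    reported with their CSV line numbers; non-monotone time stamps and
    (when ``tank_side`` is given) out-of-tank coordinates are rejected
    with the offending trial named.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trajectory CSV missing columns: {missing}")
    numeric = df[["t_s", "x_cm", "y_cm"]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | df["trial_id"].isna()
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
        raise ValidationError(f"malformed trajectory rows at CSV lines {lines}")
    df[["t_s", "x_cm", "y_cm"]] = numeric
    trajectories = []
    for trial_id, g in df.groupby("trial_id", sort=True):
        g = g.sort_values("t_s")
        fish = g["fish_id"].astype(str).unique()
        if fish.size > 1:
            raise ValidationError(f"trial {trial_id}: multiple fish ids {list(fish)}")
        t = g["t_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"trial {trial_id}: non-monotone time stamps")
        xy = g[["x_cm", "y_cm"]].to_numpy(float)
        if tank_side is not None and (np.any(xy < 0) or np.any(xy > tank_side)):
            raise ValidationError(f"trial {trial_id}: coordinates outside the tank square")
        trajectories.append(Trajectory(str(trial_id), str(fish[0]), t, xy))
    return trajectories


def write_trajectories(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    """Write trajectories back to CSV (with crop provenance if present)."""
    pd.concat([tr.to_frame() for tr in trajectories], ignore_index=True).to_csv(
        path, index=False
    )


def arc_length(points: np.ndarray) -> float:
    """Total Euclidean length of a polyline."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise DegenerateTrajectoryError("arc_length needs at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _cumulative_arclength(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def truncate_to_length(points: np.ndarray, length: float) -> np.ndarray:
    """Prefix of a polyline with arc length exactly ``length``.

    The final partial segment is linearly interpolated.  Never lengthens
    the path.
    """
    pts = np.asarray(points, float)
    s = _cumulative_arclength(pts)
    total = s[-1]
    if total <= 0:
        raise DegenerateTrajectoryError("cannot truncate a zero-length path")
    if length >= total - 1e-12:
        return pts.copy()
    if length <= 0:
        raise ContractError("truncation length must be positive")
    k = int(np.searchsorted(s, length, side="right"))
    frac = (length - s[k - 1]) / (s[k] - s[k - 1])
    cut = pts[k - 1] + frac * (pts[k] - pts[k - 1])
    return np.vstack([pts[:k], cut])


def crop_to_common_length(observed: np.ndarray, model: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Truncate the longer of two polylines so both arc lengths match.

    Both outputs have arc length min(L_obs, L_model) to within 1e-9 cm.
    """
    obs = np.asarray(observed, float)
    mod = np.asarray(model, float)
    L = min(arc_length(obs), arc_length(mod))
    if L <= 0:
        raise DegenerateTrajectoryError("zero-length input to crop_to_common_length")
    return truncate_to_length(obs, L), truncate_to_length(mod, L)


def _refine_to_resolution(pts: np.ndarray, n_points: int) -> np.ndarray:
    """Subdivide polyline segments so none exceeds L/(n_points - 1)."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    max_len = seg.sum() / (n_points - 1)
    pieces = np.maximum(np.ceil(seg / max_len - 1e-9).astype(int), 1)
    if np.all(pieces == 1):
        return pts
    out = [pts[:1]]
    for i, k in enumerate(pieces):
        frac = np.arange(1, k + 1)[:, None] / k
        out.append(pts[i] + frac * (pts[i + 1] - pts[i]))
    return np.vstack(out)


def interpolate_1000(points: np.ndarray, n_points: int = N_INTERP) -> InterpolatedPath:
    """Resample a polyline at equal arc-length stations.

    x and y are each fitted with a modified-Akima (shape-preserving
    piecewise-cubic) interpolant against cumulative arc length and
    evaluated at ``n_points`` equally spaced stations; 2-point inputs
    reduce exactly to linear interpolation.  End points are reproduced
    exactly.

    Knots are first refined to the station resolution (no segment longer
    than L/(n-1)): on very sparse polylines such as a 3-vertex L, raw
    Akima would smooth direction changes at the scale of whole segments;
    refinement keeps the resampling polyline-faithful and confines the
    cubic smoothing to below station scale.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise DegenerateTrajectoryError("interpolation needs at least 2 points")
    # collapse consecutive duplicates so arc length is strictly increasing
    keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12])
    pts = pts[keep]
    if pts.shape[0] < 2:
        raise DegenerateTrajectoryError("all points identical; nothing to interpolate")
    pts = _refine_to_resolution(pts, n_points)
    s = _cumulative_arclength(pts)
    length = s[-1]
    stations = np.linspace(0.0, length, n_points)
    if pts.shape[0] == 2:
        out = np.column_stack(
            [np.interp(stations, s, pts[:, 0]), np.interp(stations, s, pts[:, 1])]
        )
    else:
        fx = Akima1DInterpolator(s, pts[:, 0], method="makima")
        fy = Akima1DInterpolator(s, pts[:, 1], method="makima")
        out = np.column_stack([fx(stations), fy(stations)])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return InterpolatedPath(out, float(length))


def pointwise_distances(a: InterpolatedPath, b: InterpolatedPath) -> tuple[np.ndarray, float]:
    """Per-station Euclidean distances between two resampled paths.

    Returns the 1000 distances and their arithmetic mean — the route
    similarity score used throughout classification.
    """
    if a.points.shape != b.points.shape:
        raise ContractError("interpolated paths must have matching shapes")
    d = np.linalg.norm(a.points - b.points, axis=1)
    return d, float(d.mean())


def mean_distance(observed: np.ndarray, model: np.ndarray) -> tuple[np.ndarray, float]:
    """Common-length, resampled, pointwise mean distance of two polylines."""
    obs_c, mod_c = crop_to_common_length(observed, model)
    return pointwise_distances(interpolate_1000(obs_c), interpolate_1000(mod_c))


def _angdiff(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Absolute angular difference in degrees, in [0, 180]."""
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)


def crop_at_turnback(
    traj: Trajectory,
    chamber: np.ndarray,
    cone_deg: float = 30.0,
    persistence: int = 2,
    analysis_window: float | None = None,
) -> Trajectory:
    """Crop a trajectory once the fish orients back toward the chamber.

    The path is first truncated to ``analysis_window`` seconds after the
    first sample (release from the door), then scanned for the first run
    of ``persistence`` consecutive steps whose heading lies within
    ``cone_deg`` of the bearing to the chamber *and* whose distance to
    the chamber decreases.  The returned prefix ends at the last sample
    before that run; if no run is found the window-truncated trajectory
    is returned unchanged (``crop_index`` None).
    """
    if traj.n_samples < 3:
        raise DegenerateTrajectoryError(f"trial {traj.trial_id}: fewer than 3 samples")
    if persistence < 1:
        raise ContractError("persistence must be >= 1")
    chamber = np.asarray(chamber, float)

    t, xy = traj.t, traj.xy
    if analysis_window is not None:
        keep = t - t[0] <= analysis_window + 1e-9
        t, xy = t[keep], xy[keep]
        if t.size < 3:
            raise DegenerateTrajectoryError(
                f"trial {traj.trial_id}: fewer than 3 samples inside the analysis window"
            )

    steps = np.diff(xy, axis=0)
    headings = np.degrees(np.arctan2(steps[:, 1], steps[:, 0]))
    to_chamber = chamber - xy[:-1]
    bearings = np.degrees(np.arctan2(to_chamber[:, 1], to_chamber[:, 0]))
    dist = np.linalg.norm(xy - chamber, axis=1)
    moving = np.linalg.norm(steps, axis=1) > 1e-12
    cond = (_angdiff(headings, bearings) <= cone_deg) & (np.diff(dist) < 0) & moving

    run = 0
    for i, ok in enumerate(cond):
        run = run + 1 if ok else 0
        if run == persistence:
            k = i - persistence + 1  # first step of the run
            if k + 1 < 3:
                raise DegenerateTrajectoryError(
                    f"trial {traj.trial_id}: turn-back at sample {k} leaves <3 samples"
                )
            return Trajectory(traj.trial_id, traj.fish_id, t[: k + 1], xy[: k + 1], crop_index=k)
    return Trajectory(traj.trial_id, traj.fish_id, t, xy, crop_index=None)
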