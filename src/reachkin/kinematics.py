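"""Per-reach kinematic scalars and trajectory summaries.

For every segmented reach the module extracts the standard scalar set of
the skilled-reaching literature: reach duration, endpoint coordinates
(distance to the pellet per axis, taken at the apex of forward
extension), path length of the outward phase, mean and maximum speed,
relative timing of the speed peak, and the maxima of acceleration and
jerk magnitudes.  Derivatives are taken by central differences on the
smoothed trajectory — third differences of raw 100 Hz positions are
noise-dominated, so smoothing is a precondition, not an option.

``average_trajectory`` builds the time-normalized mean +/- SD band per
axis (forward / sideward / upward) across the reaches of a session, the
summary used to compare reach shapes between categories or days.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .trajectory import ReachSegment, Trajectory3D, _runs

#: Numeric feature columns used for clustering.
FEATURE_COLUMNS = (
    "duration_s",
    "end_x_mm",
    "end_y_mm",
    "end_z_mm",
    "path_mm",
    "vmean_mm_s",
    "vmax_mm_s",
    "tvmax_frac",
    "amax_mm_s2",
    "jmax_mm_s3",
    "apex_x_mm",
    "apex_y_mm",
    "apex_z_mm",
)


@dataclasses.dataclass
class ReachScalars:
    """Kinematic feature vector of a single reach.

    Positions are mm relative to the pellet rest position, so endpoint
    magnitudes read directly as per-axis distance to the pellet.  The
    endpoint is taken at the apex frame (maximal forward extension) —
    the segment end belongs to the retraction, not to the reach target.
    ``complete_frac`` is the fraction of finite frames inside the
    segment; below 0.5 the kinematic fields are NaN and the reach should
    be scored as an artifact downstream.
    """

    duration_s: float
    end_x_mm: float
    end_y_mm: float
    end_z_mm: float
    path_mm: float
    vmean_mm_s: float
    vmax_mm_s: float
    tvmax_frac: float
    amax_mm_s2: float
    jmax_mm_s3: float
    apex_x_mm: float
    apex_y_mm: float
    apex_z_mm: float
    complete_frac: float


def differentiate(traj: Trajectory3D, order: int = 1) -> np.ndarray:
    """Numerical derivative of a trajectory, mm/s^order.

    Central differences on interior frames and one-sided differences at
    run edges, applied independently to each finite run of each
    coordinate; runs shorter than ``order + 1`` frames become NaN with a
    warning.  NaN frames propagate (the derivative is only defined where
    the position is).
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    dt = 1.0 / traj.fs
    out = np.full_like(traj.xyz, np.nan)
    short_runs = 0
    for c in range(3):
        v = traj.xyz[:, c]
        for r0, r1 in _runs(np.isfinite(v)):
            if r1 - r0 < order + 1:
                short_runs += 1
                continue
            vals = v[r0:r1]
            for _ in range(order):
                vals = np.gradient(vals, dt)
            out[r0:r1, c] = vals
    if short_runs:
        warnings.warn(
            f"{short_runs} finite runs too short for order-{order} derivative",
            stacklevel=2,
        )
    return out


def _speed(traj: Trajectory3D) -> np.ndarray:
    v = differentiate(traj, 1)
    return np.linalg.norm(v, axis=1)


def compute_scalars(seg: ReachSegment, traj: Trajectory3D) -> ReachScalars:
    """Extract the kinematic scalar set of one reach segment."""
    if seg.end > traj.n_frames:
        raise ValueError("segment exceeds trajectory bounds")
    sl = slice(seg.start, seg.end)
    xyz = traj.xyz[sl]
    finite = np.isfinite(xyz).all(axis=1)
    complete = float(finite.mean()) if len(finite) else 0.0
    duration = seg.n_frames / traj.fs
    if complete < 0.5:
        nan = float("nan")
        return ReachScalars(
            duration, nan, nan, nan, nan, nan, nan, nan, nan, nan, nan, nan, nan,
            complete_frac=complete,
        )
    apex_pos = traj.xyz[seg.apex_frame]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        speed = _speed(traj)[sl]
        accel = np.linalg.norm(differentiate(traj, 2), axis=1)[sl]
        jerk = np.linalg.norm(differentiate(traj, 3), axis=1)[sl]
        vmax = float(np.nanmax(speed)) if np.isfinite(speed).any() else float("nan")
        vmean = float(np.nanmean(speed)) if np.isfinite(speed).any() else float("nan")
        amax = float(np.nanmax(accel)) if np.isfinite(accel).any() else float("nan")
        jmax = float(np.nanmax(jerk)) if np.isfinite(jerk).any() else float("nan")
    if np.isfinite(speed).any():
        tvmax = float(np.nanargmax(speed)) / seg.n_frames
    else:
        tvmax = float("nan")
    # outward path: sum of consecutive finite steps from start to apex
    outward = traj.xyz[seg.start : seg.apex_frame + 1]
    ok = np.isfinite(outward).all(axis=1)
    steps = np.linalg.norm(np.diff(outward, axis=0), axis=1)
    both = ok[:-1] & ok[1:]
    path = float(np.nansum(steps[both])) if both.any() else 0.0
    return ReachScalars(
        duration_s=duration,
        end_x_mm=float(apex_pos[0]),
        end_y_mm=float(apex_pos[1]),
        end_z_mm=float(apex_pos[2]),
        path_mm=path,
        vmean_mm_s=vmean,
        vmax_mm_s=vmax,
        tvmax_frac=tvmax,
        amax_mm_s2=amax,
        jmax_mm_s3=jmax,
        apex_x_mm=float(apex_pos[0]),
        apex_y_mm=float(apex_pos[1]),
        apex_z_mm=float(apex_pos[2]),
        complete_frac=complete,
    )


def scalar_table(
    segments: Sequence[ReachSegment],
    traj: Trajectory3D,
    labels: Sequence | None = None,
) -> pd.DataFrame:
    """One row per reach: segment bounds, scalar features, outcome label."""
    rows = []
    for i, seg in enumerate(segments):
        sc = compute_scalars(seg, traj)
        row = {"start_frame": seg.start, "end_frame": seg.end}
        row.update({k: v for k, v in dataclasses.asdict(sc).items() if k != "complete_frac"})
        row["label"] = str(labels[i]) if labels is not None else ""
        row["cluster"] = pd.NA
        rows.append(row)
    cols = ["start_frame", "end_frame", *FEATURE_COLUMNS, "label", "cluster"]
    return pd.DataFrame(rows, columns=cols)


@dataclasses.dataclass
class AverageTrajectory:
    """Pointwise mean +/- SD of time-normalized reaches, per axis."""

    fraction: np.ndarray  # (n_samples,) normalized time in [0, 1]
    mean: np.ndarray  # (n_samples, 3) mm
    sd: np.ndarray  # (n_samples, 3) mm
    n_reaches: int


def average_trajectory(
    segments: Sequence[ReachSegment],
    traj: Trajectory3D,
    n_samples: int = 100,
) -> AverageTrajectory:
    """Average reach shape across segments.

    Each reach is linearly time-normalized to ``n_samples`` points and
    averaged pointwise per axis (forward / sideward / upward, values as
    distance to the pellet); the per-axis SD band quantifies reach
    variability.  Reaches with no finite frames are skipped.
    """
    if not segments:
        raise ValueError("average_trajectory needs at least one segment")
    frac = np.linspace(0.0, 1.0, n_samples)
    curves = []
    for seg in segments:
        frames = np.arange(seg.start, seg.end)
        q = seg.start + frac * (seg.n_frames - 1)
        cols = []
        for c in range(3):
            v = traj.xyz[seg.start : seg.end, c]
            ok = np.isfinite(v)
            if not ok.any():
                cols = None
                break
            cols.append(np.interp(q, frames[ok], v[ok]))
        if cols is not None:
            curves.append(np.column_stack(cols))
    if not curves:
        raise ValueError("no segment had finite frames")
    stack = np.stack(curves)
    return AverageTrajectory(
        fraction=frac,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0),
        n_reaches=len(curves),
    )
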