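"""3D trajectory containers, cleaning, and reach segmentation.

Coordinates follow the reaching-box convention: the origin sits at the
pellet rest position, +x points forward (from the slit toward the pellet),
+y sideward, +z upward; units are millimetres.  Time is ``frame / fs``
seconds with a 0-based contiguous frame index.

The paw trajectory of a training session is a sequence of idle epochs
(paw resting at the slit) interrupted by reach events: fast forward
excursions toward the pellet followed by retraction.  ``segment_reaches``
detects those events from the forward (x) coordinate with a
peak-prominence criterion and hysteresis bounds, replacing manual span
selection with a reproducible detector; ``load_manual_segments`` ingests
hand-picked spans for parity with a manual workflow.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .exceptions import SegmentValidationError


@dataclasses.dataclass
class Trajectory3D:
    """Per-frame 3D track of one keypoint, NaN marking missing frames.

    Parameters
    ----------
    xyz : (n, 3) float array, mm
    fs : float
        Sampling rate, frames per second.
    keypoint : str
        Name of the tracked body part ("palm", "pellet", ...).
    """

    xyz: np.ndarray
    fs: float = 100.0
    keypoint: str = "palm"

    def __post_init__(self):
        self.xyz = np.array(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n_frames, 3)")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    @property
    def t(self) -> np.ndarray:
        """Time of each frame in seconds."""
        return np.arange(self.n_frames) / self.fs

    def finite_mask(self) -> np.ndarray:
        """Boolean mask of frames where all three coordinates are finite."""
        return np.isfinite(self.xyz).all(axis=1)

    def copy(self) -> "Trajectory3D":
        return Trajectory3D(self.xyz.copy(), self.fs, self.keypoint)


@dataclasses.dataclass(frozen=True)
class ReachSegment:
    """Half-open frame window ``[start, end)`` containing one reach."""

    start: int
    end: int
    apex_frame: int
    source: str = "auto"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end})")
        if not (self.start <= self.apex_frame < self.end):
            raise ValueError(
                f"apex frame {self.apex_frame} outside [{self.start}, {self.end})"
            )

    @property
    def n_frames(self) -> int:
        return self.end - self.start

    def duration_s(self, fs: float) -> float:
        return self.n_frames / fs


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where ``mask`` is True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def interpolate_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly fill NaN gaps of length <= max_gap bounded by finite samples.

    Longer gaps and gaps touching the array edges are left missing.
    """
    out = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(out)
    if max_gap <= 0 or finite.all() or not finite.any():
        return out
    for g0, g1 in _runs(~finite):
        if g0 == 0 or g1 == len(out):
            continue  # edge gap: no bracketing samples
        if g1 - g0 > max_gap:
            continue
        x0, x1 = out[g0 - 1], out[g1]
        frac = np.arange(1, g1 - g0 + 1) / (g1 - g0 + 1)
        out[g0:g1] = x0 + frac * (x1 - x0)
    return out


def smooth_series(values: np.ndarray, window: int, order: int) -> np.ndarray:
    """Savitzky-Golay smooth each finite run; short runs are left as-is."""
    if window % 2 == 0 or window <= order:
        raise ValueError("smooth window must be odd and greater than the order")
    out = np.asarray(values, dtype=float).copy()
    for r0, r1 in _runs(np.isfinite(out)):
        if r1 - r0 < window:
            warnings.warn(
                f"finite run of {r1 - r0} frames shorter than smoothing window "
                f"{window}; left unsmoothed",
                stacklevel=2,
            )
            continue
        out[r0:r1] = savgol_filter(out[r0:r1], window, order, mode="interp")
    return out


def preprocess_trajectory(
    traj: Trajectory3D,
    max_gap: int = 5,
    smooth_window: int = 7,
    smooth_order: int = 3,
) -> Trajectory3D:
    """Gap-fill and smooth a 3D trajectory, per coordinate."""
    xyz = traj.xyz.copy()
    for c in range(3):
        v = interpolate_gaps(xyz[:, c], max_gap)
        xyz[:, c] = smooth_series(v, smooth_window, smooth_order)
    return Trajectory3D(xyz, traj.fs, traj.keypoint)


def preprocess(
    obj,
    likelihood_min: float = 0.6,
    max_gap: int = 5,
    smooth_window: int = 7,
    smooth_order: int = 3,
):
    """Clean a 2D keypoint track or a 3D trajectory.

    For 2D tracks (objects exposing ``data`` / ``keypoints``), samples with
    likelihood below ``likelihood_min`` are first set missing; for both
    kinds, gaps up to ``max_gap`` frames are linearly interpolated and the
    remaining finite runs are Savitzky-Golay smoothed.
    """
    if isinstance(obj, Trajectory3D):
        return preprocess_trajectory(obj, max_gap, smooth_window, smooth_order)
    if hasattr(obj, "data") and hasattr(obj, "keypoints"):
        data = obj.data.copy()
        for kp in obj.keypoints:
            bad = data[f"{kp}_likelihood"].to_numpy() < likelihood_min
            for field in ("u", "v"):
                col = f"{kp}_{field}"
                v = data[col].to_numpy(dtype=float).copy()
                v[bad] = np.nan
                v = interpolate_gaps(v, max_gap)
                data[col] = smooth_series(v, smooth_window, smooth_order)
        return type(obj)(data=data, fs=obj.fs, view_id=obj.view_id)
    raise TypeError(f"cannot preprocess object of type {type(obj)!r}")


def segment_reaches(
    traj: Trajectory3D,
    forward_threshold: float = 2.0,
    min_prominence: float = 3.0,
    min_duration: int = 10,
    max_duration: int = 200,
    baseline: float | None = None,
) -> list[ReachSegment]:
    """Detect reach events as prominent forward (x) excursions.

    A reach apex is a local maximum of x(t) with prominence at least
    ``min_prominence`` mm whose height exceeds ``baseline +
    forward_threshold``.  Segment bounds extend outward from the apex to
    the hysteresis level ``baseline + 0.25 * prominence``; segments with
    duration outside ``[min_duration, max_duration]`` frames are
    discarded.  ``baseline`` defaults to the median of the finite forward
    coordinate (the paw rests at the slit most of the time, so the median
    tracks the slit plane).

    Returns segments sorted by start frame; overlaps between neighbouring
    apexes are cut at the minimum of x between them (earlier apex wins the
    boundary frame).
    """
    if forward_threshold <= 0 or min_prominence <= 0:
        raise ValueError("thresholds must be positive")
    x = traj.x
    finite = np.isfinite(x)
    if not finite.any():
        return []
    if baseline is None:
        baseline = float(np.median(x[finite]))
    xm = np.where(finite, x, -np.inf)
    peaks, props = find_peaks(xm, prominence=min_prominence)
    n = len(x)
    raw: list[tuple[int, int, int]] = []
    for p, prom in zip(peaks, props["prominences"]):
        if x[p] < baseline + forward_threshold:
            continue
        thr = baseline + 0.25 * float(prom)
        s = int(p)
        while s > 0 and xm[s - 1] >= thr:
            s -= 1
        e = int(p)
        while e < n - 1 and xm[e + 1] >= thr:
            e += 1
        raw.append((s, e + 1, int(p)))
    raw.sort(key=lambda t: (t[0], t[2]))
    # overlapping spans mean x never crossed below threshold between the
    # peaks: one excursion, keep the higher apex (earlier apex on ties)
    merged: list[tuple[int, int, int]] = []
    for s, e, a in raw:
        if merged and s < merged[-1][1]:
            s0, e0, a0 = merged[-1]
            keep = a0 if xm[a0] >= xm[a] else a
            merged[-1] = (s0, max(e0, e), keep)
        else:
            merged.append((s, e, a))
    segments = []
    for s, e, a in merged:
        if min_duration <= e - s <= max_duration:
            segments.append(ReachSegment(s, e, a, source="auto"))
    return segments


def load_manual_segments(path, traj: Trajectory3D) -> list[ReachSegment]:
    """Read manually selected reach spans from a CSV of (start_frame, end_frame).

    Spans are half-open frame windows validated against the trajectory
    length; invalid or mutually overlapping spans raise
    :class:`SegmentValidationError` listing every offender.  The apex of
    each span is the frame of maximal forward extension within it.
    """
    df = pd.read_csv(path)
    required = {"start_frame", "end_frame"}
    if not required.issubset(df.columns):
        raise SegmentValidationError(
            f"manual segment file must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    spans = [(int(r.start_frame), int(r.end_frame)) for r in df.itertuples()]
    n = traj.n_frames
    offenders = [sp for sp in spans if not (0 <= sp[0] < sp[1] <= n)]
    ordered = sorted(spans)
    for (s0, e0), (s1, e1) in zip(ordered, ordered[1:]):
        if e0 > s1:
            offenders.append((s1, e1))
    if offenders:
        raise SegmentValidationError(
            f"invalid or overlapping spans: {sorted(set(offenders))}",
            offenders=sorted(set(offenders)),
        )
    segments = []
    for s, e in ordered:
        xs = traj.x[s:e]
        if np.isfinite(xs).any():
            apex = s + int(np.nanargmax(xs))
        else:
            apex = s
        segments.append(ReachSegment(s, e, apex, source="manual"))
    return segments
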