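"""End-to-end convenience wrappers: 2D tracks -> 3D -> segments -> scalars.

These functions chain the module-level operations in the order a session
is actually processed: mask low-likelihood 2D samples, triangulate each
keypoint across the front and mirror views, clean and smooth the 3D
trajectories, optionally align them onto the static reference points,
detect reaches on the palm, classify outcomes against the pellet track
and assemble the per-reach scalar table.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import pandas as pd

from .geometry import CameraModel, align_to_reference, triangulate
from .io_formats import Keypoint2DTrack
from .kinematics import scalar_table
from .outcomes import ClassifierParams, OutcomeLabel, classify_session
from .trajectory import (
    ReachSegment,
    Trajectory3D,
    preprocess_trajectory,
    segment_reaches,
)


def reconstruct(
    tracks: Mapping[str, Keypoint2DTrack],
    cameras: Mapping[str, CameraModel],
    keypoints: Sequence[str] | None = None,
    likelihood_min: float = 0.6,
    max_gap: int = 5,
    smooth_window: int = 7,
    smooth_order: int = 3,
    reference_points: Mapping[str, Sequence[float]] | None = None,
) -> dict[str, Trajectory3D]:
    """Triangulate per-view 2D tracks into cleaned 3D trajectories.

    Uses every view present in both ``tracks`` and ``cameras``.  Samples
    below ``likelihood_min`` are dropped before triangulation; frames
    seen by fewer than two views come out NaN and are gap-filled (up to
    ``max_gap``) and smoothed afterwards.  When ``reference_points``
    gives the triangulated static points, all trajectories are mapped
    onto the nominal box frame with a similarity transform.
    """
    views = [v for v in tracks if v in cameras]
    if len(views) < 2:
        raise ValueError(f"need >= 2 views with cameras, got {views}")
    if keypoints is None:
        common = set(tracks[views[0]].keypoints)
        for v in views[1:]:
            common &= set(tracks[v].keypoints)
        keypoints = sorted(common)
    fs = tracks[views[0]].fs
    cams = [cameras[v] for v in views]
    out: dict[str, Trajectory3D] = {}
    for kp in keypoints:
        obs = [tracks[v].masked_uv(kp, likelihood_min) for v in views]
        xyz = triangulate(obs, cams)
        traj = Trajectory3D(xyz, fs=fs, keypoint=kp)
        out[kp] = preprocess_trajectory(traj, max_gap, smooth_window, smooth_order)
    if reference_points is not None:
        aligned = {}
        for kp, traj in out.items():
            aligned[kp], _ = align_to_reference(traj, reference_points)
        out = aligned
    return out


def score_session(
    palm: Trajectory3D,
    pellet: Trajectory3D | None = None,
    segments: Sequence[ReachSegment] | None = None,
    classifier_params: ClassifierParams | None = None,
    manual_labels: Mapping[int, OutcomeLabel] | None = None,
    **segment_kwargs,
) -> tuple[list[ReachSegment], pd.DataFrame]:
    """Segment a palm trajectory and build the labeled scalar table.

    ``segments`` overrides automatic detection (e.g. manually selected
    spans); labels come from the rule cascade when a pellet trajectory is
    available, with ``manual_labels`` taking precedence per segment.
    """
    if segments is None:
        segments = segment_reaches(palm, **segment_kwargs)
    segments = list(segments)
    labels = None
    if pellet is not None and segments:
        labels = classify_session(
            segments, palm, pellet, classifier_params, manual=manual_labels
        )
    table = scalar_table(segments, palm, labels=labels)
    return segments, table
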