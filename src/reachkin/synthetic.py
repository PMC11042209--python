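"""Synthetic reach-to-grasp scenes with exact ground truth.

Every downstream module is testable without video: this module builds a
full training-session fixture — minimum-jerk paw reaches of each outcome
category, pellet dynamics, a front camera plus two mirror views, a
checkerboard calibration target and an Arduino-style sensor log — all
deterministic under a single seed.

The reach model is the minimum-jerk point-to-point movement
``s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5``: the quintic with zero
velocity and acceleration at both ends, the standard idealization of
ballistic limb transport.  Its closed form gives exact expected scalars
(peak speed 1.875 D/T at mid-movement), which is what makes parameter
recovery checkable.

Geometry follows the reaching-box convention: origin at the pellet rest
position, +x forward (slit toward pellet), +y sideward, +z up, mm.  The
slit plane sits ``slit_pellet_distance`` behind the pellet.  Mirror
views are produced *independently* of the geometry module: each 3D point
is reflected about the mirror plane with the explicit Householder
formula and projected through the front camera, so virtual-camera
algebra can be validated against this generator.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CameraModel, Correspondences, mirror_camera
from .io_formats import (
    Keypoint2DTrack,
    SensorLog,
    write_calibration,
    write_sensor_log,
    write_track_table,
    write_trajectory_table,
)
from .outcomes import OutcomeLabel
from .session_metrics import SessionCounts
from .trajectory import Trajectory3D

#: Outcome composition of a default synthetic session.  Artifacts are
#: recording failures rather than behaviors and are opt-in via the mix.
DEFAULT_OUTCOME_MIX: dict[OutcomeLabel, float] = {
    OutcomeLabel.GRASPED: 0.35,
    OutcomeLabel.MISSED: 0.25,
    OutcomeLabel.FLICKED: 0.15,
    OutcomeLabel.LOST: 0.10,
    OutcomeLabel.IN_VAIN: 0.15,
}


@dataclasses.dataclass
class SceneConfig:
    """Study conditions of the synthetic scene.

    Defaults encode the physical setup: 100 Hz camera sampling, pellet
    rest position 7 mm in front of the slit, ~2 mm pellet, a 4x4-square
    checkerboard with 1 mm pitch for calibration, and tracker-like noise
    (0.5 px in image space, 0.05 mm in world space).
    """

    fs: float = 100.0
    slit_pellet_distance: float = 7.0
    pellet_diameter: float = 2.0
    board_rows: int = 4
    board_cols: int = 4
    board_square_mm: float = 1.0
    noise_px: float = 0.5
    noise_mm: float = 0.05
    dropout: float = 0.0
    mouth_point: tuple[float, float, float] = (-10.0, 0.0, 5.0)
    idle_jitter_mm: float = 0.02
    reach_time_range_s: tuple[float, float] = (0.25, 0.40)
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name in ("slit_pellet_distance", "pellet_diameter", "board_square_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# cameras and mirrors


def _look_at_camera(
    center, target, f: float = 1800.0, image_size=(1440, 1080)
) -> CameraModel:
    """Pinhole camera at ``center`` looking at ``target``, +z world up."""
    C = np.asarray(center, dtype=float)
    z = np.asarray(target, dtype=float) - C
    z /= np.linalg.norm(z)
    x = np.cross(z, np.array([0.0, 0.0, 1.0]))
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    K = np.array(
        [[f, 0.0, image_size[0] / 2], [0.0, f, image_size[1] / 2], [0.0, 0.0, 1.0]]
    )
    P = K @ np.hstack([R, (-R @ C)[:, None]])
    return CameraModel(P, mirrored=False, image_size=image_size)


@dataclasses.dataclass
class SceneGeometry:
    """Front camera plus the two mirror planes (point, unit normal)."""

    front: CameraModel
    mirror_planes: dict[str, tuple[np.ndarray, np.ndarray]]

    def virtual_camera(self, view: str) -> CameraModel:
        point, normal = self.mirror_planes[view]
        return mirror_camera(self.front, point, normal)

    def cameras(self, views: Sequence[str]) -> dict[str, CameraModel]:
        out = {}
        for v in views:
            out[v] = self.front if v == "front" else self.virtual_camera(v)
        return out


def default_geometry(config: SceneConfig | None = None) -> SceneGeometry:
    """Camera 26 cm in front of the box, mirrors at 45 deg flanking it."""
    front = _look_at_camera((260.0, 0.0, 40.0), (0.0, 0.0, 0.0))
    s = np.sqrt(0.5)
    planes = {
        "left_mirror": (np.array([-2.0, -28.0, 0.0]), np.array([s, s, 0.0])),
        "right_mirror": (np.array([-2.0, 28.0, 0.0]), np.array([s, -s, 0.0])),
    }
    return SceneGeometry(front=front, mirror_planes=planes)


def _reflect(points: np.ndarray, point, normal) -> np.ndarray:
    """Householder reflection of (n, 3) points about a mirror plane.

    Deliberately independent of geometry.reflection_matrix so the two
    code paths can cross-check each other.
    """
    p = np.asarray(point, dtype=float)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    X = np.atleast_2d(np.asarray(points, dtype=float))
    return X - 2.0 * ((X - p) @ n)[:, None] * n[None, :]


# ---------------------------------------------------------------------------
# checkerboard calibration fixtures


def checkerboard_corners(
    rows: int = 4, cols: int = 4, square: float = 1.0
) -> np.ndarray:
    """Corner grid of a rows x cols *squares* board: (rows+1)(cols+1)
    points with exact ``square`` mm pitch, ordered left-to-right,
    top-to-bottom, centered at the board origin in its own plane."""
    jj, ii = np.meshgrid(np.arange(cols + 1), np.arange(rows + 1))
    pts = np.column_stack(
        [
            (jj.ravel() - cols / 2) * square,
            (ii.ravel() - rows / 2) * square,
            np.zeros((rows + 1) * (cols + 1)),
        ]
    )
    return pts


def _rotation_from_rotvec(v: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.eye(3)
    k = v / angle
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def checkerboard_scene(
    config: SceneConfig,
    geometry: SceneGeometry | None = None,
    n_poses: int = 3,
    views: Sequence[str] = ("front", "left_mirror"),
    noise_px: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, dict[str, Correspondences]]:
    """Checkerboard corners in >= 3 poses with per-view projections.

    A single board plane is degenerate for DLT, so poses are rotated and
    shifted copies of the board near the pellet workspace.  Returns the
    stacked world corners and per-view :class:`Correspondences` (pixel
    noise optional).
    """
    if n_poses < 2:
        raise ValueError("need >= 2 board poses for a non-coplanar point set")
    if geometry is None:
        geometry = default_geometry(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    base = checkerboard_corners(config.board_rows, config.board_cols, config.board_square_mm)
    world = []
    for _ in range(n_poses):
        R = _rotation_from_rotvec(rng.uniform(-0.6, 0.6, size=3))
        t = np.array(
            [rng.uniform(-2, 2), rng.uniform(-3, 3), rng.uniform(4, 10)]
        )
        world.append(base @ R.T + t)
    world = np.vstack(world)
    corr = {}
    for view in views:
        if view == "front":
            img = geometry.front.project(world)
        else:
            point, normal = geometry.mirror_planes[view]
            img = geometry.front.project(_reflect(world, point, normal))
        if noise_px > 0:
            img = img + rng.normal(0.0, noise_px, size=img.shape)
        corr[view] = Correspondences(world.copy(), img, view_id=view)
    return world, corr


# ---------------------------------------------------------------------------
# minimum-jerk reaches


def min_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalized displacement 10 tau^3 - 15 tau^4 + 6 tau^5 on [0, 1]."""
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


#: Peak of the minimum-jerk speed profile in units of D/T (at tau = 1/2).
MIN_JERK_PEAK_SPEED = 1.875


def min_jerk_reach(
    D: float,
    T: float,
    fs: float,
    target,
    start=(0.0, 0.0, 0.0),
) -> Trajectory3D:
    """Straight minimum-jerk movement of amplitude ``D`` mm over ``T`` s.

    The movement runs from ``start`` a distance ``D`` along the
    direction toward ``target`` (so the endpoint is ``target`` exactly
    when ``|target - start| = D``), sampled at ``fs`` with zero velocity
    and acceleration at both ends.
    """
    if D <= 0 or T <= 0:
        raise ValueError("D and T must be positive")
    n = int(round(T * fs))
    if n < 4:
        raise ValueError(f"T*fs = {T * fs:.1f} gives too few samples (< 4)")
    p0 = np.asarray(start, dtype=float)
    direction = np.asarray(target, dtype=float) - p0
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("target must differ from start")
    direction = direction / norm
    tau = np.arange(n + 1) / n
    xyz = p0[None, :] + (D * min_jerk_profile(tau))[:, None] * direction[None, :]
    return Trajectory3D(xyz, fs=fs, keypoint="palm")


# ---------------------------------------------------------------------------
# full sessions


@dataclasses.dataclass(frozen=True)
class ReachTruth:
    """Ground truth for one generated reach."""

    start: int
    end: int
    apex_frame: int
    label: OutcomeLabel
    paw: str  # "left" | "right"
    target: tuple[float, float, float]  # apex position, mm
    amplitude_mm: float  # D of the outward minimum-jerk phase
    reach_time_s: float  # T of the outward phase
    max_speed_mm_s: float  # peak speed over the window, 1.875 * dist / T of its fastest phase
    duration_s: float  # full window (out + hold + retract)


@dataclasses.dataclass
class SessionData:
    """One synthetic training session with its ground truth."""

    trajectories: dict[str, Trajectory3D]
    truth: list[ReachTruth]
    sensor_log: SensorLog
    config: SceneConfig
    geometry: SceneGeometry

    @property
    def n_frames(self) -> int:
        return self.trajectories["palm"].n_frames

    def counts(self) -> SessionCounts:
        """Session counts with grasped as success; artifacts not scored."""
        fr = fl = sr = sl = 0
        for r in self.truth:
            if r.label is OutcomeLabel.ARTIFACT:
                continue
            if r.label is OutcomeLabel.GRASPED:
                if r.paw == "right":
                    sr += 1
                else:
                    sl += 1
            elif r.paw == "right":
                fr += 1
            else:
                fl += 1
        return SessionCounts(fr, fl, sr, sl)


def _phase(p0: np.ndarray, p1: np.ndarray, n: int) -> np.ndarray:
    """n frames moving p0 -> p1 on a minimum-jerk profile, ending at p1
    (the starting point itself is not repeated)."""
    tau = np.arange(1, n + 1) / n
    return p0[None, :] + min_jerk_profile(tau)[:, None] * (p1 - p0)[None, :]


def generate_session(
    config: SceneConfig,
    n_reaches: int = 8,
    outcome_mix: Mapping[OutcomeLabel, float] | None = None,
    paw_bias: float = 0.5,
) -> SessionData:
    """Generate one session: idle epochs alternating with reach events.

    Each reach is an outward minimum-jerk transport from the slit rest
    position to an outcome-dependent apex, a short hold, and a
    minimum-jerk retraction (via the mouth for grasped/lost).  Pellet
    dynamics implement the outcome semantics: co-transport to the mouth
    (grasped), co-transport then drop (lost), a fast knock-off (flicked),
    a static pellet (missed), no pellet (in_vain) or a mostly-missing paw
    track (artifact).  The sensor log's front-bar channel rises at every
    reach onset.  All randomness derives from ``config.seed``.
    """
    mix = dict(DEFAULT_OUTCOME_MIX if outcome_mix is None else outcome_mix)
    probs = np.array([float(v) for v in mix.values()])
    if n_reaches < 0:
        raise ValueError("n_reaches must be >= 0")
    if len(probs) == 0 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("outcome_mix probabilities must be >= 0 and sum to 1")
    if not 0.0 <= paw_bias <= 1.0:
        raise ValueError("paw_bias must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    slit_x = -config.slit_pellet_distance
    mouth = np.asarray(config.mouth_point, dtype=float)
    pellet_rest = np.zeros(3)
    labels = list(mix.keys())
    drawn = [labels[i] for i in rng.choice(len(labels), size=n_reaches, p=probs)]
    paws = ["right" if rng.random() < paw_bias else "left" for _ in range(n_reaches)]

    palm_parts: list[np.ndarray] = []
    pellet_parts: list[np.ndarray] = []
    bar_parts: list[np.ndarray] = []
    truth: list[ReachTruth] = []
    cursor = 0
    prev_pos: np.ndarray | None = None

    def _idle(rest: np.ndarray, n: int, pellet_present: bool) -> None:
        # the paw moves continuously: walk from wherever it was to the new
        # rest posture over the first idle frames, then hold with jitter
        nonlocal cursor
        pos = np.repeat(rest[None, :], n, axis=0)
        if prev_pos is not None and n > 20:
            pos[:12] = _phase(prev_pos, rest, 12)
        pos += rng.normal(0.0, config.idle_jitter_mm, size=(n, 3))
        palm_parts.append(pos)
        pel = np.repeat(pellet_rest[None, :], n, axis=0)
        if not pellet_present:
            pel[:] = np.nan
        pellet_parts.append(pel)
        bar_parts.append(np.zeros(n, dtype=int))
        cursor += n

    for label, paw in zip(drawn, paws):
        side = 1.0 if paw == "right" else -1.0
        rest = np.array([slit_x, side * 1.2 + rng.normal(0.0, 0.2), 0.5])
        _idle(rest, int(rng.integers(40, 80)), pellet_present=label is not OutcomeLabel.IN_VAIN)

        if label is OutcomeLabel.MISSED:
            apex = pellet_rest + np.array(
                [0.0, side * rng.uniform(3.5, 5.0), rng.uniform(0.0, 1.5)]
            )
        elif label is OutcomeLabel.IN_VAIN:
            apex = pellet_rest + rng.normal(0.0, 0.2, size=3)
        else:
            off = rng.normal(0.0, 1.0, size=3)
            apex = pellet_rest + 0.3 * off / max(np.linalg.norm(off), 1e-9)

        T_out = rng.uniform(*config.reach_time_range_s)
        n_out = int(round(T_out * fs))
        D = float(np.linalg.norm(apex - rest))
        reach_start = cursor
        palm_out = _phase(rest, apex, n_out)
        n_hold = 3  # static grasp hold at the apex
        palm_hold = np.repeat(apex[None, :], n_hold, axis=0)

        via_mouth = label in (OutcomeLabel.GRASPED, OutcomeLabel.LOST, OutcomeLabel.ARTIFACT)
        n_ret1 = int(round(rng.uniform(0.25, 0.35) * fs))
        phase_speeds = [MIN_JERK_PEAK_SPEED * D / (n_out / fs)]
        if via_mouth:
            n_ret2 = int(round(rng.uniform(0.20, 0.30) * fs))
            palm_ret = np.vstack([_phase(apex, mouth, n_ret1), _phase(mouth, rest, n_ret2)])
            phase_speeds.append(
                MIN_JERK_PEAK_SPEED * float(np.linalg.norm(mouth - apex)) / (n_ret1 / fs)
            )
            phase_speeds.append(
                MIN_JERK_PEAK_SPEED * float(np.linalg.norm(rest - mouth)) / (n_ret2 / fs)
            )
        else:
            palm_ret = _phase(apex, rest, n_ret1)
            phase_speeds.append(
                MIN_JERK_PEAK_SPEED * float(np.linalg.norm(rest - apex)) / (n_ret1 / fs)
            )
        palm_reach = np.vstack([palm_out, palm_hold, palm_ret])
        n_win = palm_reach.shape[0]
        reach_end = reach_start + n_win

        # pellet dynamics; grip offset stays inside the contact radius but
        # past displacement_min quickly once transport starts
        pel = np.repeat(pellet_rest[None, :], n_win, axis=0)
        grip = np.array([0.3, 0.0, 0.6])
        pickup = n_out + n_hold  # first retraction frame
        if label is OutcomeLabel.IN_VAIN:
            pel[:] = np.nan
        elif label in (OutcomeLabel.GRASPED, OutcomeLabel.ARTIFACT):
            pel[pickup : pickup + n_ret1] = palm_reach[pickup : pickup + n_ret1] + grip
            pel[pickup + n_ret1 :] = mouth + grip
        elif label is OutcomeLabel.LOST:
            # detach early enough that the drop point stays well outside
            # the mouth zone, late enough for a >= 3-frame carried run
            k_det = int(round(rng.uniform(0.35, 0.45) * n_ret1))
            pel[pickup : pickup + k_det] = palm_reach[pickup : pickup + k_det] + grip
            pel[pickup + k_det :] = palm_reach[pickup + k_det - 1] + grip
        elif label is OutcomeLabel.FLICKED:
            ang = rng.uniform(0.2, 0.6)
            dir_flick = np.array([np.cos(ang), side * np.sin(ang), 0.0])
            jump = pellet_rest + 6.0 * dir_flick
            pel[n_out] = pellet_rest + 0.5 * (jump - pellet_rest)
            pel[n_out + 1 :] = jump
        # MISSED: pellet stays at rest

        palm_reach = palm_reach.copy()
        if label is OutcomeLabel.ARTIFACT:
            b0 = int(0.2 * n_win)
            b1 = int(0.8 * n_win)
            palm_reach[b0:b1] = np.nan

        palm_parts.append(palm_reach)
        pellet_parts.append(pel)
        bar_parts.append(np.ones(n_win, dtype=int))
        cursor = reach_end
        prev_pos = rest

        apex_frame = reach_start + n_out  # middle of the 4-frame apex plateau
        truth.append(
            ReachTruth(
                start=reach_start,
                end=reach_end,
                apex_frame=apex_frame,
                label=label,
                paw=paw,
                target=tuple(float(v) for v in apex),
                amplitude_mm=D,
                reach_time_s=n_out / fs,
                max_speed_mm_s=max(phase_speeds),
                duration_s=n_win / fs,
            )
        )

    # trailing idle epoch
    rest_tail = np.array([slit_x, 1.2, 0.5])
    _idle(rest_tail, int(rng.integers(50, 80)), pellet_present=True)

    palm = np.vstack(palm_parts)
    pellet = np.vstack(pellet_parts)
    if config.noise_mm > 0:
        for arr in (palm, pellet):
            mask = np.isfinite(arr)
            arr[mask] += rng.normal(0.0, config.noise_mm, size=int(mask.sum()))

    n_total = palm.shape[0]
    bar = np.concatenate(bar_parts)
    with np.errstate(invalid="ignore"):
        beam = (np.nan_to_num(palm[:, 0], nan=-99.0) > -3.0).astype(int)
    log = SensorLog(
        frame=np.arange(n_total),
        channels={
            "front_bar": bar,
            "floor_touch": (1 - bar).astype(int),
            "beam_break": beam,
        },
    )
    return SessionData(
        trajectories={
            "palm": Trajectory3D(palm, fs=fs, keypoint="palm"),
            "pellet": Trajectory3D(pellet, fs=fs, keypoint="pellet"),
        },
        truth=truth,
        sensor_log=log,
        config=config,
        geometry=default_geometry(config),
    )


# ---------------------------------------------------------------------------
# projection to 2D views


def project_scene(
    trajectories: Mapping[str, Trajectory3D],
    geometry: SceneGeometry,
    noise_px: float = 0.0,
    dropout: float = 0.0,
    seed: int = 0,
    views: Sequence[str] = ("front", "left_mirror"),
) -> dict[str, Keypoint2DTrack]:
    """Project 3D trajectories into per-view 2D keypoint tracks.

    Mirror views reflect each point about the mirror plane and project
    through the front camera (the physical light path).  Gaussian pixel
    noise is added per view; ``dropout`` is the per-frame probability of
    a low-likelihood sample (likelihood < 0.5), all other samples draw a
    high likelihood (> 0.9).  Points behind the camera are marked
    missing.  Deterministic under ``seed``.
    """
    if noise_px < 0 or not 0.0 <= dropout <= 1.0:
        raise ValueError("noise_px must be >= 0 and dropout in [0, 1]")
    rng = np.random.default_rng(seed)
    fs = next(iter(trajectories.values())).fs
    out = {}
    for view in views:
        cols = {}
        for name, traj in trajectories.items():
            X = traj.xyz
            finite = np.isfinite(X).all(axis=1)
            if view == "front":
                Xv = X
            else:
                point, normal = geometry.mirror_planes[view]
                Xv = np.where(finite[:, None], _reflect(X, point, normal), np.nan)
            uv = np.full((X.shape[0], 2), np.nan)
            depths = geometry.front.depths(np.nan_to_num(Xv, nan=1.0))
            ok = finite & (depths > 0)
            if (finite & ~ok).any():
                warnings.warn(
                    f"{int((finite & ~ok).sum())} points behind the camera in "
                    f"view '{view}' marked missing",
                    stacklevel=2,
                )
            if ok.any():
                uv[ok] = geometry.front.project(Xv[ok])
                if noise_px > 0:
                    uv[ok] += rng.normal(0.0, noise_px, size=(int(ok.sum()), 2))
            lk = rng.uniform(0.92, 0.999, size=X.shape[0])
            low = rng.random(X.shape[0]) < dropout
            lk[low] = rng.uniform(0.05, 0.45, size=int(low.sum()))
            lk[~ok] = 0.0
            cols[f"{name}_u"] = uv[:, 0]
            cols[f"{name}_v"] = uv[:, 1]
            cols[f"{name}_likelihood"] = lk
        out[view] = Keypoint2DTrack(data=pd.DataFrame(cols), fs=fs, view_id=view)
    return out


# ---------------------------------------------------------------------------
# fixture emission


def simulate_to_directory(
    config: SceneConfig,
    outdir,
    n_reaches: int = 8,
    outcome_mix: Mapping[OutcomeLabel, float] | None = None,
    paw_bias: float = 0.5,
    views: Sequence[str] = ("front", "left_mirror"),
) -> Path:
    """Emit a complete session fixture set into ``outdir``.

    Writes per-view track tables (CSV), the checkerboard correspondence
    table, the true-camera calibration TOML, the sensor log, the 3D
    ground-truth trajectories and a ground-truth JSON with reach windows,
    labels and exact kinematic parameters.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    session = generate_session(config, n_reaches, outcome_mix, paw_bias)
    geom = session.geometry
    tracks = project_scene(
        session.trajectories,
        geom,
        noise_px=config.noise_px,
        dropout=config.dropout,
        seed=config.seed + 1,
        views=views,
    )
    for view, track in tracks.items():
        write_track_table(track, outdir / f"{view}.csv", dialect="csv")
    write_calibration(geom.cameras(views), outdir / "calibration.toml")
    write_sensor_log(session.sensor_log, outdir / "sensor_log.csv")
    write_trajectory_table(session.trajectories, outdir / "trajectories_3d.csv")
    world, corr = checkerboard_scene(config, geom, views=views, seed=config.seed + 2)
    rows = []
    for view, c in corr.items():
        for i in range(len(c)):
            rows.append(
                {
                    "view": view,
                    "point_id": i,
                    "X": c.object_points[i, 0],
                    "Y": c.object_points[i, 1],
                    "Z": c.object_points[i, 2],
                    "u": c.image_points[i, 0],
                    "v": c.image_points[i, 1],
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "correspondences.csv", index=False)
    gt = {
        "config": {
            "fs": config.fs,
            "slit_pellet_distance": config.slit_pellet_distance,
            "noise_mm": config.noise_mm,
            "noise_px": config.noise_px,
            "seed": config.seed,
        },
        "reaches": [
            {
                "start": r.start,
                "end": r.end,
                "apex_frame": r.apex_frame,
                "label": r.label.value,
                "paw": r.paw,
                "target": list(r.target),
                "amplitude_mm": r.amplitude_mm,
                "reach_time_s": r.reach_time_s,
                "max_speed_mm_s": r.max_speed_mm_s,
                "duration_s": r.duration_s,
            }
            for r in session.truth
        ],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    return outdir


# ---------------------------------------------------------------------------
# cohort-level generator for learning curves


def generate_training_cohort(
    n_animals: int = 6,
    n_days: int = 7,
    seed: int = 0,
    reaches_range: tuple[int, int] = (40, 150),
    success_range: tuple[float, float] = (0.10, 0.35),
    dominance: float = 0.85,
) -> pd.DataFrame:
    """Per-animal, per-day session counts with a configured learning trend.

    Daily reach counts rise linearly across training days toward the
    upper end of ``reaches_range`` (Poisson-dispersed) and success
    probability rises linearly across ``success_range``; each animal has
    a dominant paw used with probability ``dominance``.  Returns a
    long-format counts table consumable by
    :func:`reachkin.session_metrics.metrics_table`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        right_dominant = rng.random() < 0.5
        bias = dominance if right_dominant else 1.0 - dominance
        for d in range(n_days):
            frac = d / max(n_days - 1, 1)
            n = int(rng.poisson(reaches_range[0] + frac * (reaches_range[1] - reaches_range[0])))
            p = success_range[0] + frac * (success_range[1] - success_range[0])
            n_right = int(rng.binomial(n, bias))
            sr = int(rng.binomial(n_right, p))
            sl = int(rng.binomial(n - n_right, p))
            rows.append(
                {
                    "animal": f"m{a + 1}",
                    "day": d + 1,
                    "failed_right": n_right - sr,
                    "failed_left": (n - n_right) - sl,
                    "successful_right": sr,
                    "successful_left": sl,
                }
            )
    return pd.DataFrame(rows)
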