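"""Readers and writers: keypoint track tables, sensor logs, calibration
files, scalar tables and trajectory tables.

This module is the pipeline's only I/O surface.  All formats are plain
text or HDF5:

* track tables — one row per frame, flattened columns ``<keypoint>_u``,
  ``<keypoint>_v``, ``<keypoint>_likelihood`` (CSV) or one HDF5 group per
  view with one dataset per keypoint field, emulating markerless-tracker
  output;
* sensor logs — CSV with a leading camera ``frame`` column and one
  integer column per data stream (front-bar touch, floor touch, beam
  break);
* calibration — TOML with one ``[views.<name>]`` table per camera
  holding the 12 row-major projection-matrix entries, the mirrored flag
  and the image size;
* scalar tables — one row per reach with the kinematic feature columns,
  as CSV or HDF5.
"""

from __future__ import annotations

import dataclasses
import tomllib
from collections.abc import Mapping, Sequence
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .exceptions import FormatError, StructuralError
from .geometry import CameraModel
from .trajectory import Trajectory3D

TRACK_FIELDS = ("u", "v", "likelihood")

#: Fixed column order of the per-reach scalar table.
SCALAR_COLUMNS = (
    "start_frame",
    "end_frame",
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
    "label",
    "cluster",
)


@dataclasses.dataclass
class Keypoint2DTrack:
    """Per-view 2D keypoint time series at a fixed frame rate.

    ``data`` has a 0-based contiguous frame index and, per keypoint,
    columns ``<kp>_u``, ``<kp>_v`` (pixels) and ``<kp>_likelihood``
    (tracker confidence in [0, 1]; NaN allowed for missing frames).
    """

    data: pd.DataFrame
    fs: float = 100.0
    view_id: str = "front"

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        idx = np.asarray(self.data.index)
        if len(idx) and not np.array_equal(idx, np.arange(len(idx))):
            raise StructuralError("frame index must be contiguous and 0-based")
        kps = self.keypoints
        if not kps:
            raise FormatError("track table contains no keypoint columns")
        for kp in kps:
            for field in TRACK_FIELDS:
                if f"{kp}_{field}" not in self.data.columns:
                    raise FormatError(f"missing column '{kp}_{field}'")
            lk = self.data[f"{kp}_likelihood"].to_numpy(dtype=float)
            finite = lk[np.isfinite(lk)]
            if ((finite < 0) | (finite > 1)).any():
                raise FormatError(
                    f"likelihood of '{kp}' outside [0, 1]"
                )

    @property
    def keypoints(self) -> list[str]:
        return sorted(
            {c[: -len("_likelihood")] for c in self.data.columns if c.endswith("_likelihood")}
        )

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def uv(self, keypoint: str) -> np.ndarray:
        """(n, 2) pixel coordinates of one keypoint."""
        return self.data[[f"{keypoint}_u", f"{keypoint}_v"]].to_numpy(dtype=float)

    def likelihood(self, keypoint: str) -> np.ndarray:
        return self.data[f"{keypoint}_likelihood"].to_numpy(dtype=float)

    def masked_uv(self, keypoint: str, likelihood_min: float = 0.6) -> np.ndarray:
        """(n, 2) coordinates with low-likelihood frames set to NaN."""
        uv = self.uv(keypoint).copy()
        uv[~(self.likelihood(keypoint) >= likelihood_min)] = np.nan
        return uv


@dataclasses.dataclass
class SensorLog:
    """Arduino-style sensor streams indexed by camera frame number.

    ``channels`` maps stream name to an integer array aligned with
    ``frame``; boolean semantics (touch / no touch) are applied only by
    edge queries.
    """

    frame: np.ndarray
    channels: dict[str, np.ndarray]

    def __post_init__(self):
        self.frame = np.asarray(self.frame, dtype=int)
        if len(self.frame) > 1 and (np.diff(self.frame) < 0).any():
            raise StructuralError("sensor-log frame numbers must be non-decreasing")
        for name, v in self.channels.items():
            v = np.asarray(v, dtype=int)
            if v.shape != self.frame.shape:
                raise StructuralError(f"channel '{name}' length mismatch")
            self.channels[name] = v

    def __len__(self) -> int:
        return len(self.frame)

    def rising_edges(self, channel: str) -> np.ndarray:
        """Camera frames at which ``channel`` switches from 0 to nonzero.

        Rising edges of the front-bar channel mark candidate trial starts.
        """
        v = (self.channels[channel] != 0).astype(int)
        if len(v) == 0:
            return np.empty(0, dtype=int)
        edges = np.flatnonzero(np.diff(v) == 1) + 1
        return self.frame[edges]


# ---------------------------------------------------------------------------
# track tables


def write_track_table(track: Keypoint2DTrack, path, dialect: str = "csv") -> None:
    path = Path(path)
    if dialect == "csv":
        out = track.data.copy()
        out.insert(0, "frame", np.arange(len(out)))
        out.to_csv(path, index=False)
    elif dialect == "hdf5":
        with h5py.File(path, "a") as f:
            if track.view_id in f:
                del f[track.view_id]
            g = f.create_group(track.view_id)
            g.attrs["fs"] = track.fs
            for kp in track.keypoints:
                gk = g.create_group(kp)
                for field in TRACK_FIELDS:
                    gk.create_dataset(
                        field, data=track.data[f"{kp}_{field}"].to_numpy(dtype=float)
                    )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_track_table(
    path,
    dialect: str = "csv",
    fs: float = 100.0,
    view_id: str | None = None,
    keypoints: Sequence[str] | None = None,
) -> Keypoint2DTrack:
    """Read a per-view keypoint track table.

    ``keypoints``, when given, declares the parts that must be present;
    a missing column raises :class:`FormatError` naming it.  For CSV,
    ``fs`` and ``view_id`` are taken from the arguments (the format
    carries no metadata); HDF5 stores both and ``view_id`` selects the
    group (defaulting to the single group present).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        df = pd.read_csv(path)
        if "frame" not in df.columns:
            raise FormatError("track CSV must have a 'frame' column")
        frames = df["frame"].to_numpy()
        if len(frames) and not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
            raise StructuralError("frame numbers must be contiguous with step 1")
        if len(frames) and frames[0] != 0:
            raise StructuralError("frame index must be 0-based")
        data = df.drop(columns="frame")
        data.index = pd.RangeIndex(len(data))
        track = Keypoint2DTrack(data=data, fs=fs, view_id=view_id or "front")
    elif dialect == "hdf5":
        with h5py.File(path, "r") as f:
            groups = list(f.keys())
            if view_id is None:
                if len(groups) != 1:
                    raise FormatError(
                        f"HDF5 file has views {groups}; specify view_id"
                    )
                view_id = groups[0]
            if view_id not in f:
                raise FormatError(f"view '{view_id}' not present in {path.name}")
            g = f[view_id]
            cols = {}
            for kp in sorted(g.keys()):
                for field in TRACK_FIELDS:
                    if field not in g[kp]:
                        raise FormatError(f"missing dataset '{kp}/{field}'")
                    cols[f"{kp}_{field}"] = np.asarray(g[kp][field])
            track = Keypoint2DTrack(
                data=pd.DataFrame(cols),
                fs=float(g.attrs.get("fs", fs)),
                view_id=view_id,
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if keypoints is not None:
        for kp in keypoints:
            for field in TRACK_FIELDS:
                if f"{kp}_{field}" not in track.data.columns:
                    raise FormatError(f"missing keypoint column '{kp}_{field}'")
    return track


# ---------------------------------------------------------------------------
# sensor logs


def parse_sensor_log(path) -> SensorLog:
    """Parse a sensor-log CSV (first column camera frame number, one
    column per data stream)."""
    df = pd.read_csv(path)
    if df.columns[0] != "frame":
        raise FormatError("sensor log must start with a 'frame' column")
    channels = {c: df[c].to_numpy(dtype=int) for c in df.columns[1:]}
    return SensorLog(frame=df["frame"].to_numpy(dtype=int), channels=channels)


def write_sensor_log(log: SensorLog, path) -> None:
    df = pd.DataFrame({"frame": log.frame, **log.channels})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# calibration TOML


def _toml_escape(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_escape(v) for v in value) + "]"
    return '"' + str(value).replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_calibration(cameras: Mapping[str, CameraModel], path) -> None:
    """Write camera models to a TOML calibration file, one ``[views.*]``
    table per view with the 12 projection entries row-major."""
    lines = []
    for name, cam in cameras.items():
        lines.append(f"[views.{name}]")
        lines.append(f"P = {_toml_escape([float(v) for v in cam.P.ravel()])}")
        lines.append(f"mirrored = {_toml_escape(cam.mirrored)}")
        if cam.image_size is not None:
            lines.append(f"image_size = {_toml_escape(list(cam.image_size))}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_calibration(
    path, required_views: Sequence[str] | None = None
) -> dict[str, CameraModel]:
    """Read a TOML calibration file written by :func:`write_calibration`.

    Malformed TOML raises ``tomllib.TOMLDecodeError`` (which carries the
    line/column); a required view missing from the file raises
    :class:`FormatError` naming it.
    """
    with open(path, "rb") as f:
        doc = tomllib.load(f)
    views = doc.get("views", {})
    cams: dict[str, CameraModel] = {}
    for name, tbl in views.items():
        if "P" not in tbl or len(tbl["P"]) != 12:
            raise FormatError(f"view '{name}' must list 12 projection entries")
        cams[name] = CameraModel(
            P=np.asarray(tbl["P"], dtype=float).reshape(3, 4),
            mirrored=bool(tbl.get("mirrored", False)),
            image_size=tuple(tbl["image_size"]) if "image_size" in tbl else None,
        )
    if required_views is not None:
        for name in required_views:
            if name not in cams:
                raise FormatError(f"calibration file is missing view '{name}'")
    return cams


def roundtrip_calibration(
    cameras: Mapping[str, CameraModel], path
) -> dict[str, CameraModel]:
    """Write then re-read a calibration file (projection matrices survive
    up to scale within 1e-9)."""
    write_calibration(cameras, path)
    return read_calibration(path, required_views=list(cameras))


# ---------------------------------------------------------------------------
# scalar tables


def write_scalar_table(table: pd.DataFrame, path, dialect: str = "csv") -> None:
    missing = [c for c in SCALAR_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"scalar table missing columns {missing}")
    out = table[list(SCALAR_COLUMNS)]
    if dialect == "csv":
        out.to_csv(path, index=False)
    elif dialect == "hdf5":
        out.to_hdf(path, key="scalars", mode="w", format="table")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_scalar_table(path, dialect: str = "csv") -> pd.DataFrame:
    if dialect == "csv":
        df = pd.read_csv(path)
    elif dialect == "hdf5":
        df = pd.read_hdf(path, key="scalars")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = [c for c in SCALAR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"scalar table missing columns {missing}")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# trajectory tables (triangulated 3D coordinates)


def write_trajectory_table(trajectories: Mapping[str, Trajectory3D], path) -> None:
    """Write triangulated trajectories as a wide CSV (columns
    ``<kp>_x_mm``/``_y_mm``/``_z_mm``), one row per frame."""
    items = list(trajectories.items())
    if not items:
        raise ValueError("no trajectories to write")
    n = items[0][1].n_frames
    cols: dict[str, np.ndarray] = {"frame": np.arange(n)}
    for name, traj in items:
        if traj.n_frames != n:
            raise StructuralError("trajectories must share the frame index")
        for i, ax in enumerate("xyz"):
            cols[f"{name}_{ax}_mm"] = traj.xyz[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trajectory_table(path, fs: float = 100.0) -> dict[str, Trajectory3D]:
    df = pd.read_csv(path)
    if "frame" not in df.columns:
        raise FormatError("trajectory CSV must have a 'frame' column")
    names = sorted({c[:-5] for c in df.columns if c.endswith("_x_mm")})
    if not names:
        raise FormatError("no '<keypoint>_x_mm' columns found")
    out = {}
    for name in names:
        cols = [f"{name}_{ax}_mm" for ax in "xyz"]
        for c in cols:
            if c not in df.columns:
                raise FormatError(f"missing column '{c}'")
        out[name] = Trajectory3D(df[cols].to_numpy(dtype=float), fs=fs, keypoint=name)
    return out
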