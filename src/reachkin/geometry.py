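"""Pinhole-camera geometry for mirror-based single-camera 3D reconstruction.

A single high-speed camera faces the reaching box; two tilted mirrors
flank it, so one video frame contains a front view and up to two side
views of the paw.  Each mirror view is modeled as a *virtual camera*: the
real camera reflected about the mirror plane.  Reflection flips
handedness, so a virtual camera decomposes as K[R|t] with det(R) = -1
(the ``mirrored`` flag).  Because the reflection lives inside the
projection matrix, standard two-view DLT triangulation applies unchanged.

Provided here:

* :func:`calibrate_dlt` — normalized direct linear transform estimation
  of a 3x4 projection matrix from 3D-2D correspondences;
* :func:`mirror_camera` — construction of the virtual camera for a
  mirror plane given as point + unit normal;
* :func:`triangulate` — per-frame linear (SVD) triangulation across two
  or more views, NaN-tolerant;
* :func:`align_to_reference` — similarity (Umeyama) alignment of a
  triangulated trajectory onto nominal static reference points, fixing
  the origin at the pellet rest position and +x forward.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import linalg

from .exceptions import DegenerateGeometryError, InsufficientDataError
from .trajectory import Trajectory3D

VIEW_NAMES = ("front", "left_mirror", "right_mirror")

#: Nominal coordinates (mm) of the static reference points used to pin the
#: trajectory frame: origin at the pellet rest position, slit plane 7 mm
#: behind it along -x, slit edges 8 mm apart.
DEFAULT_REFERENCE_POINTS: dict[str, tuple[float, float, float]] = {
    "pellet_rest": (0.0, 0.0, 0.0),
    "slit_left": (-7.0, -4.0, 0.0),
    "slit_right": (-7.0, 4.0, 0.0),
}


@dataclasses.dataclass
class CameraModel:
    """Projective pinhole camera: pixels <- homogeneous mm.

    ``mirrored`` marks a virtual (reflected) camera, i.e. det(R) = -1 in
    the K[R|t] decomposition.
    """

    P: np.ndarray
    mirrored: bool = False
    image_size: tuple[int, int] | None = None

    def __post_init__(self):
        self.P = np.array(self.P, dtype=float)
        if self.P.shape != (3, 4):
            raise ValueError("P must be 3x4")
        if np.linalg.matrix_rank(self.P[:, :3]) != 3:
            raise DegenerateGeometryError("P[:, :3] must have rank 3")
        if self.image_size is not None:
            self.image_size = (int(self.image_size[0]), int(self.image_size[1]))

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project (n, 3) world points (mm) to (n, 2) pixel coordinates."""
        X = np.atleast_2d(np.asarray(points, dtype=float))
        Xh = np.hstack([X, np.ones((X.shape[0], 1))])
        x = Xh @ self.P.T
        return x[:, :2] / x[:, 2:3]

    def depths(self, points: np.ndarray) -> np.ndarray:
        """Homogeneous scale of each projected point (sign = cheirality)."""
        X = np.atleast_2d(np.asarray(points, dtype=float))
        Xh = np.hstack([X, np.ones((X.shape[0], 1))])
        return Xh @ self.P[2]

    def decompose(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """RQ-decompose P into (K, R, t) with K upper triangular, positive
        diagonal, K[2, 2] = 1.  det(R) is -1 for mirrored cameras."""
        M = self.P[:, :3]
        K, R = linalg.rq(M)
        S = np.diag(np.where(np.diag(K) < 0, -1.0, 1.0))
        K = K @ S
        R = S @ R
        t = np.linalg.solve(K, self.P[:, 3])
        return K / K[2, 2], R, t


@dataclasses.dataclass
class Correspondences:
    """3D-2D point correspondences for one camera view.

    ``object_points`` are world coordinates in mm (e.g. checkerboard
    corners across several board poses, ordered left-to-right,
    top-to-bottom within a pose); ``image_points`` the matching pixel
    observations.
    """

    object_points: np.ndarray
    image_points: np.ndarray
    view_id: str = "front"

    def __post_init__(self):
        self.object_points = np.asarray(self.object_points, dtype=float)
        self.image_points = np.asarray(self.image_points, dtype=float)
        if self.object_points.ndim != 2 or self.object_points.shape[1] != 3:
            raise ValueError("object_points must be (n, 3)")
        if self.image_points.shape != (self.object_points.shape[0], 2):
            raise ValueError("image_points must be (n, 2) matching object_points")

    def __len__(self) -> int:
        return self.object_points.shape[0]


@dataclasses.dataclass
class CalibrationResult:
    camera: CameraModel
    reprojection_error_px: float
    n_points: int


def _normalize_points(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalization: centroid at origin, mean norm sqrt(dim)."""
    dim = pts.shape[1]
    centroid = pts.mean(axis=0)
    dist = np.linalg.norm(pts - centroid, axis=1).mean()
    if dist == 0:
        raise DegenerateGeometryError("all points coincide")
    s = np.sqrt(dim) / dist
    T = np.eye(dim + 1)
    T[:dim, :dim] *= s
    T[:dim, dim] = -s * centroid
    ph = np.hstack([pts, np.ones((pts.shape[0], 1))]) @ T.T
    return ph, T


def calibrate_dlt(corr: Correspondences) -> CalibrationResult:
    """Estimate a projection matrix by the normalized direct linear transform.

    Requires at least 6 correspondences spanning a genuinely 3D point set
    (a single checkerboard plane is degenerate for DLT; use several board
    poses).  The algebraic least-squares solution is taken from the SVD of
    the stacked DLT system after Hartley normalization of both point sets;
    the sign of P is fixed so that points lie in front of the camera,
    which makes det(R) of the decomposition report handedness (mirrored
    views come out with det(R) = -1).
    """
    X, x = corr.object_points, corr.image_points
    n = len(corr)
    if n < 6:
        raise InsufficientDataError(f"DLT calibration needs >= 6 points, got {n}")
    Xc = X - X.mean(axis=0)
    sv = np.linalg.svd(Xc, compute_uv=False)
    if sv[2] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError(
            "calibration points are (nearly) coplanar; DLT is degenerate — "
            "use checkerboard poses with different orientations"
        )
    Xh, U = _normalize_points(X)
    xh, T = _normalize_points(x)
    A = np.zeros((2 * n, 12))
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -xh[:, 0:1] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -xh[:, 1:2] * Xh
    _, _, Vt = np.linalg.svd(A)
    Pn = Vt[-1].reshape(3, 4)
    P = np.linalg.solve(T, Pn) @ U
    cam = CameraModel(P / np.linalg.norm(P), mirrored=False)
    if np.median(cam.depths(X)) < 0:
        cam = CameraModel(-cam.P, mirrored=False)
    _, R, _ = cam.decompose()
    cam.mirrored = bool(np.linalg.det(R) < 0)
    err = float(np.linalg.norm(cam.project(X) - x, axis=1).mean())
    return CalibrationResult(cam, err, n)


def reflection_matrix(point, normal) -> np.ndarray:
    """Homogeneous 4x4 reflection about the plane through ``point`` with
    unit ``normal``."""
    p = np.asarray(point, dtype=float)
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise DegenerateGeometryError("mirror normal must be nonzero")
    n = n / norm
    d = float(n @ p)
    H = np.eye(4)
    H[:3, :3] -= 2.0 * np.outer(n, n)
    H[:3, 3] = 2.0 * d * n
    return H


def mirror_camera(cam: CameraModel, point, normal) -> CameraModel:
    """Virtual camera seeing the scene through a planar mirror.

    The mirror view observed by ``cam`` equals the direct view of the
    reflected camera ``P @ H``; the ``mirrored`` flag is toggled because
    reflection flips handedness.
    """
    H = reflection_matrix(point, normal)
    return CameraModel(cam.P @ H, mirrored=not cam.mirrored, image_size=cam.image_size)


def triangulate(
    observations: Sequence[np.ndarray],
    cameras: Sequence[CameraModel],
) -> np.ndarray:
    """Linear per-frame triangulation of 2D observations from >= 2 views.

    ``observations[i]`` is an (n, 2) pixel array for ``cameras[i]``; NaN
    marks a missing observation.  Frames seen by fewer than two views
    yield NaN points.  Mirrored cameras need no special casing — the
    reflection is inside their projection matrix.
    """
    if len(observations) != len(cameras) or len(cameras) < 2:
        raise ValueError("need matching observations for at least two cameras")
    obs = [np.atleast_2d(np.asarray(o, dtype=float)) for o in observations]
    n = obs[0].shape[0]
    for o in obs:
        if o.shape != (n, 2):
            raise ValueError("all views must observe the same frame set")
    out = np.full((n, 3), np.nan)
    Ps = [c.P for c in cameras]
    valid_any = False
    for f in range(n):
        rows = []
        for o, P in zip(obs, Ps):
            u, v = o[f]
            if np.isfinite(u) and np.isfinite(v):
                rows.append(u * P[2] - P[0])
                rows.append(v * P[2] - P[1])
        if len(rows) < 4:
            continue
        _, _, Vt = np.linalg.svd(np.asarray(rows))
        Xh = Vt[-1]
        if abs(Xh[3]) < 1e-12:
            continue
        out[f] = Xh[:3] / Xh[3]
        valid_any = True
    if n > 0 and not valid_any:
        warnings.warn("no frame had two valid views; trajectory is empty", stacklevel=2)
    return out


@dataclasses.dataclass
class SimilarityTransform:
    """x -> scale * R @ x + t with R a proper rotation."""

    scale: float
    R: np.ndarray
    t: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        X = np.asarray(points, dtype=float)
        return self.scale * X @ self.R.T + self.t

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.R.T
        s = 1.0 / self.scale
        return SimilarityTransform(s, Rinv, -s * Rinv @ self.t)


def fit_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``src`` onto ``dst``
    (Umeyama's closed form, rotation constrained to det +1)."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must both be (n, 3)")
    if src.shape[0] < 3:
        raise InsufficientDataError("similarity fit needs >= 3 points")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    Xc, Yc = src - mu_s, dst - mu_d
    sv = np.linalg.svd(Xc, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("reference points are collinear")
    cov = Yc.T @ Xc / src.shape[0]
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    var_src = (Xc**2).sum() / src.shape[0]
    scale = float(np.trace(np.diag(S) @ D) / var_src)
    t = mu_d - scale * R @ mu_s
    return SimilarityTransform(scale, R, t)


def align_to_reference(
    traj: Trajectory3D,
    measured: Mapping[str, Sequence[float]],
    nominal: Mapping[str, Sequence[float]] | None = None,
) -> tuple[Trajectory3D, SimilarityTransform]:
    """Map a triangulated trajectory into the nominal box frame.

    ``measured`` holds triangulated coordinates of named static points
    (pellet rest position, slit edges, ...) in the arbitrary calibration
    gauge; ``nominal`` their known box-frame coordinates (defaults to
    :data:`DEFAULT_REFERENCE_POINTS`).  A least-squares similarity
    transform (rotation + translation + isotropic scale) computed from
    the shared names is applied to every frame, making coordinates
    absolute mm relative to the pellet with +x forward and +z up.
    """
    if nominal is None:
        nominal = DEFAULT_REFERENCE_POINTS
    names = [k for k in measured if k in nominal]
    if len(names) < 3:
        raise InsufficientDataError(
            f"need >= 3 shared reference points, got {len(names)} ({names})"
        )
    src = np.asarray([measured[k] for k in names], dtype=float)
    dst = np.asarray([nominal[k] for k in names], dtype=float)
    tf = fit_similarity(src, dst)
    return Trajectory3D(tf.apply(traj.xyz), traj.fs, traj.keypoint), tf
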