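"""Reach outcome classification and clustering.

Every scored reach receives exactly one of six outcome categories, the
standard per-trial vocabulary of single-pellet reaching:

* ``grasped`` — the pellet was picked up and carried to the mouth;
* ``missed`` — the paw never touched the pellet;
* ``flicked`` — the pellet was touched and knocked off the disk;
* ``lost`` — the pellet was picked up but dropped on the way to the mouth;
* ``in_vain`` — the animal reached while no pellet was present;
* ``artifact`` — the recorded trajectory is not an acceptable reach.

In a manual workflow these labels are assigned from video; here a
deterministic rule cascade reproduces them from the paw and pellet
trajectories, and :func:`load_manual_labels` ingests hand-assigned
labels that override the rules when provided.  "Contact" means the
paw-pellet distance drops below the pellet radius scale
(``contact_radius``); "carrying" means contact while the pellet is
displaced at least ``displacement_min`` from its rest position, for at
least ``comove_min_frames`` consecutive frames — gating on displacement
keeps the slow approach phase (paw hovering near a static pellet) from
counting as co-movement.
"""

from __future__ import annotations

import dataclasses
import enum
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture
from sklearn.preprocessing import StandardScaler

from .kinematics import FEATURE_COLUMNS
from .trajectory import ReachSegment, Trajectory3D


class OutcomeLabel(str, enum.Enum):
    GRASPED = "grasped"
    MISSED = "missed"
    FLICKED = "flicked"
    LOST = "lost"
    IN_VAIN = "in_vain"
    ARTIFACT = "artifact"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


LABELS: tuple[OutcomeLabel, ...] = tuple(OutcomeLabel)


@dataclasses.dataclass
class ClassifierParams:
    """Geometry-scaled thresholds of the outcome rule cascade (mm).

    Defaults follow the box geometry: the sugar pellet is ~2 mm in
    diameter (contact radius), and the mouth zone is a 5 mm sphere
    around a point behind the slit.
    """

    contact_radius: float = 2.0
    mouth_point: tuple[float, float, float] = (-10.0, 0.0, 5.0)
    mouth_radius: float = 5.0
    displacement_min: float = 1.0
    min_duration: int = 10
    max_duration: int = 200
    comove_min_frames: int = 3
    #: frames past the segment end over which the pellet's fate is
    #: resolved — detected windows end early in retraction, before a
    #: carried pellet reaches the mouth
    fate_horizon: int = 60


def _longest_true_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def classify_reach(
    seg: ReachSegment,
    paw: Trajectory3D,
    pellet: Trajectory3D,
    params: ClassifierParams | None = None,
    fate_end: int | None = None,
) -> OutcomeLabel:
    """Assign one of the six outcome categories to a reach segment.

    Decision cascade (first match wins):

    a. paw track < 50% finite inside the segment, or segment duration
       outside the acceptable bounds -> ``artifact``;
    b. pellet track all-NaN inside the segment -> ``in_vain``;
    c. minimum paw-pellet distance above ``contact_radius`` inside the
       segment -> ``missed``;
    d. carried (contact + displaced >= ``displacement_min`` for >=
       ``comove_min_frames`` consecutive frames): pellet position where
       carrying *ended* inside the mouth zone -> ``grasped``, outside
       -> ``lost``;
    e. not carried but pellet displaced >= ``displacement_min``
       -> ``flicked``; otherwise the touch moved nothing -> ``missed``.

    Rules (d) and (e) are evaluated over the segment extended to
    ``fate_end`` (default ``seg.end + params.fate_horizon``): an
    automatically detected window closes at the hysteresis crossing,
    before transport to the mouth completes.  Pass the next segment's
    start as ``fate_end`` to keep neighbouring reaches from leaking in
    (:func:`classify_session` does this).
    """
    if params is None:
        params = ClassifierParams()
    if paw.n_frames != pellet.n_frames:
        raise ValueError("paw and pellet trajectories must share frames")
    if seg.end > paw.n_frames:
        raise ValueError("segment exceeds trajectory bounds")
    if fate_end is None:
        fate_end = seg.end + params.fate_horizon
    fate_end = int(np.clip(fate_end, seg.end, paw.n_frames))
    core = slice(seg.start, seg.end)
    ext = slice(seg.start, fate_end)
    paw_c, pel_c = paw.xyz[core], pellet.xyz[core]

    complete = float(np.isfinite(paw_c).all(axis=1).mean())
    duration_ok = params.min_duration <= seg.n_frames <= params.max_duration
    if complete < 0.5 or not duration_ok:
        return OutcomeLabel.ARTIFACT

    pel_finite_c = np.isfinite(pel_c).all(axis=1)
    if not pel_finite_c.any():
        return OutcomeLabel.IN_VAIN

    dist_c = np.linalg.norm(paw_c - pel_c, axis=1)
    if np.nanmin(dist_c) > params.contact_radius:
        return OutcomeLabel.MISSED

    paw_e, pel_e = paw.xyz[ext], pellet.xyz[ext]
    pel_finite = np.isfinite(pel_e).all(axis=1) & np.isfinite(paw_e).all(axis=1)
    pellet_rest = pel_c[pel_finite_c][0]
    dist = np.linalg.norm(paw_e - pel_e, axis=1)
    displacement = np.linalg.norm(pel_e - pellet_rest, axis=1)
    carried = (
        (dist < params.contact_radius)
        & (displacement >= params.displacement_min)
        & pel_finite
    )
    if _longest_true_run(carried) >= params.comove_min_frames:
        last_carried = int(np.flatnonzero(carried)[-1])
        to_mouth = np.linalg.norm(
            pel_e[last_carried] - np.asarray(params.mouth_point)
        )
        return OutcomeLabel.GRASPED if to_mouth <= params.mouth_radius else OutcomeLabel.LOST
    if np.nanmax(displacement[pel_finite], initial=0.0) >= params.displacement_min:
        return OutcomeLabel.FLICKED
    return OutcomeLabel.MISSED


def classify_session(
    segments: Sequence[ReachSegment],
    paw: Trajectory3D,
    pellet: Trajectory3D,
    params: ClassifierParams | None = None,
    manual: Mapping[int, OutcomeLabel] | None = None,
) -> list[OutcomeLabel]:
    """Classify every segment; manual labels (by segment index) override.

    Each segment's fate window is clipped at the next segment's onset so
    a neighbouring reach cannot contaminate the pellet-fate evaluation.
    """
    segments = list(segments)
    labels = []
    for i, seg in enumerate(segments):
        nxt = segments[i + 1].start if i + 1 < len(segments) else paw.n_frames
        horizon = (params or ClassifierParams()).fate_horizon
        labels.append(
            classify_reach(
                seg, paw, pellet, params, fate_end=min(seg.end + horizon, nxt)
            )
        )
    if manual:
        for idx, lab in manual.items():
            if not 0 <= idx < len(labels):
                raise ValueError(f"manual label index {idx} out of range")
            labels[idx] = OutcomeLabel(lab)
    return labels


def load_manual_labels(path) -> dict[int, OutcomeLabel]:
    """Read a manual label CSV with columns (segment_index, label)."""
    df = pd.read_csv(path)
    required = {"segment_index", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manual label file needs columns {sorted(required)}")
    return {int(r.segment_index): OutcomeLabel(r.label) for r in df.itertuples()}


def count_categories(table: pd.DataFrame) -> dict[str, int]:
    """Reach counts over exactly the six categories (zeros included)."""
    counts = {lab.value: 0 for lab in LABELS}
    for v in table["label"]:
        if pd.isna(v) or str(v) == "":
            raise ValueError("scalar table contains unlabeled rows")
        key = str(v)
        if key not in counts:
            raise ValueError(f"unknown outcome label {key!r}")
        counts[key] += 1
    return counts


@dataclasses.dataclass
class ClusterResult:
    labels: np.ndarray  # per-row cluster index; -1 for rows with NaN features
    silhouette: float
    k: int
    method: str


def choose_k(table: pd.DataFrame, seed: int = 0) -> int:
    """Default cluster count: number of non-empty outcome categories when
    labels are present, otherwise the silhouette-maximizing k in [2, 6]."""
    labels = table.get("label")
    if labels is not None:
        nonempty = {str(v) for v in labels if not pd.isna(v) and str(v) != ""}
        if len(nonempty) >= 1:
            return max(len(nonempty), 1)
    X, ok = _feature_matrix(table)
    best_k, best_s = 2, -np.inf
    for k in range(2, min(6, ok.sum() - 1) + 1):
        res = cluster_reaches(table, method="kmeans", k=k, seed=seed)
        if res.silhouette > best_s:
            best_k, best_s = k, res.silhouette
    return best_k


def _feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    ok = np.isfinite(X).all(axis=1)
    return X, ok


def cluster_reaches(
    table: pd.DataFrame,
    method: str = "kmeans",
    k: int | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Cluster reaches on their standardized scalar features.

    Features are internally standardized to zero mean / unit variance, so
    the result is invariant to per-feature rescaling of the input.  Rows
    with non-finite features (e.g. artifacts) receive cluster -1.
    Deterministic given ``seed``.
    """
    X, ok = _feature_matrix(table)
    n = int(ok.sum())
    if k is None:
        k = choose_k(table, seed=seed)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} usable rows")
    out = np.full(len(table), -1, dtype=int)
    if k == 1:
        out[ok] = 0
        return ClusterResult(out, float("nan"), 1, method)
    Z = StandardScaler().fit_transform(X[ok])
    if method == "kmeans":
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(Z)
    elif method == "agglomerative":
        labels = AgglomerativeClustering(n_clusters=k).fit_predict(Z)
    elif method == "gmm":
        labels = GaussianMixture(n_components=k, random_state=seed).fit(Z).predict(Z)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    sil = float(silhouette_score(Z, labels)) if 1 < k < n else float("nan")
    out[ok] = labels
    return ClusterResult(out, sil, k, method)
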