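"""Session- and cohort-level learning metrics for the reach-to-grasp task.

From the four per-session reach counts (failed/successful x left/right)
this module derives:

* total reaches                     total = fr + fl + sr + sl
* percentage of right-paw reaches   pct_right = (fr + sr) / total * 100
* paw dominance — the paw used for *more than* 70% of all reaches
  (strict inequality; the mirrored rule, below 30%, assigns left);
* success rate                      successful / (failed + successful)
* the shaping criterion — at least 20 reaches in a session *and* an
  established paw dominance;
* the learner criterion — success rate at or above the 30% literature
  threshold (boundary inclusive).

``learning_curve`` aggregates a cohort into per-day mean +/- SEM series,
the standard presentation of acquisition over the 7 training days.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd

DOMINANCE_PCT = 70.0
LEARNER_THRESHOLD = 0.30
SHAPING_MIN_REACHES = 20

COUNT_COLUMNS = ("failed_right", "failed_left", "successful_right", "successful_left")


@dataclasses.dataclass(frozen=True)
class SessionCounts:
    """Per-session reach counts by paw and outcome."""

    failed_right: int
    failed_left: int
    successful_right: int
    successful_left: int

    def __post_init__(self):
        for name in COUNT_COLUMNS:
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def successful(self) -> int:
        return self.successful_right + self.successful_left

    @property
    def failed(self) -> int:
        return self.failed_right + self.failed_left

    @property
    def total(self) -> int:
        return self.successful + self.failed

    @property
    def right(self) -> int:
        return self.failed_right + self.successful_right


@dataclasses.dataclass(frozen=True)
class SessionMetrics:
    total_reaches: int
    pct_right: float  # NaN when no reaches
    dominant_paw: str  # "left" | "right" | "none"
    success_rate: float  # fraction; NaN when no reaches
    shaping_pass: bool
    learner: bool
    rates_defined: bool


def compute_metrics(counts: SessionCounts) -> SessionMetrics:
    """Derive session metrics and criterion flags from the four counts.

    With zero total reaches the rates are undefined (NaN, ``rates_defined``
    False) and every criterion flag is False.
    """
    total = counts.total
    if total == 0:
        return SessionMetrics(0, float("nan"), "none", float("nan"), False, False, False)
    pct_right = 100.0 * counts.right / total
    if pct_right > DOMINANCE_PCT:
        dominant = "right"
    elif pct_right < 100.0 - DOMINANCE_PCT:
        dominant = "left"
    else:
        dominant = "none"
    success_rate = counts.successful / total
    shaping = total >= SHAPING_MIN_REACHES and dominant != "none"
    learner = success_rate >= LEARNER_THRESHOLD
    return SessionMetrics(
        total_reaches=total,
        pct_right=pct_right,
        dominant_paw=dominant,
        success_rate=success_rate,
        shaping_pass=shaping,
        learner=learner,
        rates_defined=True,
    )


def learning_curve(values_by_animal: Sequence[Sequence[float]]) -> pd.DataFrame:
    """Per-day mean +/- SEM of a session metric across animals.

    ``values_by_animal`` is an (n_animals, n_days) array-like; NaN marks
    a missing session.  SEM is SD(ddof=1)/sqrt(n) over animals with data
    on that day; a day with a single animal reports SEM 0 with a warning
    (so the curve stays plottable).  Returns a frame with columns
    ``day`` (1-based), ``mean``, ``sem``, ``n``.
    """
    arr = np.asarray(values_by_animal, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("need a non-empty (n_animals, n_days) array")
    n = np.isfinite(arr).sum(axis=0)
    if (n == 0).any():
        raise ValueError("every day needs at least one animal with data")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(n), 0.0)
    if (n == 1).any():
        warnings.warn("SEM reported as 0 on days with a single animal", stacklevel=2)
    return pd.DataFrame(
        {"day": np.arange(1, arr.shape[1] + 1), "mean": mean, "sem": sem, "n": n}
    )


def metrics_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Session metrics for a long-format counts table.

    ``counts`` needs columns ``animal``, ``day`` and the four count
    columns; the result appends the metric and criterion columns row by
    row.
    """
    required = {"animal", "day", *COUNT_COLUMNS}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    rows = []
    for r in counts.itertuples():
        m = compute_metrics(
            SessionCounts(
                failed_right=int(r.failed_right),
                failed_left=int(r.failed_left),
                successful_right=int(r.successful_right),
                successful_left=int(r.successful_left),
            )
        )
        rows.append({"animal": r.animal, "day": r.day, **dataclasses.asdict(m)})
    return pd.DataFrame(rows)
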