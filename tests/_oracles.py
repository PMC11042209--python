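"""Independent oracles used by the test suite.

These deliberately re-derive expected values through a different route
than the library (brute force, dense enumeration, generic optimization)
so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares


def nonlinear_triangulation(observations, cameras) -> np.ndarray:
    """Per-point 3D estimate minimizing the nonlinear reprojection error.

    Generic unconstrained least squares started from the midpoint of the
    scene; independent of the library's linear SVD triangulation.
    """
    obs = [np.atleast_2d(np.asarray(o, dtype=float)) for o in observations]
    n = obs[0].shape[0]
    out = np.full((n, 3), np.nan)
    Ps = [np.asarray(c.P, dtype=float) for c in cameras]

    def residual(X, uvs, mats):
        Xh = np.append(X, 1.0)
        res = []
        for uv, P in zip(uvs, mats):
            x = P @ Xh
            res.extend(x[:2] / x[2] - uv)
        return np.asarray(res)

    for f in range(n):
        uvs, mats = [], []
        for o, P in zip(obs, Ps):
            if np.isfinite(o[f]).all():
                uvs.append(o[f])
                mats.append(P)
        if len(uvs) < 2:
            continue
        sol = least_squares(residual, x0=np.zeros(3), args=(uvs, mats), method="lm")
        out[f] = sol.x
    return out


def min_jerk_peak_speed_ratio(n_grid: int = 200001) -> float:
    """Peak of the minimum-jerk speed profile in units of D/T, found by
    dense numeric maximization of the closed-form derivative."""
    tau = np.linspace(0.0, 1.0, n_grid)
    v = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    return float(v.max())


def session_rules_oracle(fr: int, fl: int, sr: int, sl: int) -> dict:
    """Direct transcription of the session-metric rules.

    total reaches = failed right + failed left + successful right +
    successful left; percentage of right reaches = (failed right +
    successful right) / total * 100; the dominant paw is the paw used for
    more than 70% of all reaches; success rate = successful / (failed +
    successful); shaping requires at least 20 reaches and a dominant paw;
    a learner reaches the 30% success threshold.
    """
    total = fr + fl + sr + sl
    if total == 0:
        return {
            "total": 0,
            "pct_right": None,
            "dominant": "none",
            "success_rate": None,
            "shaping": False,
            "learner": False,
        }
    pct_right = (fr + sr) / total * 100.0
    pct_left = (fl + sl) / total * 100.0
    if pct_right > 70.0:
        dominant = "right"
    elif pct_left > 70.0:
        dominant = "left"
    else:
        dominant = "none"
    success = (sr + sl) / total
    return {
        "total": total,
        "pct_right": pct_right,
        "dominant": dominant,
        "success_rate": success,
        "shaping": total >= 20 and dominant != "none",
        "learner": success >= 0.30,
    }


def threshold_crossing_segments(x: np.ndarray, thr: float) -> list[tuple[int, int]]:
    """Brute-force scan of all maximal runs with x >= thr (NaN breaks a
    run); used to cross-check hysteresis segmentation bounds."""
    runs = []
    start = None
    for i, v in enumerate(x):
        above = np.isfinite(v) and v >= thr
        if above and start is None:
            start = i
        elif not above and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(x)))
    return runs
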