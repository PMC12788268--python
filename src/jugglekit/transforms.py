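"""Day-level performance metric and monotone + robust-z preprocessing.

Perf is the mean successful-catch count over the ten best trials of a
participant-day.  The three skill indices are brought onto a common scale
before modeling: Prediction is logit-transformed (with clipping at
eps = 1e-4 to handle the 0/1 boundary), Accuracy is negative-log
transformed so that larger is better, Sequencing is used as-is; each is
then standardized with a robust z-score based on the median and the
median absolute deviation (MAD), ``z = (x - median) / (1.4826 * MAD)``,
where 1.4826 makes the MAD a consistent estimator of the Gaussian SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LOGIT_EPS",
    "MAD_CONSISTENCY",
    "RobustScale",
    "perf_metric",
    "logit_transform",
    "neglog_transform",
    "robust_z",
    "standardize_indices",
    "association_diagnostics",
]

LOGIT_EPS = 1e-4
MAD_CONSISTENCY = 1.4826


def perf_metric(trial_catch_counts) -> float:
    """Mean successful-catch count over the ten best trials of a day.

    Trials are pooled over the day's real-world sessions; when fewer than
    ten trials exist, the mean of all of them is used.  Empty input yields
    NaN (missing day).
    """
    counts = np.asarray(list(trial_catch_counts), dtype=float)
    if counts.size == 0:
        return np.nan
    top = np.sort(counts)[-10:]
    return float(top.mean())


def logit_transform(p) -> np.ndarray | float:
    """Logit of a Prediction value, clipped to [eps, 1 - eps], eps = 1e-4."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("Prediction values must lie in [0, 1]")
    q = np.clip(p, LOGIT_EPS, 1.0 - LOGIT_EPS)
    out = np.log(q / (1.0 - q))
    return float(out) if out.ndim == 0 else out


def neglog_transform(a) -> np.ndarray | float:
    """Negative log of an Accuracy volume; larger output = better accuracy."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("Accuracy values must be positive")
    out = -np.log(a)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RobustScale:
    """Provenance of a robust z-transform (invertible)."""

    median: float
    mad: float
    scale: float  # 1.4826 * MAD, or SD fallback
    degenerate: bool  # True when MAD = 0 and the SD fallback was used


def robust_z(x, return_scale: bool = False):
    """Robust z-score: (x - median) / (1.4826 * MAD).

    With MAD = 0 (more than half the values tied) the scale degenerates;
    the sample SD is substituted and the result flagged via
    :class:`RobustScale.degenerate`.  Raises when no positive scale exists.
    """
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise ValueError("need at least two finite values")
    med = float(np.median(finite))
    mad = float(np.median(np.abs(finite - med)))
    degenerate = mad == 0.0
    scale = MAD_CONSISTENCY * mad if not degenerate else float(finite.std(ddof=1))
    if scale == 0.0:
        raise ValueError("degenerate scale: values are constant")
    z = (x - med) / scale
    if return_scale:
        return z, RobustScale(med, mad, scale, degenerate)
    return z


def standardize_indices(day_indices: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the monotone transforms and robust z-scores to a day-level table.

    Expects columns ``P``, ``A``, ``S``; adds ``P_t``, ``A_t``, ``S_t`` and
    ``Z_P``, ``Z_A``, ``Z_S``.  Standardization is over the pooled table
    (all participants, days and groups), matching the pooled modeling;
    missing values propagate.  Returns the augmented table and a provenance
    dict of medians/MADs per index.
    """
    out = day_indices.copy()
    out["P_t"] = logit_transform(out["P"].to_numpy())
    out["A_t"] = np.where(
        out["A"].notna(), neglog_transform(out["A"].fillna(1.0).to_numpy()), np.nan
    )
    out["S_t"] = out["S"]
    provenance: dict = {"eps": LOGIT_EPS, "mad_constant": MAD_CONSISTENCY}
    for raw, z in (("P_t", "Z_P"), ("A_t", "Z_A"), ("S_t", "Z_S")):
        zvals, sc = robust_z(out[raw].to_numpy(), return_scale=True)
        out[z] = zvals
        provenance[z] = {
            "median": sc.median,
            "mad": sc.mad,
            "scale": sc.scale,
            "degenerate": sc.degenerate,
        }
    return out, provenance


def association_diagnostics(z_table: pd.DataFrame, predictors=("Z_P", "Z_A", "Z_S")) -> dict:
    """Pairwise Pearson correlations and variance inflation factors.

    VIF_j = 1 / (1 - R^2_j) from an OLS regression of predictor j on the
    others (with intercept).  Constant columns make both undefined and are
    flagged with infinite VIF.
    """
    cols = list(predictors)
    X = z_table[cols].dropna().to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least three complete rows")
    result: dict = {"correlations": {}, "vif": {}}
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            xi, xj = X[:, i], X[:, j]
            if xi.std() == 0 or xj.std() == 0:
                result["correlations"][(cols[i], cols[j])] = (np.nan, np.nan)
                continue
            r, p = stats.pearsonr(xi, xj)
            result["correlations"][(cols[i], cols[j])] = (float(r), float(p))
    for j, name in enumerate(cols):
        others = np.delete(X, j, axis=1)
        y = X[:, j]
        if y.std() == 0:
            result["vif"][name] = np.inf
            continue
        design = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sst = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst
        result["vif"][name] = np.inf if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return result
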