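"""Prediction and Accuracy indices from two-ball visual-occlusion trials.

Prediction (P) is the fraction of valid occlusion trials in which BOTH
hands complete the second catch.  Accuracy (A) is the geometric mean of
95% probability-ellipsoid volumes fitted to hand-centred second-catch
point clouds, per hand and per block; smaller A means tighter clustering.
The 95% ellipsoid is the Gaussian coverage ellipsoid of the sample
covariance, scaled by the chi-square(3 df) quantile:

    V = (4/3) * pi * c^(3/2) * sqrt(det(Sigma)),   c = chi2.ppf(0.95, 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from . import sequencing
from .tracking import BallTrack

__all__ = [
    "OcclusionTrial",
    "EllipsoidFit",
    "DayOcclusionIndices",
    "schedule_shutter",
    "prediction_index",
    "hand_centered",
    "fit_ellipsoid",
    "accuracy_index",
    "day_occlusion_indices",
]

CONDITION_NOMINAL_COVERAGE = 0.95
COND_FLOOR = 1e-6  # min/max covariance eigenvalue ratio below which the fit is unstable


@dataclass
class OcclusionTrial:
    """One two-ball occlusion throw--catch attempt."""

    participant: int
    day: int
    block: int
    condition: str  # "apex_locked" | "none" | "random"
    success: dict  # hand -> bool, second-catch outcome
    catch_pos: dict = field(default_factory=dict)  # hand -> 3-vector or None
    wrist_pos: dict = field(default_factory=dict)  # hand -> 3-vector
    shutter_intervals: list = field(default_factory=list)  # [(t_close, t_open)]
    valid: bool = True
    invalid_reason: str = ""

    @property
    def both_success(self) -> bool:
        return bool(self.success.get("L")) and bool(self.success.get("R"))


@dataclass
class EllipsoidFit:
    center: np.ndarray
    cov: np.ndarray
    volume: float
    n_points: int
    stable: bool


@dataclass
class DayOcclusionIndices:
    participant: int
    day: int
    n_succ: int
    n_valid: int
    P: float
    volumes: dict  # (hand, block) -> volume of stable fits
    A: float


def schedule_shutter(
    ball_track: BallTrack,
    condition: str,
    shutter_duration: float = 0.5,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """Shutter-closure intervals for one trial.

    ``apex_locked``: one interval starting at the ball's flight apex;
    ``none``: no closure; ``random``: one interval of the same duration
    with onset drawn uniformly over the flight.  Raises ``ValueError``
    when an apex is required but none is detectable.
    """
    if condition == "none":
        return []
    if condition == "apex_locked":
        apexes = sequencing.detect_apexes(ball_track.t, ball_track.vertical)
        if len(apexes) == 0:
            raise ValueError("no apex detected; trial invalid")
        t0 = float(apexes[0])
    elif condition == "random":
        rng = np.random.default_rng(0) if rng is None else rng
        lo, hi = float(ball_track.t[0]), float(ball_track.t[-1])
        t0 = float(rng.uniform(lo, hi))
    else:
        raise ValueError(f"unknown occlusion condition {condition!r}")
    return [(t0, t0 + shutter_duration)]


def prediction_index(trials: list[OcclusionTrial]) -> tuple[float, int, int]:
    """Prediction index P = N_succ / N_valid over a participant-day.

    A trial counts as a success only when both hands complete the second
    catch; invalid trials are excluded from both counts.  Returns
    ``(P, n_succ, n_valid)``; P is NaN when no trial is valid.
    """
    valid = [tr for tr in trials if tr.valid]
    n_valid = len(valid)
    n_succ = sum(tr.both_success for tr in valid)
    if n_valid == 0:
        return np.nan, 0, 0
    return n_succ / n_valid, n_succ, n_valid


def hand_centered(catch_pos: np.ndarray, wrist_pos: np.ndarray) -> np.ndarray:
    """Catch position expressed in the wrist-centred frame (translation only)."""
    catch_pos = np.asarray(catch_pos, dtype=float)
    wrist_pos = np.asarray(wrist_pos, dtype=float)
    if not (np.isfinite(catch_pos).all() and np.isfinite(wrist_pos).all()):
        raise ValueError("positions must be finite")
    return catch_pos - wrist_pos


def fit_ellipsoid(points: np.ndarray, coverage: float = 0.95) -> EllipsoidFit:
    """Fit the Gaussian ``coverage`` probability ellipsoid to a 3-D cloud.

    Uses the sample covariance (n-1 normalisation).  The fit is flagged
    unstable when fewer than 4 points are given or the covariance is nearly
    singular (eigenvalue ratio below ``COND_FLOOR``); unstable volumes must
    not enter the Accuracy geometric mean.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    n = len(points)
    center = points.mean(axis=0)
    if n < 4:
        return EllipsoidFit(center, np.full((3, 3), np.nan), np.nan, n, stable=False)
    cov = np.cov(points, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(cov)
    stable = eig[0] > 0 and eig[0] / eig[-1] > COND_FLOOR
    c = chi2.ppf(coverage, df=3)
    det = float(np.linalg.det(cov))
    volume = (4.0 / 3.0) * np.pi * c**1.5 * np.sqrt(det) if det > 0 else np.nan
    return EllipsoidFit(center, cov, volume, n, stable=stable and np.isfinite(volume))


def accuracy_index(volumes: dict) -> float:
    """Accuracy index A: geometric mean of stable ellipsoid volumes.

    ``volumes`` maps ``(hand, block)`` to a volume.  With both hands stable
    in every block the exponent is ``1 / (2 * n_blocks)``; when unstable
    blocks have been dropped the mean is taken over the remaining volumes,
    which reduces to the same expression for complete data.  Returns NaN
    when either hand has no stable block.
    """
    by_hand: dict[str, list[float]] = {"L": [], "R": []}
    for (hand, _block), v in volumes.items():
        if np.isfinite(v) and v > 0:
            by_hand[hand].append(v)
    if not by_hand["L"] or not by_hand["R"]:
        return np.nan
    vols = by_hand["L"] + by_hand["R"]
    return float(np.exp(np.mean(np.log(vols))))


def day_occlusion_indices(
    trials: list[OcclusionTrial], participant: int = 0, day: int = 0
) -> DayOcclusionIndices:
    """Compute P and A for one participant-day from its occlusion trials."""
    P, n_succ, n_valid = prediction_index(trials)
    volumes: dict = {}
    for hand in ("L", "R"):
        blocks = sorted({tr.block for tr in trials})
        for b in blocks:
            pts = [
                hand_centered(tr.catch_pos[hand], tr.wrist_pos[hand])
                for tr in trials
                if tr.valid and tr.block == b and tr.catch_pos.get(hand) is not None
            ]
            if not pts:
                continue
            fit = fit_ellipsoid(np.stack(pts))
            if fit.stable:
                volumes[(hand, b)] = fit.volume
    A = accuracy_index(volumes)
    return DayOcclusionIndices(participant, day, n_succ, n_valid, P, volumes, A)
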