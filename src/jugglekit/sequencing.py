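"""Sequencing index: instantaneous ball phases and 120-degree spacing scores.

The Sequencing score of a window quantifies how closely the three balls of
a cascade maintain the ideal 120-degree phase offsets.  Phases come from
the analytic signal (Hilbert transform) of the smoothed, mean-subtracted
vertical position of each ball; windows span three consecutive apexes from
three distinct balls; the window score is

    S_w = mean_k [ 1 - (d12 + d13 + d23) / (3 * 180deg) ],

where ``d_ij`` is the circular distance (folded to [0deg, 180deg]) between
the pairwise phase difference and the ideal 120-degree offset.  Because no
ball ordering is privileged, ``d_ij`` is measured to the nearest of +120
and -120 degrees, which makes the score invariant to ball relabeling and
to a common phase rotation.

Day-level S is the arithmetic mean of all valid window scores pooled over
a participant-day; days with too few windows are excluded by a
log-distribution rule (three log-SDs below the log-mean window count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, hilbert

from .tracking import BallTrack

__all__ = [
    "PhaseSeries",
    "SequencingWindow",
    "DaySequencing",
    "smooth_center",
    "instantaneous_phase",
    "detect_apexes",
    "make_windows",
    "window_score",
    "score_trial",
    "day_sequencing",
    "exclude_low_window_days",
]

IDEAL_OFFSET_DEG = 120.0


@dataclass
class PhaseSeries:
    """Per-ball instantaneous phases on a common time grid."""

    t: np.ndarray  # (n,)
    phi: np.ndarray  # (n_balls, n), radians in (-pi, pi]
    valid: np.ndarray  # (n_balls, n) bool, phase usable
    ball_ids: tuple


@dataclass
class SequencingWindow:
    w_start: float
    w_end: float
    ball_ids: tuple  # the three distinct balls whose apexes bound the window
    K: int = 0
    S_w: float = np.nan


@dataclass
class DaySequencing:
    participant: int
    day: int
    n_windows: int
    S: float
    excluded: bool = False
    reason: str = ""


def smooth_center(y: np.ndarray, fs: float, cutoff: float = 2.0) -> np.ndarray:
    """Zero-phase low-pass filter (4th-order Butterworth, forward-backward)
    and mean-subtract a vertical position series.  Requires >= 1 s of data."""
    y = np.asarray(y, dtype=float)
    if len(y) < fs:
        raise ValueError("need at least 1 s of samples to smooth")
    if not 0 < cutoff < fs / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    b, a = butter(4, cutoff, btype="low", fs=fs)
    y_s = filtfilt(b, a, y)
    return y_s - y_s.mean()


def instantaneous_phase(y_tilde: np.ndarray) -> np.ndarray:
    """Phase of the analytic signal, radians wrapped to (-pi, pi].

    The input must be zero-mean and band-limited for the phase to be
    meaningful; an all-zero series has no defined phase and is rejected.
    """
    y_tilde = np.asarray(y_tilde, dtype=float)
    if np.allclose(y_tilde, 0.0):
        raise ValueError("phase undefined for an all-zero series")
    return np.angle(hilbert(y_tilde))


def detect_apexes(
    t: np.ndarray, y: np.ndarray, refractory: float = 0.0, min_height: float | None = None
) -> np.ndarray:
    """Times of flight apexes: downward zero-crossings of vertical velocity
    with negative acceleration, at least ``refractory`` seconds apart.

    ``min_height`` (same units as ``y``) discards low-amplitude apexes, e.g.
    filter ripples around a resting ball; on a mean-subtracted series a
    floor of 0 keeps only above-average peaks, which flight apexes are.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 3:
        return np.empty(0)
    v = np.gradient(y, t)
    a = np.gradient(v, t)
    idx = np.nonzero((v[:-1] > 0) & (v[1:] <= 0))[0]
    idx = idx[a[idx] < 0]
    if min_height is not None:
        idx = idx[y[idx] >= min_height]
    apexes = []
    for i in idx:
        # linear interpolation of the zero crossing between samples
        denom = v[i] - v[i + 1]
        frac = v[i] / denom if denom > 0 else 0.0
        t_apex = t[i] + frac * (t[i + 1] - t[i])
        if apexes and t_apex - apexes[-1] < refractory:
            continue
        apexes.append(t_apex)
    return np.asarray(apexes)


def make_windows(apexes: list[tuple[float, int]]) -> list[SequencingWindow]:
    """Sliding windows over a merged apex stream.

    ``apexes`` is a time-sorted list of ``(time, ball_id)``.  Every run of
    three consecutive apexes with pairwise-distinct ball labels yields one
    window spanning [first apex, third apex]; windows overlap by sliding
    one apex at a time.
    """
    apexes = sorted(apexes)
    windows = []
    for i in range(len(apexes) - 2):
        labels = tuple(b for _, b in apexes[i : i + 3])
        if len(set(labels)) == 3:
            windows.append(
                SequencingWindow(w_start=apexes[i][0], w_end=apexes[i + 2][0], ball_ids=labels)
            )
    return windows


def _circdist_deg(a: np.ndarray, b: float) -> np.ndarray:
    """Circular distance |a - b| mod 360, folded to [0, 180] degrees."""
    d = np.mod(a - b + 180.0, 360.0) - 180.0
    return np.abs(d)


def pairwise_deviation_deg(phi_i: np.ndarray, phi_j: np.ndarray) -> np.ndarray:
    """Deviation of the phase difference phi_j - phi_i (degrees) from the
    nearest ideal offset (+120 or -120 degrees), folded to [0, 180]."""
    diff = np.degrees(phi_j) - np.degrees(phi_i)
    return np.minimum(
        _circdist_deg(diff, IDEAL_OFFSET_DEG), _circdist_deg(diff, -IDEAL_OFFSET_DEG)
    )


def window_score(phases: PhaseSeries, window: SequencingWindow) -> SequencingWindow:
    """Score one window: mean over usable samples of 1 - sum(d_ij)/540deg.

    Usable samples are those inside [w_start, w_end] where all three phases
    are valid.  A window with no usable sample is returned with K = 0 and
    NaN score, to be dropped by the caller.
    """
    m = (phases.t >= window.w_start) & (phases.t <= window.w_end)
    m &= phases.valid.all(axis=0)
    K = int(m.sum())
    if K == 0:
        window.K, window.S_w = 0, np.nan
        return window
    phi = phases.phi[:, m]
    d12 = pairwise_deviation_deg(phi[0], phi[1])
    d13 = pairwise_deviation_deg(phi[0], phi[2])
    d23 = pairwise_deviation_deg(phi[1], phi[2])
    s = 1.0 - (d12 + d13 + d23) / (3.0 * 180.0)
    window.K, window.S_w = K, float(np.mean(s))
    return window


def compute_phases(
    tracks: list[BallTrack],
    fs: float,
    cutoff: float = 2.0,
    edge_exclude_cycles: float = 1.0,
    cycle_period: float | None = None,
) -> PhaseSeries:
    """Smoothed-signal Hilbert phases for three tracks on their shared grid.

    The first and last ``edge_exclude_cycles`` cycles are marked unusable to
    avoid Hilbert edge effects; the cycle length is taken from the median
    apex spacing unless given.
    """
    if len(tracks) != 3:
        raise ValueError("Sequencing is defined for exactly three balls")
    t = tracks[0].t
    phi = np.empty((3, len(t)))
    valid = np.zeros((3, len(t)), dtype=bool)
    for k, tr in enumerate(tracks):
        if not np.array_equal(tr.t, t):
            raise ValueError("tracks must share a common time grid")
        y = smooth_center(tr.vertical, fs, cutoff)
        phi[k] = instantaneous_phase(y)
        period = cycle_period
        if period is None:
            apx = detect_apexes(t, y)
            period = float(np.median(np.diff(apx))) if len(apx) > 1 else (t[-1] - t[0])
        edge = edge_exclude_cycles * period
        valid[k] = (t >= t[0] + edge) & (t <= t[-1] - edge)
    return PhaseSeries(t=t, phi=phi, valid=valid, ball_ids=tuple(tr.ball_id for tr in tracks))


def score_trial(
    tracks: list[BallTrack],
    fs: float,
    cutoff: float = 2.0,
    edge_exclude_cycles: float = 1.0,
) -> list[SequencingWindow]:
    """Full per-trial Sequencing pipeline: phases, apexes, windows, scores."""
    phases = compute_phases(tracks, fs, cutoff, edge_exclude_cycles)
    apexes: list[tuple[float, int]] = []
    refractory = 0.0
    smoothed = {}
    for tr in tracks:
        y = smooth_center(tr.vertical, fs, cutoff)
        smoothed[tr.ball_id] = y
        # flight apexes sit near the top of the oscillation; a floor of half
        # an SD rejects low-amplitude ripples (e.g. around a resting ball)
        floor = 0.5 * float(np.std(y))
        apx = detect_apexes(tr.t, y, min_height=floor)
        if len(apx) > 1:
            refractory = max(refractory, 0.25 * float(np.median(np.diff(apx))))
    for tr in tracks:
        floor = 0.5 * float(np.std(smoothed[tr.ball_id]))
        for t_a in detect_apexes(
            tr.t, smoothed[tr.ball_id], refractory=refractory, min_height=floor
        ):
            apexes.append((float(t_a), tr.ball_id))
    windows = make_windows(apexes)
    scored = [window_score(phases, w) for w in windows]
    return [w for w in scored if w.K > 0]


def day_sequencing(
    windows: list[SequencingWindow], participant: int = 0, day: int = 0
) -> DaySequencing:
    """Day-level S: arithmetic mean of all valid pooled window scores."""
    scores = [w.S_w for w in windows if w.K > 0 and np.isfinite(w.S_w)]
    if not scores:
        return DaySequencing(participant, day, 0, np.nan, excluded=True, reason="no valid windows")
    return DaySequencing(participant, day, len(scores), float(np.mean(scores)))


def exclude_low_window_days(counts: np.ndarray) -> tuple[np.ndarray, float]:
    """Exclusion mask for participant-days with too few Sequencing windows.

    The threshold is three log-scale SDs below the log-mean of the positive
    window counts, ``exp(mean(log N) - 3 sd(log N))``; days with ``N`` below
    it, and all zero-window days, are excluded.  Returns (mask, threshold)
    with ``mask[i]`` True when day ``i`` is excluded.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("window counts must be non-negative")
    pos = counts[counts >= 1]
    if len(pos) == 0:
        return np.ones(len(counts), dtype=bool), np.nan
    logs = np.log(pos)
    threshold = float(np.exp(logs.mean() - 3.0 * logs.std(ddof=0)))
    return (counts == 0) | (counts < threshold), threshold
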