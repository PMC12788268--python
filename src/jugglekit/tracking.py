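"""Ball-trajectory reconstruction from frame-wise detections.

Turns unordered per-frame candidate lists into continuous per-ball tracks,
labels throw/catch events from ball--hand proximity, and trims continuous
detection streams into juggling-trial segments.

Coordinate convention
---------------------
All metric positions are in metres and seconds with the *last* axis
up-positive vertical: 2-D positions are ``(lateral, vertical)`` and 3-D
positions ``(lateral, frontback, vertical)``.  Pixel-frame detections (y
down-positive) must be converted with :func:`ingest_pixel_frames` before
tracking, so a single sign convention holds everywhere downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DetectionFrame",
    "BallTrack",
    "Event",
    "TrialSegment",
    "PixelCalibration",
    "TrackingDegradedWarning",
    "ingest_pixel_frames",
    "trim_trials",
    "track_balls",
    "label_events",
]


class TrackingDegradedWarning(UserWarning):
    """Raised as a warning when retained tracks cover too few frames."""


@dataclass(frozen=True)
class PixelCalibration:
    """Affine map between metric (up-positive) and pixel (down-positive) frames."""

    px_per_m: float
    frame_height: float
    x_offset_px: float = 0.0

    def to_pixels(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        out = pos * self.px_per_m
        out[..., 0] += self.x_offset_px
        out[..., -1] = self.frame_height - out[..., -1]
        return out

    def to_metric(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        out = pos.copy()
        out[..., -1] = self.frame_height - out[..., -1]
        out[..., 0] -= self.x_offset_px
        return out / self.px_per_m


@dataclass
class DetectionFrame:
    """Unordered ball candidates and hand positions for one video frame."""

    t: float
    ball_candidates: np.ndarray  # (k, d) array, possibly empty
    hand_positions: dict[str, np.ndarray | None] = field(default_factory=dict)
    calibration: PixelCalibration | None = None  # set iff positions are in pixels

    def __post_init__(self) -> None:
        self.ball_candidates = np.atleast_2d(np.asarray(self.ball_candidates, dtype=float))
        if self.ball_candidates.size == 0:
            self.ball_candidates = self.ball_candidates.reshape(0, 2)
        if not np.isfinite(self.ball_candidates).all():
            raise ValueError("non-finite ball candidate positions")


@dataclass(frozen=True)
class Event:
    kind: str  # "throw" | "catch"
    t: float
    hand: str  # "L" | "R"


@dataclass
class BallTrack:
    """A single ball's trajectory with its throw/catch events."""

    ball_id: int
    t: np.ndarray
    pos: np.ndarray  # (n, d), last axis vertical up-positive
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.atleast_2d(np.asarray(self.pos, dtype=float))
        if self.t.ndim != 1 or len(self.t) != len(self.pos):
            raise ValueError("t and pos length mismatch")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def vertical(self) -> np.ndarray:
        return self.pos[:, -1]

    def throws(self) -> list[Event]:
        return [e for e in self.events if e.kind == "throw"]

    def catches(self) -> list[Event]:
        return [e for e in self.events if e.kind == "catch"]


@dataclass
class TrialSegment:
    start_t: float
    end_t: float
    n_catches: int = 0
    valid: bool = True

    def __post_init__(self) -> None:
        if not self.end_t > self.start_t:
            raise ValueError("end_t must exceed start_t")


def ingest_pixel_frames(frames: list[DetectionFrame]) -> list[DetectionFrame]:
    """Convert pixel-frame detections (y down) to metric up-positive frames."""
    out = []
    for f in frames:
        if f.calibration is None:
            out.append(f)
            continue
        cal = f.calibration
        cands = cal.to_metric(f.ball_candidates) if len(f.ball_candidates) else f.ball_candidates
        hands = {
            h: (None if p is None else cal.to_metric(np.asarray(p, dtype=float)))
            for h, p in f.hand_positions.items()
        }
        out.append(DetectionFrame(t=f.t, ball_candidates=cands, hand_positions=hands))
    return out


# ---------------------------------------------------------------------------
# Trial trimming
# ---------------------------------------------------------------------------

def trim_trials(
    frames: list[DetectionFrame],
    shoulder_line: float,
    knee_line: float,
    hold_out: float = 1.0,
) -> list[TrialSegment]:
    """Segment a continuous detection stream into juggling trials.

    A trial opens at the first frame with at least two candidates above the
    knee line, is confirmed once any candidate later crosses the shoulder
    line, and closes when fewer than two candidates stay above the knee line
    for ``hold_out`` seconds.  Unconfirmed openings (no shoulder crossing)
    are discarded.
    """
    if shoulder_line <= knee_line:
        raise ValueError("shoulder_line must be above knee_line")
    segments: list[TrialSegment] = []
    in_trial = False
    confirmed = False
    start_t = 0.0
    lull_start: float | None = None
    last_active_t: float | None = None

    for f in frames:
        heights = f.ball_candidates[:, -1] if len(f.ball_candidates) else np.empty(0)
        n_above_knee = int(np.sum(heights > knee_line))
        any_above_shoulder = bool(np.any(heights > shoulder_line))
        if not in_trial:
            if n_above_knee >= 2:
                in_trial, confirmed = True, any_above_shoulder
                start_t = f.t
                last_active_t = f.t
                lull_start = None
        else:
            confirmed = confirmed or any_above_shoulder
            if n_above_knee >= 2:
                last_active_t = f.t
                lull_start = None
            else:
                if lull_start is None:
                    lull_start = f.t
                if f.t - lull_start >= hold_out:
                    if confirmed and last_active_t is not None and last_active_t > start_t:
                        segments.append(TrialSegment(start_t, last_active_t))
                    in_trial = False
    if in_trial and confirmed and last_active_t is not None and last_active_t > start_t:
        segments.append(TrialSegment(start_t, last_active_t))
    return segments


# ---------------------------------------------------------------------------
# Multi-ball tracking
# ---------------------------------------------------------------------------

class _Track:
    __slots__ = ("t", "pos", "vel", "last_t", "missed")

    def __init__(self, t: float, p: np.ndarray) -> None:
        self.t = [t]
        self.pos = [p]
        self.vel = np.zeros_like(p)
        self.last_t = t
        self.missed = 0

    def predict(self, t: float) -> np.ndarray:
        return self.pos[-1] + self.vel * (t - self.last_t)

    def update(self, t: float, p: np.ndarray) -> None:
        dt = t - self.last_t
        if dt > 0:
            self.vel = (p - self.pos[-1]) / dt
        self.t.append(t)
        self.pos.append(p)
        self.last_t = t
        self.missed = 0


def track_balls(
    frames: list[DetectionFrame],
    max_jump: float = 0.15,
    max_gap: int = 5,
    n_balls: int = 3,
    min_coverage: float = 0.8,
) -> list[BallTrack]:
    """Link per-frame candidates into ``n_balls`` continuous tracks.

    Per frame, candidates are assigned to active tracks by repeatedly taking
    the globally cheapest (track, candidate) pair whose distance to the
    track's constant-velocity prediction is within ``max_jump`` metres per
    elapsed frame.  Unmatched tracks coast up to ``max_gap`` frames and then
    close; unmatched candidates seed new tracks.  The ``n_balls`` longest
    tracks are returned; a :class:`TrackingDegradedWarning` is emitted when
    their mean frame coverage falls below ``min_coverage``.
    """
    if max_jump <= 0 or max_gap < 0:
        raise ValueError("max_jump must be positive and max_gap non-negative")
    times = np.array([f.t for f in frames], dtype=float)
    if len(times) > 1 and np.any(np.diff(times) < 0):
        raise ValueError("frames must be time-ordered")
    dt_frame = float(np.median(np.diff(times))) if len(times) > 1 else 1.0

    active: list[_Track] = []
    closed: list[_Track] = []
    for f in frames:
        cands = f.ball_candidates
        n_c = len(cands)
        matched_tracks: set[int] = set()
        matched_cands: set[int] = set()
        if active and n_c:
            preds = np.stack([tr.predict(f.t) for tr in active])
            dists = np.linalg.norm(preds[:, None, :] - cands[None, :, :], axis=-1)
            gates = np.array(
                [max_jump * max(1.0, (f.t - tr.last_t) / dt_frame) for tr in active]
            )
            order = np.argsort(dists, axis=None)
            for flat in order:
                i, j = divmod(int(flat), n_c)
                if i in matched_tracks or j in matched_cands:
                    continue
                if dists[i, j] > gates[i]:
                    continue
                active[i].update(f.t, cands[j])
                matched_tracks.add(i)
                matched_cands.add(j)
        still: list[_Track] = []
        for i, tr in enumerate(active):
            if i in matched_tracks:
                still.append(tr)
            else:
                tr.missed += 1
                (closed if tr.missed > max_gap else still).append(tr)
        active = [tr for tr in still if tr.missed <= max_gap]
        for j in range(n_c):
            if j not in matched_cands:
                active.append(_Track(f.t, cands[j]))
    closed.extend(active)

    closed.sort(key=lambda tr: len(tr.t), reverse=True)
    kept = closed[:n_balls]
    tracks = [
        BallTrack(ball_id=i + 1, t=np.array(tr.t), pos=np.stack(tr.pos))
        for i, tr in enumerate(kept)
    ]
    if len(times):
        coverage = np.mean([len(tr.t) / len(times) for tr in kept]) if kept else 0.0
        if len(kept) < n_balls or coverage < min_coverage:
            warnings.warn(
                f"degraded tracking: {len(kept)}/{n_balls} tracks, "
                f"mean coverage {coverage:.2f}",
                TrackingDegradedWarning,
                stacklevel=2,
            )
    return tracks


# ---------------------------------------------------------------------------
# Event labeling
# ---------------------------------------------------------------------------

def _resample(t_src: np.ndarray, pos_src: np.ndarray, t_dst: np.ndarray) -> np.ndarray:
    return np.stack([np.interp(t_dst, t_src, pos_src[:, k]) for k in range(pos_src.shape[1])], axis=1)


def label_events(
    tracks: list[BallTrack],
    hand_traj: dict[str, tuple[np.ndarray, np.ndarray]],
    hand_radius: float = 0.1,
    min_hold: int = 3,
) -> list[BallTrack]:
    """Annotate tracks with throw and catch events from ball--hand proximity.

    A throw is the first frame a held ball leaves the ``hand_radius``
    neighbourhood of its hand while moving upward; a catch is the first frame
    it enters the opposite hand's neighbourhood and stays inside for at least
    ``min_hold`` frames.  Tracks on which no event can be labeled are
    returned unchanged (empty event list) so callers can exclude them.
    """
    if hand_radius <= 0 or min_hold < 1:
        raise ValueError("hand_radius must be positive and min_hold >= 1")
    out: list[BallTrack] = []
    for track in tracks:
        dists = {}
        for hand, (t_h, p_h) in hand_traj.items():
            p = _resample(np.asarray(t_h, float), np.atleast_2d(p_h), track.t)
            dists[hand] = np.linalg.norm(track.pos - p, axis=1)
        events = _label_one(track, dists, hand_radius, min_hold)
        out.append(replace(track, events=events))
    return out


def _label_one(
    track: BallTrack,
    dists: dict[str, np.ndarray],
    hand_radius: float,
    min_hold: int,
) -> list[Event]:
    hands = sorted(dists)
    n = len(track.t)
    vy = np.gradient(track.vertical, track.t) if n > 1 else np.zeros(n)
    inside = {h: dists[h] < hand_radius for h in hands}

    events: list[Event] = []
    holder: str | None = None
    for h in hands:  # initial holder, if the ball starts in a hand
        if inside[h][0]:
            holder = h
    i = 0
    while i < n:
        if holder is not None:
            # wait for exit with upward velocity -> throw
            if not inside[holder][i] and vy[i] > 0:
                events.append(Event("throw", float(track.t[i]), holder))
                holder = None
            i += 1
        else:
            # in flight: look for a sustained entry into a hand
            caught = None
            for h in hands:
                if events and events[-1].kind == "throw" and h == events[-1].hand:
                    continue  # catches go to the opposite hand
                if inside[h][i] and np.all(inside[h][i : i + min_hold]) and i + min_hold <= n:
                    caught = h
                    break
            if caught is not None:
                # only record catches that complete a labeled throw, so events
                # alternate throw/catch; a pick-up at the trial edge still sets
                # the holder but is not an event
                if events:
                    events.append(Event("catch", float(track.t[i]), caught))
                holder = caught
            i += 1
    return events
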