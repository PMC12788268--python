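"""Synthetic kinematic and performance data with known ground truth.

Emulates the raw streams of a three-ball juggling training study: vertical
cascade trajectories with per-throw timing jitter and trial-ending drops,
two-ball occlusion-catch trials with Bernoulli success and 3-D Gaussian
catch scatter, frame-wise detection tables with dropout / false positives,
and day-level performance drawn from a Gamma GLM generative model.  Every
generator is a pure function of (config, seed), so downstream stages can be
tested against exact ground truth.

The cascade waveform is piecewise-parabolic: ballistic flight under the
configured gravity, and a hand-carry (dwell) arc with constant upward
acceleration chosen to match position and velocity at catch and re-throw.
This keeps the trajectory C1-continuous and periodic, as a real carried
ball is, rather than freezing the ball at the hand between throws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occlusion import OcclusionTrial, schedule_shutter
from .tracking import BallTrack, DetectionFrame, Event, PixelCalibration

__all__ = [
    "CascadeSimConfig",
    "OcclusionSimConfig",
    "PerfGenConfig",
    "GroundTruth",
    "StudySimConfig",
    "simulate_cascade",
    "simulate_occlusion_session",
    "corrupt_detections",
    "generate_performance",
    "generate_study",
]

# Cascade scoop geometry: balls are released near the body midline and
# caught at the outside, which keeps the two flight arcs from colliding.
THROW_X = {"L": -0.06, "R": 0.06}  # m, release positions (inner)
CATCH_X = {"L": -0.34, "R": 0.34}  # m, catch positions (outer)
HAND_X = CATCH_X  # hands rest at the catch-ready position
HAND_Y = 1.0  # m, throw/catch height


@dataclass(frozen=True)
class CascadeSimConfig:
    """Three-ball cascade simulation parameters (one trial)."""

    n_balls: int = 3
    gravity: float = 9.81  # m/s^2; fractions of 9.81 model reduced-g training
    cycle_period: float = 1.35  # s per ball cycle; throws spaced period/3
    phase_jitter_sd: float = 0.0  # radians of per-throw timing noise
    dwell_fraction: float = 0.5  # fraction of the cycle the ball is hand-held
    drop_hazard: float = 0.0  # per-throw probability the trial ends in a drop
    frame_rate: float = 60.0  # Hz
    n_cycles: int = 10  # throws per ball if no drop occurs
    trial_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gravity) and self.gravity > 0):
            raise ValueError("gravity must be finite and positive")
        if not (np.isfinite(self.cycle_period) and self.cycle_period > 0):
            raise ValueError("cycle_period must be finite and positive")
        if not (np.isfinite(self.frame_rate) and self.frame_rate > 0):
            raise ValueError("frame_rate must be finite and positive")
        if not 0 < self.dwell_fraction < 1:
            raise ValueError("dwell_fraction must be in (0, 1)")
        if self.phase_jitter_sd < 0:
            raise ValueError("phase_jitter_sd must be non-negative")
        if not 0 <= self.drop_hazard <= 1:
            raise ValueError("drop_hazard must be a probability")


@dataclass(frozen=True)
class OcclusionSimConfig:
    """Two-ball occlusion-catch session parameters."""

    n_trials: int = 60  # 300 on full test days
    success_prob: float = 0.8  # P(both hands complete the second catch)
    catch_cov: np.ndarray = field(
        default_factory=lambda: 0.0036 * np.eye(3)
    )  # m^2, hand-centred catch scatter (6 cm sd per axis)
    blocks: int = 4
    shutter_duration: float = 0.5  # s
    condition_mix: dict = field(
        default_factory=lambda: {"apex_locked": 1 / 3, "none": 1 / 3, "random": 1 / 3}
    )
    flight_time: float = 0.7  # s, occluded ball flight duration
    frame_rate: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        cov = np.asarray(self.catch_cov, dtype=float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("catch_cov must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("catch_cov must be positive-definite")
        object.__setattr__(self, "catch_cov", cov)
        if not 0 <= self.success_prob <= 1:
            raise ValueError("success_prob must be in [0, 1]")
        if abs(sum(self.condition_mix.values()) - 1.0) > 1e-9:
            raise ValueError("condition_mix proportions must sum to 1")


@dataclass(frozen=True)
class PerfGenConfig:
    """Generative Gamma-Log performance model: log mu = X beta, Perf ~ Gamma."""

    beta: tuple = (2.5563, 0.4073, 0.1669, 0.5279)  # intercept, b_P, b_A, b_S
    dispersion: float = 0.6  # Gamma dispersion phi
    n_participants: int = 20
    days: tuple = (1, 5, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")
        if len(self.beta) != 4:
            raise ValueError("beta must be (intercept, beta_P, beta_A, beta_S)")


@dataclass
class GroundTruth:
    """Exact latent state behind one simulated cascade trial."""

    true_phases: dict  # ball_id -> (t, phase radians), nominal cycle phase
    true_events: dict  # ball_id -> list[Event]
    n_catches: int  # completed catches before any drop
    dropped: bool


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def _throw_hand(ball: int, cycle: int) -> str:
    return "R" if (ball + 3 * cycle) % 2 == 0 else "L"


def simulate_cascade(
    cfg: CascadeSimConfig, rng: np.random.Generator | None = None
) -> tuple[list[BallTrack], GroundTruth]:
    """Simulate one three-ball cascade trial.

    Returns one :class:`BallTrack` per ball, sampled at ``cfg.frame_rate``
    with true throw/catch events attached, plus the ground truth.  Throws of
    ball ``b`` are nominally at ``b*T/3 + c*T`` with Gaussian timing jitter
    of sd ``phase_jitter_sd * T / (2*pi)`` seconds; flights are ballistic
    under ``cfg.gravity``.  Each throw may end the trial with probability
    ``drop_hazard`` (a drop at its catch).
    """
    if cfg.n_balls != 3:
        raise ValueError("cascade generator supports exactly 3 balls")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    T = cfg.cycle_period
    t_f = (1.0 - cfg.dwell_fraction) * T
    v0 = cfg.gravity * t_f / 2.0
    jit_sd = cfg.phase_jitter_sd * T / (2.0 * np.pi)

    # a warm-up of one dwell before the first throw lets every ball start
    # mid-carry, so the trial opens in steady-state cascade motion
    warmup = cfg.dwell_fraction * T
    # jittered throw schedule; a drop truncates the trial at the failed catch
    throws: dict[int, list[float]] = {}
    t_end = warmup + cfg.n_cycles * T + T / 3.0
    dropped = False
    for b in range(3):
        tt = np.array([warmup + b * T / 3.0 + c * T for c in range(cfg.n_cycles)])
        if jit_sd > 0:
            tt = tt + rng.normal(0.0, jit_sd, size=len(tt))
        # a ball cannot be re-thrown before it lands: enforce a minimum
        # throw-to-throw spacing of one flight plus a short dwell
        min_gap = t_f + 0.1 * T
        for i in range(1, len(tt)):
            if tt[i] < tt[i - 1] + min_gap:
                tt[i] = tt[i - 1] + min_gap
        throws[b] = list(tt)
    if cfg.drop_hazard > 0:
        events_flat = sorted(
            (t, b, c) for b in range(3) for c, t in enumerate(throws[b])
        )
        for t, b, c in events_flat:
            if rng.random() < cfg.drop_hazard:
                dropped = True
                t_end = min(t_end, t + t_f)  # trial ends at the failed catch
                break

    tracks: list[BallTrack] = []
    true_events: dict[int, list[Event]] = {}
    true_phases: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    n_catches = 0
    t_grid = np.arange(0.0, t_end, 1.0 / cfg.frame_rate)
    t_d_nominal = cfg.dwell_fraction * T
    for b in range(3):
        y = np.full_like(t_grid, HAND_Y)
        x = np.full_like(t_grid, THROW_X[_throw_hand(b, 0)])
        events: list[Event] = []
        # before its first throw the ball follows its steady-state cycle:
        # the tail of the previous (virtual) flight, then the hand-carry arc
        t0 = throws[b][0]
        h0 = _throw_hand(b, 0)
        if t0 > 0:
            h_prev = "L" if h0 == "R" else "R"
            t_vthrow = t0 - T  # virtual previous throw
            t_vcatch = t0 - t_d_nominal
            m = (t_grid >= 0) & (t_grid < min(max(t_vcatch, 0.0), t_end))
            if m.any():
                dt = t_grid[m] - t_vthrow
                y[m] = HAND_Y + v0 * dt - 0.5 * cfg.gravity * dt**2
                x[m] = THROW_X[h_prev] + (CATCH_X[h0] - THROW_X[h_prev]) * dt / t_f
            m = (t_grid >= max(t_vcatch, 0.0)) & (t_grid < min(t0, t_end))
            if m.any():
                tau = t_grid[m] - t_vcatch
                a = 2.0 * v0 / t_d_nominal
                y[m] = HAND_Y - v0 * tau + 0.5 * a * tau**2
                x[m] = CATCH_X[h0] + (THROW_X[h0] - CATCH_X[h0]) * tau / t_d_nominal
        for c, t_throw in enumerate(throws[b]):
            if t_throw >= t_end:
                break
            t_catch = t_throw + t_f
            h_throw = _throw_hand(b, c)
            h_catch = "L" if h_throw == "R" else "R"
            # ballistic flight: released at the inner (scoop) position,
            # caught at the opposite hand's outer position
            m = (t_grid >= t_throw) & (t_grid < min(t_catch, t_end))
            dt = t_grid[m] - t_throw
            y[m] = HAND_Y + v0 * dt - 0.5 * cfg.gravity * dt**2
            x[m] = THROW_X[h_throw] + (CATCH_X[h_catch] - THROW_X[h_throw]) * dt / t_f
            events.append(Event("throw", t_throw, h_throw))
            if t_catch >= t_end:
                break  # drop: the catch never completes
            events.append(Event("catch", t_catch, h_catch))
            n_catches += 1
            # hand-carry arc until the next throw; after a final catch the
            # ball simply rests in the hand (y stays at HAND_Y)
            t_next = throws[b][c + 1] if c + 1 < len(throws[b]) else np.inf
            if t_next >= t_end:
                # rest in the hand; small per-ball offset so two balls held
                # by one hand at the trial end do not coincide
                x[(t_grid >= t_catch)] = CATCH_X[h_catch] + 0.04 * (b - 1)
                continue
            t_d = t_next - t_catch
            m = (t_grid >= t_catch) & (t_grid < min(t_next, t_end))
            if t_d > 0 and m.any():
                a = 2.0 * v0 / t_d
                dt = t_grid[m] - t_catch
                y[m] = HAND_Y - v0 * dt + 0.5 * a * dt**2
                x[m] = CATCH_X[h_catch] + (THROW_X[h_catch] - CATCH_X[h_catch]) * dt / t_d
        tracks.append(BallTrack(ball_id=b + 1, t=t_grid.copy(), pos=np.stack([x, y], axis=1), events=events))
        true_events[b + 1] = events
        phase = (
            np.mod(2.0 * np.pi * (t_grid - warmup - b * T / 3.0) / T + np.pi, 2.0 * np.pi)
            - np.pi
        )
        true_phases[b + 1] = (t_grid.copy(), phase)

    truth = GroundTruth(
        true_phases=true_phases,
        true_events=true_events,
        n_catches=n_catches,
        dropped=dropped,
    )
    return tracks, truth


def cascade_hand_trajectories(
    tracks: list[BallTrack], t_grid: np.ndarray | None = None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Hand trajectories implied by a cascade: a hand carries its held ball
    between that ball's catch and next throw, and rests at its base otherwise."""
    if t_grid is None:
        t_grid = tracks[0].t
    traj = {}
    for hand in ("L", "R"):
        pos = np.stack(
            [np.full_like(t_grid, HAND_X[hand]), np.full_like(t_grid, HAND_Y)], axis=1
        )
        # dwell duration inferred from catch->throw gaps, for pre-trial carries
        gaps = [
            nxt.t - ev.t
            for track in tracks
            for ev, nxt in zip(track.events, track.events[1:])
            if ev.kind == "catch" and nxt.kind == "throw"
        ]
        dwell = float(np.median(gaps)) if gaps else 0.0
        for track in tracks:
            evs = track.events
            carries = []
            if evs and evs[0].kind == "throw" and evs[0].hand == hand:
                # carry tail from the (virtual) catch preceding the first throw
                carries.append((max(t_grid[0], evs[0].t - dwell), evs[0].t))
            for i, ev in enumerate(evs):
                if ev.kind != "catch" or ev.hand != hand:
                    continue
                t_next = next((e.t for e in evs[i + 1 :] if e.kind == "throw"), np.inf)
                carries.append((ev.t, t_next))
            for t_from, t_to in carries:
                m = (t_grid >= t_from) & (t_grid < t_to)
                ball_pos = np.stack(
                    [np.interp(t_grid[m], track.t, track.pos[:, k]) for k in range(2)],
                    axis=1,
                )
                pos[m] = ball_pos
        traj[hand] = (t_grid.copy(), pos)
    return traj


# ---------------------------------------------------------------------------
# Occlusion session
# ---------------------------------------------------------------------------

_WRIST = {"L": np.array([-0.25, 0.05, 1.0]), "R": np.array([0.25, 0.05, 1.0])}


def simulate_occlusion_session(
    cfg: OcclusionSimConfig, rng: np.random.Generator | None = None
) -> list[OcclusionTrial]:
    """Simulate one occlusion session of two-ball throw--catch trials.

    Each trial carries a condition label, per-hand second-catch outcomes
    (jointly successful with probability ``success_prob``), and, for
    successful catches, a 3-D catch position equal to the wrist position
    plus a draw from N(0, catch_cov).  Shutter intervals follow the trial's
    condition: apex-locked, absent, or uniformly random over the flight.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    conditions = list(cfg.condition_mix)
    probs = np.array([cfg.condition_mix[c] for c in conditions])
    chol = np.linalg.cholesky(cfg.catch_cov)
    trials: list[OcclusionTrial] = []
    per_block = int(np.ceil(cfg.n_trials / cfg.blocks))
    for i in range(cfg.n_trials):
        condition = conditions[rng.choice(len(conditions), p=probs)]
        block = i // per_block
        # occluded-ball vertical flight (ballistic), for shutter scheduling
        t_f = cfg.flight_time
        v0 = 9.81 * t_f / 2.0
        t = np.arange(0.0, t_f, 1.0 / cfg.frame_rate)
        y = HAND_Y + v0 * t - 0.5 * 9.81 * t**2
        track = BallTrack(ball_id=2, t=t, pos=np.stack([np.zeros_like(t), y], axis=1))
        both_ok = rng.random() < cfg.success_prob
        if both_ok:
            success = {"L": True, "R": True}
        else:  # attribute the failure to one or both hands
            success = [
                {"L": False, "R": True},
                {"L": True, "R": False},
                {"L": False, "R": False},
            ][rng.choice(3)]
        wrist = {h: _WRIST[h] + rng.normal(0.0, 0.01, size=3) for h in ("L", "R")}
        catch_pos = {
            h: (wrist[h] + chol @ rng.standard_normal(3) if success[h] else None)
            for h in ("L", "R")
        }
        shutter, valid, reason = [], True, ""
        try:
            shutter = schedule_shutter(track, condition, cfg.shutter_duration, rng=rng)
        except ValueError:
            valid, reason = False, "no apex detected"
        trials.append(
            OcclusionTrial(
                participant=0,
                day=0,
                block=block,
                condition=condition,
                success=success,
                catch_pos=catch_pos,
                wrist_pos=wrist,
                shutter_intervals=shutter,
                valid=valid,
                invalid_reason=reason,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# Detection corruption
# ---------------------------------------------------------------------------

def corrupt_detections(
    tracks: list[BallTrack],
    dropout_rate: float = 0.0,
    false_positive_rate: float = 0.0,
    noise_sd: float = 0.0,
    hand_traj: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    calibration: PixelCalibration | None = None,
    rng: np.random.Generator | None = None,
    frame_extent: tuple[float, float] = (-1.5, 3.0),
) -> list[DetectionFrame]:
    """Degrade clean tracks into frame-wise unordered detection tables.

    Each true ball appears with probability ``1 - dropout_rate``, perturbed
    by isotropic Gaussian noise of sd ``noise_sd`` (pixels if a calibration
    is given, metres otherwise); Poisson(``false_positive_rate``) false
    candidates per frame are placed uniformly in the frame; candidate order
    is shuffled.  With a :class:`PixelCalibration` the output is projected
    to the pixel frame (y down-positive), as a camera would report it.
    """
    if not 0 <= dropout_rate <= 1:
        raise ValueError("dropout_rate must be in [0, 1]")
    if false_positive_rate < 0 or noise_sd < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(0) if rng is None else rng
    t_grid = tracks[0].t
    dim = tracks[0].pos.shape[1]
    positions = np.stack([tr.pos for tr in tracks])  # (n_balls, n_frames, d)
    lo, hi = frame_extent
    frames: list[DetectionFrame] = []
    for i, t in enumerate(t_grid):
        cands = []
        for b in range(len(tracks)):
            if dropout_rate and rng.random() < dropout_rate:
                continue
            p = positions[b, i].copy()
            if calibration is not None:
                p = calibration.to_pixels(p)
            if noise_sd:
                p = p + rng.normal(0.0, noise_sd, size=dim)
            cands.append(p)
        n_fp = rng.poisson(false_positive_rate) if false_positive_rate else 0
        for _ in range(n_fp):
            p = rng.uniform(lo, hi, size=dim)
            if calibration is not None:
                p = calibration.to_pixels(p)
            cands.append(p)
        if len(cands) > 1:
            cands = [cands[j] for j in rng.permutation(len(cands))]
        hands = {}
        if hand_traj is not None:
            for h, (t_h, p_h) in hand_traj.items():
                p = np.array([np.interp(t, t_h, p_h[:, k]) for k in range(p_h.shape[1])])
                hands[h] = calibration.to_pixels(p) if calibration is not None else p
        arr = np.stack(cands) if cands else np.empty((0, dim))
        frames.append(
            DetectionFrame(t=float(t), ball_candidates=arr, hand_positions=hands, calibration=calibration)
        )
    return frames


# ---------------------------------------------------------------------------
# Performance generation (Gamma-Log generative model)
# ---------------------------------------------------------------------------

def generate_performance(
    indices: pd.DataFrame, cfg: PerfGenConfig, rng: np.random.Generator | None = None
) -> pd.Series:
    """Draw day-level performance from the Gamma-Log generative model.

    ``log mu = b0 + b_P*Z_P + b_A*Z_A + b_S*Z_S``; Perf ~ Gamma with mean
    ``mu`` and dispersion ``phi`` (shape ``1/phi``, scale ``mu*phi``).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    Z = indices[["Z_P", "Z_A", "Z_S"]].to_numpy(dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("standardized indices must be finite")
    b0, bP, bA, bS = cfg.beta
    mu = np.exp(b0 + Z @ np.array([bP, bA, bS]))
    shape = 1.0 / cfg.dispersion
    perf = rng.gamma(shape, mu * cfg.dispersion)
    return pd.Series(perf, index=indices.index, name="Perf")


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

# Day-level skill schedule: timing jitter falls, catch success rises and
# catch scatter tightens across training days, mirroring early learning.
_DAY_SKILL = {
    1: {"jitter": 0.9, "success": 0.55, "scatter": 0.09, "drop": 0.10},
    5: {"jitter": 0.55, "success": 0.80, "scatter": 0.07, "drop": 0.05},
    10: {"jitter": 0.35, "success": 0.92, "scatter": 0.05, "drop": 0.03},
}


@dataclass(frozen=True)
class StudySimConfig:
    """Whole-study simulation: participants x days, both training groups."""

    n_participants: int = 20
    days: tuple = (1, 5, 10)
    cascade: CascadeSimConfig = field(default_factory=CascadeSimConfig)
    occlusion: OcclusionSimConfig = field(default_factory=OcclusionSimConfig)
    perf: PerfGenConfig = field(default_factory=PerfGenConfig)
    cascade_trials: int = 4
    dropout_rate: float = 0.02
    false_positive_rate: float = 0.2
    noise_sd: float = 0.004  # m, detection noise
    participant_sd: float = 0.25  # log-scale heterogeneity of skill levels
    day_skill: dict = field(default_factory=lambda: dict(_DAY_SKILL))
    seed: int = 0


@dataclass
class ParticipantDay:
    participant: int
    day: int
    group: str
    detection_trials: list  # list of list[DetectionFrame]
    truth_tracks: list  # list of list[BallTrack] (clean, with events)
    hand_trajs: list  # list of hand trajectory dicts
    truths: list  # list of GroundTruth
    occlusion_trials: list  # list[OcclusionTrial]


def generate_study(cfg: StudySimConfig, seed: int | None = None) -> list[ParticipantDay]:
    """Generate raw streams for every participant-day of a synthetic study.

    Participants 1..n/2 form the Low-g group, the rest Normal-g (group
    labels only; the gravity intervention itself is not simulated).  Skill
    follows the day schedule with log-normal participant heterogeneity.
    Deterministic given (cfg, seed).
    """
    master = cfg.seed if seed is None else seed
    records: list[ParticipantDay] = []
    half = cfg.n_participants // 2
    for p in range(1, cfg.n_participants + 1):
        p_ss = np.random.SeedSequence(entropy=master, spawn_key=(p,))
        p_rng = np.random.default_rng(p_ss)
        # independent participant-level factors per skill dimension (>1 = worse);
        # the three indices are distinct sub-skills, not one latent ability
        skill_s, skill_p, skill_a = np.exp(
            p_rng.normal(0.0, cfg.participant_sd, size=3)
        )
        group = "Low-g" if p <= half else "Normal-g"
        for day in cfg.days:
            d_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=master, spawn_key=(p, day))
            )
            sk = cfg.day_skill[day]
            jitter = sk["jitter"] * skill_s
            success = float(np.clip(sk["success"] ** skill_p, 0.0, 1.0))
            scatter = sk["scatter"] * skill_a
            cas = CascadeSimConfig(
                gravity=cfg.cascade.gravity,
                cycle_period=cfg.cascade.cycle_period,
                phase_jitter_sd=jitter,
                dwell_fraction=cfg.cascade.dwell_fraction,
                drop_hazard=sk["drop"],
                frame_rate=cfg.cascade.frame_rate,
                n_cycles=cfg.cascade.n_cycles,
            )
            det_trials, truth_tracks, hand_trajs, truths = [], [], [], []
            for _ in range(cfg.cascade_trials):
                tracks, truth = simulate_cascade(cas, rng=d_rng)
                hands = cascade_hand_trajectories(tracks)
                frames = corrupt_detections(
                    tracks,
                    dropout_rate=cfg.dropout_rate,
                    false_positive_rate=cfg.false_positive_rate,
                    noise_sd=cfg.noise_sd,
                    hand_traj=hands,
                    rng=d_rng,
                )
                det_trials.append(frames)
                truth_tracks.append(tracks)
                hand_trajs.append(hands)
                truths.append(truth)
            occ = OcclusionSimConfig(
                n_trials=cfg.occlusion.n_trials,
                success_prob=success,
                catch_cov=scatter**2 * np.eye(3),
                blocks=cfg.occlusion.blocks,
                shutter_duration=cfg.occlusion.shutter_duration,
                condition_mix=cfg.occlusion.condition_mix,
                frame_rate=cfg.occlusion.frame_rate,
            )
            occ_trials = simulate_occlusion_session(occ, rng=d_rng)
            for tr in occ_trials:
                tr.participant, tr.day = p, day
            records.append(
                ParticipantDay(
                    participant=p,
                    day=day,
                    group=group,
                    detection_trials=det_trials,
                    truth_tracks=truth_tracks,
                    hand_trajs=hand_trajs,
                    truths=truths,
                    occlusion_trials=occ_trials,
                )
            )
    return records
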