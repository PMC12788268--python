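"""Phase estimation and Sequencing-score tests, including a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jugglekit import sequencing
from jugglekit.sequencing import (
    PhaseSeries,
    SequencingWindow,
    detect_apexes,
    exclude_low_window_days,
    instantaneous_phase,
    make_windows,
    smooth_center,
    window_score,
)


def brute_force_window_score(phi_deg: np.ndarray) -> float:
    """Independent loop evaluation of the window score on (3, K) phases in degrees.

    Naive circular arithmetic: for each sample and pair, the deviation is the
    smallest absolute angle between the raw pairwise difference and +/-120 deg.
    """
    total = 0.0
    K = phi_deg.shape[1]
    for k in range(K):
        dev_sum = 0.0
        for i, j in ((0, 1), (0, 2), (1, 2)):
            diff = phi_deg[j, k] - phi_deg[i, k]
            best = 360.0
            for ideal in (120.0, -120.0):
                d = abs(diff - ideal) % 360.0
                if d > 180.0:
                    d = 360.0 - d
                best = min(best, d)
            dev_sum += best
        total += 1.0 - dev_sum / 540.0
    return total / K


def _phase_series(phi_deg: np.ndarray) -> PhaseSeries:
    n = phi_deg.shape[1]
    t = np.arange(n, dtype=float)
    return PhaseSeries(
        t=t, phi=np.radians(phi_deg), valid=np.ones((3, n), bool), ball_ids=(1, 2, 3)
    )


def _score(phi_deg: np.ndarray) -> float:
    w = SequencingWindow(w_start=-1.0, w_end=phi_deg.shape[1] + 1.0, ball_ids=(1, 2, 3))
    return window_score(_phase_series(phi_deg), w).S_w


class TestWindowScore:
    def test_exact_120_spacing_scores_one(self):
        t = np.linspace(0, 720, 50)
        phi = np.stack([t, t + 120.0, t + 240.0])
        assert _score(phi) == pytest.approx(1.0, abs=1e-12)

    def test_in_phase_balls_score_one_third(self):
        # all pairwise differences 0 -> every deviation is 120 degrees
        phi = np.zeros((3, 20))
        assert _score(phi) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_single_ball_offset_epsilon(self):
        # one ball off by eps leaves two pairs deviating by eps each
        eps = 3.0
        phi = np.stack([np.zeros(10), np.full(10, 120.0 + eps), np.full(10, 240.0)])
        assert _score(phi) == pytest.approx(1.0 - eps / 270.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_phases(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            phi = rng.uniform(-180.0, 180.0, size=(3, rng.integers(1, 40)))
            assert _score(phi) == pytest.approx(brute_force_window_score(phi), abs=1e-12)

    @given(
        rotation=st.floats(-720, 720, allow_nan=False),
        perm=st.permutations([0, 1, 2]),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_to_rotation_and_relabeling(self, rotation, perm, seed):
        phi = np.random.default_rng(seed).uniform(-180, 180, size=(3, 15))
        base = _score(phi)
        assert 0.0 <= base <= 1.0
        assert _score(phi + rotation) == pytest.approx(base, abs=1e-9)
        assert _score(phi[list(perm)]) == pytest.approx(base, abs=1e-9)

    def test_empty_window_dropped(self):
        ps = _phase_series(np.zeros((3, 10)))
        w = window_score(ps, SequencingWindow(w_start=100.0, w_end=200.0, ball_ids=(1, 2, 3)))
        assert w.K == 0 and np.isnan(w.S_w)


class TestInstantaneousPhase:
    def test_cosine_phase_is_linear(self):
        fs, f = 60.0, 1.0
        t = np.arange(0, 10, 1 / fs)
        phi = np.degrees(instantaneous_phase(np.cos(2 * np.pi * f * t)))
        expected = np.mod(np.degrees(2 * np.pi * f * t) + 180, 360) - 180
        interior = slice(60, -60)
        err = np.abs(np.mod(phi[interior] - expected[interior] + 180, 360) - 180)
        assert err.max() < 1.0

    def test_sine_lags_cosine_by_90(self):
        fs, f = 60.0, 1.0
        t = np.arange(0, 10, 1 / fs)
        phi = np.degrees(instantaneous_phase(np.sin(2 * np.pi * f * t)))
        expected = np.mod(np.degrees(2 * np.pi * f * t) - 90 + 180, 360) - 180
        interior = slice(60, -60)
        err = np.abs(np.mod(phi[interior] - expected[interior] + 180, 360) - 180)
        assert err.max() < 1.0

    def test_third_period_offsets_give_120(self):
        T, fs = 1.5, 60.0
        t = np.arange(0, 15, 1 / fs)
        phis = [instantaneous_phase(np.cos(2 * np.pi * (t - b * T / 3) / T)) for b in range(3)]
        interior = slice(120, -120)
        for i, j in ((0, 1), (1, 2)):
            diff = np.degrees(phis[i][interior] - phis[j][interior])
            dev = np.abs(np.mod(diff - 120.0 + 180.0, 360.0) - 180.0)
            assert dev.max() < 1.0

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros(100))


class TestSmoothCenter:
    def test_constant_series_maps_to_zeros(self):
        out = smooth_center(np.full(300, 5.0), fs=60.0)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_passband_sinusoid_barely_attenuated(self):
        fs = 60.0
        t = np.arange(0, 20, 1 / fs)
        y = np.sin(2 * np.pi * 1.5 * t)
        out = smooth_center(y, fs, cutoff=5.0)
        interior = slice(120, -120)
        amp = np.ptp(out[interior]) / np.ptp(y[interior])
        assert abs(amp - 1.0) < 0.01

    def test_high_frequency_noise_power_reduced(self):
        fs = 60.0
        t = np.arange(0, 20, 1 / fs)
        noise = 0.5 * np.sin(2 * np.pi * 20.0 * t)
        out = smooth_center(np.sin(2 * np.pi * 1.0 * t) + noise, fs, cutoff=5.0)
        resid = out - smooth_center(np.sin(2 * np.pi * 1.0 * t), fs, cutoff=5.0)
        assert np.mean(resid**2) < 0.1 * np.mean(noise**2)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            smooth_center(np.ones(30), fs=60.0)


class TestApexes:
    def test_parabola_apex_at_v0_over_g(self):
        v0, g, fs = 3.0, 9.81, 60.0
        t = np.arange(0, 2 * v0 / g, 1 / fs)
        apexes = detect_apexes(t, v0 * t - 0.5 * g * t**2)
        assert len(apexes) == 1
        assert abs(apexes[0] - v0 / g) <= 1 / fs

    def test_sinusoid_apexes_spaced_by_period(self):
        T, fs = 1.5, 60.0
        t = np.arange(0, 10 * T, 1 / fs)
        apexes = detect_apexes(t, np.sin(2 * np.pi * t / T))
        assert np.all(np.abs(np.diff(apexes) - T) <= 1 / fs)

    def test_jittered_cascade_apex_count_equals_throws(self, clean_cascade):
        cfg, tracks, truth = clean_cascade
        for tr in tracks:
            y = smooth_center(tr.vertical, cfg.frame_rate)
            apexes = detect_apexes(
                tr.t, y, refractory=0.25 * cfg.cycle_period, min_height=0.5 * np.std(y)
            )
            n_throws = sum(e.kind == "throw" for e in truth.true_events[tr.ball_id])
            assert abs(len(apexes) - n_throws) <= 1  # edge cycles may clip one


class TestWindows:
    @pytest.mark.parametrize(
        "labels, expected",
        [([1, 2, 3, 1, 2, 3], 4), ([1, 1, 2, 3], 1), ([1, 2, 1, 2], 0), ([1, 2], 0)],
    )
    def test_window_enumeration(self, labels, expected):
        apexes = [(float(i), b) for i, b in enumerate(labels)]
        assert len(make_windows(apexes)) == expected

    def test_windows_span_first_to_third_apex(self):
        wins = make_windows([(0.0, 1), (0.5, 2), (1.1, 3)])
        assert wins[0].w_start == 0.0 and wins[0].w_end == 1.1


class TestDayAggregation:
    def test_day_mean_of_windows(self):
        wins = [
            SequencingWindow(0, 1, (1, 2, 3), K=5, S_w=1.0),
            SequencingWindow(1, 2, (1, 2, 3), K=5, S_w=0.5),
        ]
        day = sequencing.day_sequencing(wins)
        assert day.S == pytest.approx(0.75)
        assert day.n_windows == 2

    def test_no_windows_flagged_missing(self):
        day = sequencing.day_sequencing([])
        assert day.excluded and np.isnan(day.S)

    def test_zero_jitter_cascade_scores_near_one(self, clean_cascade):
        cfg, tracks, _ = clean_cascade
        wins = sequencing.score_trial(tracks, cfg.frame_rate)
        day = sequencing.day_sequencing(wins)
        assert day.S >= 0.98

    def test_day_s_decreases_with_jitter(self):
        from jugglekit import synth

        means = []
        for jitter in (0.0, 0.3, 0.6, 0.9):
            scores = []
            for seed in range(6):
                cfg = synth.CascadeSimConfig(phase_jitter_sd=jitter, seed=seed)
                tracks, _ = synth.simulate_cascade(cfg)
                wins = sequencing.score_trial(tracks, cfg.frame_rate)
                scores.extend(w.S_w for w in wins)
            means.append(np.mean(scores))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestWindowCountExclusion:
    def test_zero_count_day_always_excluded(self):
        mask, _ = exclude_low_window_days(np.array([0]))
        assert mask.tolist() == [True]

    def test_lognormal_threshold_near_closed_form(self):
        rng = np.random.default_rng(99)
        counts = np.exp(rng.normal(3.5, 0.7, size=5000))
        _, threshold = exclude_low_window_days(counts)
        assert threshold == pytest.approx(np.exp(3.5 - 3 * 0.7), rel=0.15)

    def test_constant_counts_keep_everything(self):
        mask, _ = exclude_low_window_days(np.full(30, 50.0))
        assert not mask.any()

    def test_fuzz_scores_stay_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            phi = rng.uniform(-1000, 1000, size=(3, rng.integers(1, 30)))
            s = _score(phi)
            assert 0.0 <= s <= 1.0
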