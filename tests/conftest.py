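import numpy as np
import pandas as pd
import pytest

from jugglekit import synth
from jugglekit.tracking import BallTrack


@pytest.fixture(scope="session")
def clean_cascade():
    """One noiseless default cascade trial with ground truth."""
    cfg = synth.CascadeSimConfig(phase_jitter_sd=0.0, drop_hazard=0.0, n_cycles=10)
    tracks, truth = synth.simulate_cascade(cfg)
    return cfg, tracks, truth


@pytest.fixture(scope="session")
def sinusoid_tracks():
    """Three pure sinusoidal 'balls' offset by a third period (ideal cascade)."""
    T, fs = 1.4, 60.0
    t = np.arange(0.0, 12 * T, 1.0 / fs)
    tracks = [
        BallTrack(
            ball_id=b + 1,
            t=t,
            pos=np.stack(
                [np.zeros_like(t), 1.0 + 0.3 * np.cos(2 * np.pi * (t - b * T / 3) / T)],
                axis=1,
            ),
        )
        for b in range(3)
    ]
    return T, fs, tracks


def make_index_table(n, rng, beta=(2.5563, 0.4073, 0.1669, 0.5279), dispersion=0.6,
                     n_participants=19):
    """Day-level table with independent standardized indices and Gamma Perf."""
    Z = rng.standard_normal((n, 3))
    df = pd.DataFrame(Z, columns=["Z_P", "Z_A", "Z_S"])
    # consecutive rows are one participant's days, so every participant
    # contributes all three days (participant and day are not confounded)
    df["participant"] = (np.arange(n) // 3) % n_participants + 1
    df["day"] = np.array([1, 5, 10])[np.arange(n) % 3]
    df["group"] = np.where(df["participant"] <= n_participants // 2, "Low-g", "Normal-g")
    cfg = synth.PerfGenConfig(beta=tuple(beta), dispersion=dispersion)
    df["Perf"] = synth.generate_performance(df, cfg, rng=rng)
    return df
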