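import numpy as np
import pandas as pd
import pytest

from dtflow import LfpRecording, SimulationConfig, TrialTable
from dtflow.containers import TRIAL_TABLE_COLUMNS

#: Published per-subject trial counts (correct, incorrect) for the eight mice.
STUDY_TRIAL_COUNTS = [
    (42, 18),
    (48, 18),
    (22, 12),
    (50, 13),
    (34, 13),
    (41, 18),
    (29, 12),
    (29, 13),
]


def make_trial_table(counts=STUDY_TRIAL_COUNTS, seed=0) -> TrialTable:
    """Trial table with the study's per-subject outcome counts."""
    rng = np.random.default_rng(seed)
    rows = []
    trial = 0
    for subject, (n_cor, n_inc) in enumerate(counts, start=1):
        for outcome, n in (("correct", n_cor), ("incorrect", n_inc)):
            for _ in range(n):
                rows.append(
                    {
                        "subject": subject,
                        "trial": trial,
                        "phase": "choice",
                        "outcome": outcome,
                        "t_start": 0.0,
                        "t_turn": 1.2,
                        "t_reward": 2.0,
                        "speed": float(rng.normal(0.15, 0.02)),
                        "duration": float(rng.normal(2.0, 0.15)),
                    }
                )
                trial += 1
    return TrialTable(pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS))


def tone(freq, duration=2.0, fs=1000.0, amplitude=1.0, regions=("mPFC",)):
    """Single- or multi-channel pure sinusoid recording."""
    t = np.arange(int(round(duration * fs))) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t)
    samples = np.tile(x, (len(regions), 1))
    return LfpRecording(samples, fs, list(regions))


@pytest.fixture(scope="session")
def study_table() -> TrialTable:
    return make_trial_table()


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated session shared across tests (read-only)."""
    from dtflow import simulate_trials

    cfg = SimulationConfig(
        n_mpfc_channels=2,
        n_md_channels=2,
        n_correct=6,
        n_incorrect=4,
        trial_duration=1.5,
        seed=11,
    )
    return simulate_trials(cfg)
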