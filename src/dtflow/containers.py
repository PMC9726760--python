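"""Core data containers for trial-based multichannel LFP analysis.

The in-memory objects are deliberately thin: an :class:`LfpRecording` wraps a
``channels x samples`` array with its sampling rate and per-channel region
labels, a :class:`TrialTable` wraps a pandas DataFrame of per-trial events and
outcomes, and :class:`BandDefinition` names a frequency interval.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LfpRecording",
    "BandDefinition",
    "TrialTable",
    "THETA",
    "DELTA",
    "BETA",
    "GAMMA",
    "CANONICAL_BANDS",
    "TRIAL_TABLE_COLUMNS",
]

#: Column order of the on-disk trial-table CSV.
TRIAL_TABLE_COLUMNS = [
    "subject",
    "trial",
    "phase",
    "outcome",
    "t_start",
    "t_turn",
    "t_reward",
    "speed",
    "duration",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, e.g. theta = 4-12 Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )

    def validate_for_rate(self, sampling_rate: float) -> None:
        if self.high >= sampling_rate / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high} Hz is at or above "
                f"Nyquist ({sampling_rate / 2} Hz)"
            )


THETA = BandDefinition("theta", 4.0, 12.0)
DELTA = BandDefinition("delta", 0.5, 4.0)
BETA = BandDefinition("beta", 12.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 80.0)

CANONICAL_BANDS = {b.name: b for b in (DELTA, THETA, BETA, GAMMA)}


@dataclass
class LfpRecording:
    """Multichannel LFP signal for one trial.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` in signal units (uV).
    sampling_rate
        Samples per second (Hz).
    channel_regions
        One region label per channel, e.g. ``["mPFC", "mPFC", "MD", "MD"]``.
    trial_id, subject_id
        Optional provenance labels carried through the pipeline.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_regions: list[str]
    trial_id: int | None = None
    subject_id: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x samples) array")
        self.channel_regions = list(self.channel_regions)
        if len(self.channel_regions) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_regions)} region labels for "
                f"{self.samples.shape[0]} channels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def region_channels(self, region: str) -> np.ndarray:
        """Indices of the channels recorded in *region*."""
        idx = np.flatnonzero(np.asarray(self.channel_regions) == region)
        if idx.size == 0:
            raise KeyError(
                f"no channels labelled {region!r}; have {sorted(set(self.channel_regions))}"
            )
        return idx

    def with_samples(self, samples: np.ndarray) -> "LfpRecording":
        """Copy of this recording with *samples* replacing the signal."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    def require_finite(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")


@dataclass
class TrialTable:
    """Per-trial event, outcome and kinematics table.

    Wraps a DataFrame with the columns in :data:`TRIAL_TABLE_COLUMNS`.  The
    event columns hold the trial-relative times (seconds) of the position
    landmarks: start box (a/d), beginning of the turn (b/e) and reward port
    (c/f) for sample/choice runs.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        self.data = self.data.loc[:, TRIAL_TABLE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_trials(self) -> int:
        return len(self.data)

    def outcome_counts(self) -> dict[str, int]:
        return self.data["outcome"].value_counts().to_dict()

    @property
    def n_correct(self) -> int:
        return int((self.data["outcome"] == "correct").sum())

    @property
    def n_incorrect(self) -> int:
        return int((self.data["outcome"] == "incorrect").sum())

    def subset(self, mask) -> "TrialTable":
        return TrialTable(self.data.loc[mask].reset_index(drop=True))

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialTable":
        path = Path(path)
        try:
            df = pd.read_csv(path)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed trial table {path}: {exc}") from exc
        if df.empty and set(TRIAL_TABLE_COLUMNS) - set(df.columns):
            raise ValueError(f"trial table {path} lacks the declared header")
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return self.data.equals(other.data)
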