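"""Hierarchical container I/O for signals, spectrograms and DTF stacks.

One HDF5 file per stage output: trial datasets under ``/trials`` (channels x
samples, with sampling-rate and region-label attributes), spectrogram stacks
under ``/spectrograms`` and per-trial DTF window stacks under ``/dtf``.
Every file carries the effective configuration hash so that artifacts from
different runs cannot be silently mixed.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .connectivity import DtfSpectrum
from .containers import LfpRecording
from .spectral import Spectrogram

__all__ = [
    "save_recordings",
    "load_recordings",
    "save_spectrograms",
    "save_dtf_windows",
    "load_dtf_windows",
    "read_config_hash",
]

SCHEMA_VERSION = 1


def _check_hash(f: h5py.File, config_hash: str | None) -> None:
    stored = f.attrs.get("config_hash")
    if config_hash is not None and stored is not None and stored != config_hash:
        raise ValueError(
            f"config hash mismatch: file {stored!r} vs expected {config_hash!r}; "
            "refusing to mix artifacts from different configurations"
        )


def _init_file(f: h5py.File, config_hash: str | None) -> None:
    f.attrs["schema_version"] = SCHEMA_VERSION
    if config_hash is not None:
        f.attrs["config_hash"] = config_hash


def save_recordings(
    path: str | Path,
    recordings: list[LfpRecording],
    config_hash: str | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        _init_file(f, config_hash)
        grp = f.create_group("trials")
        for rec in recordings:
            d = grp.create_dataset(
                f"trial_{rec.trial_id:05d}", data=rec.samples, chunks=True
            )
            d.attrs["sampling_rate"] = rec.sampling_rate
            d.attrs["channel_regions"] = np.array(rec.channel_regions, dtype="S")
            d.attrs["trial_id"] = -1 if rec.trial_id is None else rec.trial_id
            d.attrs["subject_id"] = -1 if rec.subject_id is None else rec.subject_id


def load_recordings(
    path: str | Path, config_hash: str | None = None
) -> list[LfpRecording]:
    out = []
    with h5py.File(path, "r") as f:
        _check_hash(f, config_hash)
        for name in sorted(f["trials"]):
            d = f["trials"][name]
            regions = [r.decode() for r in d.attrs["channel_regions"]]
            tid = int(d.attrs["trial_id"])
            sid = int(d.attrs["subject_id"])
            out.append(
                LfpRecording(
                    samples=d[()],
                    sampling_rate=float(d.attrs["sampling_rate"]),
                    channel_regions=regions,
                    trial_id=None if tid < 0 else tid,
                    subject_id=None if sid < 0 else sid,
                )
            )
    return out


def save_spectrograms(
    path: str | Path,
    specs: dict[int, Spectrogram],
    config_hash: str | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        _init_file(f, config_hash)
        grp = f.create_group("spectrograms")
        for trial_id, spec in specs.items():
            d = grp.create_dataset(f"trial_{trial_id:05d}", data=spec.power, chunks=True)
            d.attrs["time_bin_centers"] = spec.time_bin_centers
            d.attrs["frequency_grid"] = spec.frequency_grid
            d.attrs["window_length"] = spec.window_length
            d.attrs["step"] = spec.step


def save_dtf_windows(
    path: str | Path,
    dtf_by_trial: dict[int, tuple[list[DtfSpectrum], np.ndarray]],
    node_regions: list[str],
    config_hash: str | None = None,
) -> None:
    """Store per-trial window stacks: gamma_sq (windows x F x N x N)."""
    with h5py.File(path, "w") as f:
        _init_file(f, config_hash)
        f.attrs["node_regions"] = np.array(node_regions, dtype="S")
        grp = f.create_group("dtf")
        for trial_id, (windows, centers) in dtf_by_trial.items():
            stack = np.stack([w.gamma_sq for w in windows])
            d = grp.create_dataset(f"trial_{trial_id:05d}", data=stack, chunks=True)
            d.attrs["window_centers"] = np.asarray(centers, dtype=float)
            d.attrs["frequency_grid"] = windows[0].frequency_grid


def load_dtf_windows(
    path: str | Path, config_hash: str | None = None
) -> tuple[dict[int, tuple[list[DtfSpectrum], np.ndarray]], list[str]]:
    out: dict[int, tuple[list[DtfSpectrum], np.ndarray]] = {}
    with h5py.File(path, "r") as f:
        _check_hash(f, config_hash)
        regions = [r.decode() for r in f.attrs["node_regions"]]
        for name in sorted(f["dtf"]):
            d = f["dtf"][name]
            freqs = d.attrs["frequency_grid"]
            centers = d.attrs["window_centers"]
            stack = d[()]
            windows = [
                DtfSpectrum(gamma_sq=g, frequency_grid=freqs, node_regions=regions)
                for g in stack
            ]
            out[int(name.split("_")[1])] = (windows, np.asarray(centers))
    return out, regions


def read_config_hash(path: str | Path) -> str | None:
    with h5py.File(path, "r") as f:
        h = f.attrs.get("config_hash")
    return None if h is None else str(h)
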