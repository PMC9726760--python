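"""End-to-end orchestration: simulate -> preprocess -> spectrogram -> DTF ->
information flow -> statistics, driven by one schema-versioned configuration.

Every output directory receives the full effective configuration
(``config.yaml``) and its hash; intermediate artifacts carry the hash so that
stages refuse inputs produced under a different configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .connectivity import windowed_dtf
from .containers import CANONICAL_BANDS, BandDefinition, LfpRecording, TrialTable
from .information_flow import delta_if, if_timecourse, map_to_position
from .preprocess import preprocess_recording
from .spectral import multitaper_spectrogram
from .stats import anova, mann_whitney, movement_control, subsample_match
from .synthetic import CouplingSpec, SimulationConfig, simulate_trials

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "information_flow_table",
    "read_trial_table",
    "write_trial_table",
]

log = logging.getLogger("dtflow")

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Stage parameters for the whole pipeline."""

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detrend_order: int = 2
    notch_quality: float = 30.0
    spectral_window: float = 0.5
    spectral_step: float = 0.125
    spectral_resolution: float = 1.0
    mvar_order: int | str = "bic"
    mvar_max_order: int = 20
    dtf_window: float = 0.5
    dtf_step: float = 0.125
    band: str = "theta"
    n_position_bins: int = 10
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            sim = dict(self.simulation)
            if "coupling_spec" in sim:
                sim["coupling_spec"] = [
                    c if isinstance(c, CouplingSpec) else CouplingSpec(**{**c, "epoch_window": tuple(c.get("epoch_window", (0.3, 0.6)))})
                    for c in sim["coupling_spec"]
                ]
            if "event_fractions" in sim:
                sim["event_fractions"] = tuple(sim["event_fractions"])
            known = {f.name for f in dataclasses.fields(SimulationConfig)}
            unknown = set(sim) - known
            if unknown:
                raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
            self.simulation = SimulationConfig(**sim)
        if self.band not in CANONICAL_BANDS:
            raise ValueError(
                f"unknown band {self.band!r}; choose from {sorted(CANONICAL_BANDS)}"
            )
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {self.schema_version}")

    @property
    def band_def(self) -> BandDefinition:
        return CANONICAL_BANDS[self.band]

    # ------------------------------------------------------------- (de)serialise
    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return clean(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def read_trial_table(path: str | Path) -> TrialTable:
    """Load a per-trial CSV, computing totals on load (logged)."""
    table = TrialTable.from_csv(path)
    log.info(
        "loaded trial table %s: %d trials (%d correct, %d incorrect)",
        path,
        table.n_trials,
        table.n_correct,
        table.n_incorrect,
    )
    return table


def write_trial_table(table: TrialTable, path: str | Path) -> None:
    table.to_csv(path)


def information_flow_table(
    recordings: list[LfpRecording],
    table: TrialTable,
    band: BandDefinition,
    window: float = 0.5,
    step: float = 0.125,
    order: int | str = "bic",
    max_order: int = 20,
    n_position_bins: int = 10,
    directions: tuple[tuple[str, str], ...] = (("mPFC", "MD"), ("MD", "mPFC")),
    dtf_by_trial: dict[int, tuple[list, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Tidy per-trial IF table.

    One row per trial x direction x bin, with columns
    subject, trial, outcome, phase, direction, band, bin_type, bin, value.
    Rest trials are position-mapped like task trials (their event columns
    hold the same layout).
    """
    meta = table.data.set_index("trial")
    rows = []
    for rec in recordings:
        tid = rec.trial_id
        info = meta.loc[tid]
        if dtf_by_trial is not None and tid in dtf_by_trial:
            windows, centers = dtf_by_trial[tid]
        else:
            windows, centers = windowed_dtf(
                rec, window=window, step=step, order=order, max_order=max_order
            )
        for src, snk in directions:
            series = if_timecourse(
                windows, centers, src, snk, band, trial_id=tid, outcome=info["outcome"]
            )
            pos = map_to_position(
                series,
                (info["t_start"], info["t_turn"], info["t_reward"]),
                n_bins_per_segment=n_position_bins,
            )
            for s, bt in ((series, "time"), (pos, "position")):
                for b, v in zip(s.bins, s.values):
                    rows.append(
                        {
                            "subject": info["subject"],
                            "trial": tid,
                            "outcome": info["outcome"],
                            "phase": info["phase"],
                            "direction": s.direction,
                            "band": band.name,
                            "bin_type": bt,
                            "bin": b,
                            "value": v,
                        }
                    )
    return pd.DataFrame(rows)


def stats_report(
    if_table: pd.DataFrame,
    trials: TrialTable,
    band_name: str,
    segment: tuple[float, float] = (0.0, 1.0),
) -> str:
    """Human-readable statistical report over an IF table."""
    lines = [f"dtflow statistics report (band: {band_name})", "=" * 46]
    lines.append(
        f"trials: {trials.n_trials} total, {trials.n_correct} correct, "
        f"{trials.n_incorrect} incorrect"
    )
    tmean = (
        if_table[if_table.bin_type == "time"]
        .groupby(["trial", "direction", "outcome"], observed=True)["value"]
        .mean()
        .reset_index()
    )
    directions = sorted(tmean.direction.unique())
    for d in directions:
        sub = tmean[tmean.direction == d]
        cor = sub[sub.outcome == "correct"]["value"].to_numpy()
        inc = sub[sub.outcome == "incorrect"]["value"].to_numpy()
        if cor.size and inc.size:
            res = mann_whitney(cor, inc)
            lines.append(f"[{d}] correct vs incorrect: {res.summary()}")
    if len(directions) == 2:
        a = tmean[tmean.direction == directions[0]]["value"].to_numpy()
        b = tmean[tmean.direction == directions[1]]["value"].to_numpy()
        if a.size and b.size:
            res = mann_whitney(a, b)
            lines.append(
                f"direction contrast {directions[0]} vs {directions[1]}: {res.summary()}"
            )
    try:
        mc = movement_control(trials.subset(trials.data.outcome != "rest"), by="outcome")
        for k, res in mc.items():
            lines.append(f"movement control ({k}): {res.summary()}")
    except ValueError as exc:
        lines.append(f"movement control skipped: {exc}")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the full pipeline into *out_dir*; bit-identical under a fixed config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    config.to_yaml(out / "config.yaml")
    (out / "config.hash").write_text(chash + "\n")

    stage = "simulate"
    try:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        recordings, table, gt = simulate_trials(sim)
        dio.save_recordings(out / "signals.h5", recordings, config_hash=chash)
        write_trial_table(table, out / "trials.csv")
        log.info("simulated %d trials", len(recordings))

        stage = "preprocess"
        clean = [
            preprocess_recording(
                r, detrend_order=config.detrend_order, notch_quality=config.notch_quality
            )
            for r in recordings
        ]
        dio.save_recordings(out / "signals_clean.h5", clean, config_hash=chash)

        stage = "spectrogram"
        specs = {
            r.trial_id: multitaper_spectrogram(
                r,
                window=config.spectral_window,
                step=config.spectral_step,
                resolution=config.spectral_resolution,
            )
            for r in clean
        }
        dio.save_spectrograms(out / "spectrograms.h5", specs, config_hash=chash)

        stage = "dtf"
        dtf_by_trial = {
            r.trial_id: windowed_dtf(
                r,
                window=config.dtf_window,
                step=config.dtf_step,
                order=config.mvar_order,
                max_order=config.mvar_max_order,
            )
            for r in clean
        }
        dio.save_dtf_windows(
            out / "dtf.h5", dtf_by_trial, clean[0].channel_regions, config_hash=chash
        )

        stage = "infoflow"
        if_table = information_flow_table(
            clean,
            table,
            config.band_def,
            window=config.dtf_window,
            step=config.dtf_step,
            order=config.mvar_order,
            max_order=config.mvar_max_order,
            n_position_bins=config.n_position_bins,
            dtf_by_trial=dtf_by_trial,
        )
        if_table.to_csv(out / "results.csv", index=False)

        stage = "stats"
        report_dir = out / "report"
        report_dir.mkdir(exist_ok=True)
        (report_dir / "stats.txt").write_text(
            stats_report(if_table, table, config.band) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
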