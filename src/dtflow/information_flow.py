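"""Region-level directed information flow (IF).

IF from a source region to a sink region is the mean DTF over all
cross-region channel pairs:

    IF_src->snk(f) = 1 / (N_src * N_snk) * sum_{i in snk} sum_{j in src} gamma^2_ij(f)

Band aggregation (theta by default) averages over in-band frequencies, the
time course evaluates this per analysis window, and the position mapping
interpolates window times onto the track coordinate between the logged
events (start -> turn -> reward) under a uniform-speed assumption.  The peak
contrast dIF is the maximum over a segment minus the value at the segment
start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import THETA, BandDefinition
from .connectivity import DtfSpectrum

__all__ = [
    "InformationFlowSeries",
    "DeltaIf",
    "region_if",
    "band_if",
    "if_timecourse",
    "map_to_position",
    "delta_if",
]


@dataclass
class InformationFlowSeries:
    """Direction- and band-resolved IF per time (or position) bin."""

    direction: str
    band: BandDefinition
    values: np.ndarray
    bins: np.ndarray
    bin_type: str = "time"  # 'time' (seconds) or 'position' (track coordinate)
    trial_id: int | None = None
    outcome: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bins = np.asarray(self.bins, dtype=float)
        if self.values.shape != self.bins.shape:
            raise ValueError("values and bins must align")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < -1e-12) or np.any(finite > 1 + 1e-12):
            raise ValueError("IF values must lie in [0, 1]")
        if self.bin_type not in ("time", "position"):
            raise ValueError("bin_type must be 'time' or 'position'")


@dataclass
class DeltaIf:
    """Peak-minus-initial IF over a trial segment."""

    delta: float
    peak_location: float
    initial_location: float


def region_if(d: DtfSpectrum, source_region: str, sink_region: str) -> np.ndarray:
    """Per-frequency IF from *source_region* to *sink_region*.

    Mean of ``gamma_sq[f, sink_node, source_node]`` over all cross-region
    channel pairs; returns one value per grid frequency.
    """
    snk = d.region_channels(sink_region)
    src = d.region_channels(source_region)
    block = d.gamma_sq[:, snk[:, None], src[None, :]]
    return block.mean(axis=(1, 2))


def band_if(
    values: np.ndarray,
    frequency_grid: np.ndarray,
    band: BandDefinition = THETA,
) -> float:
    """Mean IF over the in-band frequencies of the grid."""
    freqs = np.asarray(frequency_grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.shape != freqs.shape:
        raise ValueError("values and frequency_grid must align")
    if band.low < freqs.min() or band.high > freqs.max():
        warnings.warn(
            f"band {band.name!r} ({band.low}-{band.high} Hz) extends beyond the "
            f"frequency grid ({freqs.min():g}-{freqs.max():g} Hz); clipping",
            stacklevel=2,
        )
    mask = (freqs >= band.low) & (freqs <= band.high)
    if not mask.any():
        raise ValueError(f"band {band.name!r} does not intersect the frequency grid")
    return float(values[mask].mean())


def if_timecourse(
    dtf_windows: list[DtfSpectrum],
    window_times: np.ndarray,
    source_region: str,
    sink_region: str,
    band: BandDefinition = THETA,
    trial_id: int | None = None,
    outcome: str | None = None,
) -> InformationFlowSeries:
    """Band IF per analysis window.

    ``window_times`` are the window centres in seconds (same grid as the DTF
    windows).
    """
    if len(dtf_windows) == 0:
        raise ValueError("need at least one DTF window")
    times = np.asarray(window_times, dtype=float)
    if times.size != len(dtf_windows):
        raise ValueError("one window time per DTF window required")
    vals = np.array(
        [
            band_if(region_if(d, source_region, sink_region), d.frequency_grid, band)
            for d in dtf_windows
        ]
    )
    return InformationFlowSeries(
        direction=f"{source_region}->{sink_region}",
        band=band,
        values=vals,
        bins=times,
        bin_type="time",
        trial_id=trial_id,
        outcome=outcome,
    )


def map_to_position(
    series: InformationFlowSeries,
    events: tuple[float, float, float],
    n_bins_per_segment: int = 10,
) -> InformationFlowSeries:
    """Map a time series onto the track coordinate and bin it.

    ``events`` are the trial-relative times of start, turn and reward.  The
    track coordinate runs linearly 0 -> 1 between start and turn and 1 -> 2
    between turn and reward (uniform speed within each leg).  Bins with no
    window centre are NaN.
    """
    if series.bin_type != "time":
        raise ValueError("series is already position-binned")
    t_start, t_turn, t_reward = events
    if any(v is None or not np.isfinite(v) for v in (t_start, t_turn, t_reward)):
        raise ValueError("position mapping requires finite event times")
    if not (t_start < t_turn < t_reward):
        raise ValueError(f"event times must be ordered, got {events}")
    t = series.bins
    pos = np.where(
        t <= t_turn,
        (t - t_start) / (t_turn - t_start),
        1.0 + (t - t_turn) / (t_reward - t_turn),
    )
    edges = np.linspace(0.0, 2.0, 2 * n_bins_per_segment + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    binned = np.full(centers.size, np.nan)
    idx = np.clip(np.digitize(pos, edges) - 1, 0, centers.size - 1)
    inside = (pos >= 0) & (pos <= 2)
    for b in range(centers.size):
        sel = inside & (idx == b)
        if sel.any():
            binned[b] = series.values[sel].mean()
    return InformationFlowSeries(
        direction=series.direction,
        band=series.band,
        values=binned,
        bins=centers,
        bin_type="position",
        trial_id=series.trial_id,
        outcome=series.outcome,
    )


def delta_if(series: InformationFlowSeries, segment: tuple[float, float]) -> DeltaIf:
    """Peak IF over ``segment`` minus the IF at the segment start.

    ``segment`` is a (start, stop) interval in the series' bin coordinate
    (e.g. track positions (0, 1) for the start-to-turn leg).
    """
    lo, hi = segment
    mask = (series.bins >= lo) & (series.bins <= hi) & np.isfinite(series.values)
    if not mask.any():
        raise ValueError(f"segment {segment} contains no finite IF bins")
    seg_bins = series.bins[mask]
    seg_vals = series.values[mask]
    peak_idx = int(np.argmax(seg_vals))
    return DeltaIf(
        delta=float(seg_vals[peak_idx] - seg_vals[0]),
        peak_location=float(seg_bins[peak_idx]),
        initial_location=float(seg_bins[0]),
    )
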