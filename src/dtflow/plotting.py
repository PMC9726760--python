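"""Matplotlib views of the pipeline outputs.

Thin helpers over the analysis objects: spectrogram images, information flow
as a function of frequency (correct vs incorrect style), and IF position
profiles with the turn landmark marked.  All functions accept an optional
``ax`` and return it, so they compose into figure grids.
"""

from __future__ import annotations

import numpy as np

from .containers import BandDefinition
from .spectral import Spectrogram

__all__ = ["plot_spectrogram", "plot_if_spectrum", "plot_if_position_profile"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_spectrogram(spec: Spectrogram, channel: int = 0, f_max: float = 40.0, ax=None):
    """Time-frequency power image for one channel (dB scale)."""
    ax = _get_ax(ax)
    keep = spec.frequency_grid <= f_max
    power = spec.power[channel][:, keep].T
    db = 10 * np.log10(np.maximum(power, np.finfo(float).tiny))
    mesh = ax.pcolormesh(
        spec.time_bin_centers, spec.frequency_grid[keep], db, shading="nearest"
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.figure.colorbar(mesh, ax=ax, label="power (dB)")
    return ax


def plot_if_spectrum(
    curves: dict[str, tuple[np.ndarray, np.ndarray]],
    band: BandDefinition | None = None,
    ax=None,
):
    """Information flow vs frequency, one line per labelled condition.

    ``curves`` maps a label (e.g. 'correct', 'incorrect') to a
    ``(frequency_grid, if_values)`` pair; ``band`` shades the band of
    interest.
    """
    ax = _get_ax(ax)
    for label, (freqs, values) in curves.items():
        ax.plot(freqs, values, label=label)
    if band is not None:
        ax.axvspan(band.low, band.high, alpha=0.15, label=band.name)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("information flow")
    ax.set_ylim(bottom=0)
    ax.legend()
    return ax


def plot_if_position_profile(
    profiles: dict[str, tuple[np.ndarray, np.ndarray]],
    turn_position: float = 1.0,
    ax=None,
):
    """Group-mean IF over track position; the turn landmark is dashed.

    ``profiles`` maps a label to a ``(position_bins, if_values)`` pair on the
    0 (start) -> 1 (turn) -> 2 (reward) coordinate.
    """
    ax = _get_ax(ax)
    for label, (bins, values) in profiles.items():
        ax.plot(bins, values, marker="o", label=label)
    ax.axvline(turn_position, linestyle="--", color="grey", label="turn")
    ax.set_xlabel("track position (start → turn → reward)")
    ax.set_ylabel("information flow")
    ax.legend()
    return ax
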