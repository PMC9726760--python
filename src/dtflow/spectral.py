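"""Multitaper time-frequency power estimation.

Sliding-window multitaper spectrograms with DPSS tapers: 500 ms windows moved
in 125 ms steps.  The native resolution of a 0.5 s window is 2 Hz, so windows
are zero-padded (default to 1 s) to evaluate the spectrum on a 1 Hz grid; the
finer grid is interpolated resolution, not added information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss

from .containers import BandDefinition, LfpRecording

__all__ = ["Spectrogram", "multitaper_spectrogram", "band_power"]


@dataclass
class Spectrogram:
    """Per-channel sliding-window power, ``power[channel, time_bin, freq_bin]``
    in signal-units^2/Hz."""

    power: np.ndarray
    time_bin_centers: np.ndarray
    frequency_grid: np.ndarray
    window_length: float
    step: float

    def __post_init__(self) -> None:
        if self.power.ndim != 3:
            raise ValueError("power must be (channels, time bins, frequency bins)")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def n_time_bins(self) -> int:
        return self.power.shape[1]


def multitaper_spectrogram(
    rec: LfpRecording,
    window: float = 0.5,
    step: float = 0.125,
    resolution: float = 1.0,
    nw: float = 2.0,
    n_tapers: int = 3,
    f_max: float = 120.0,
) -> Spectrogram:
    """Sliding-window multitaper power spectrum.

    Parameters
    ----------
    window, step
        Window length and hop in seconds.
    resolution
        Frequency-grid spacing in Hz, reached by zero-padding each window.
    nw, n_tapers
        DPSS time-bandwidth product and taper count.
    f_max
        Upper edge of the returned grid (clipped to Nyquist).
    """
    fs = rec.sampling_rate
    win_n = int(round(window * fs))
    step_n = int(round(step * fs))
    if step_n <= 0:
        raise ValueError("step must be positive")
    if win_n > rec.n_samples:
        raise ValueError(
            f"window of {window} s ({win_n} samples) longer than the "
            f"{rec.n_samples}-sample recording"
        )
    nfft = max(win_n, int(round(fs / resolution)))
    tapers = dpss(win_n, NW=nw, Kmax=n_tapers, norm=2)  # unit-energy tapers

    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    keep = freqs <= min(f_max, fs / 2)
    freqs = freqs[keep]

    n_bins = (rec.n_samples - win_n) // step_n + 1
    power = np.empty((rec.n_channels, n_bins, freqs.size))
    centers = (np.arange(n_bins) * step_n + win_n / 2) / fs
    for b in range(n_bins):
        seg = rec.samples[:, b * step_n : b * step_n + win_n]
        seg = seg - seg.mean(axis=1, keepdims=True)
        # (channels, tapers, samples) -> rFFT over samples
        tapered = seg[:, None, :] * tapers[None, :, :]
        spec = np.fft.rfft(tapered, n=nfft, axis=2)[:, :, keep]
        pxx = (np.abs(spec) ** 2).mean(axis=1) / fs
        # one-sided density: double all bins except DC and (if present) Nyquist
        scale = np.full(freqs.size, 2.0)
        scale[freqs == 0] = 1.0
        scale[freqs == fs / 2] = 1.0
        power[:, b, :] = pxx * scale
    return Spectrogram(
        power=power,
        time_bin_centers=centers,
        frequency_grid=freqs,
        window_length=window,
        step=step,
    )


def band_power(spec: Spectrogram, band: BandDefinition) -> np.ndarray:
    """Mean in-band power per channel and time bin, ``(channels, time_bins)``."""
    mask = (spec.frequency_grid >= band.low) & (spec.frequency_grid <= band.high)
    if not mask.any():
        raise ValueError(
            f"band {band.name!r} ({band.low}-{band.high} Hz) does not intersect "
            "the spectrogram frequency grid"
        )
    return spec.power[:, :, mask].mean(axis=2)
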