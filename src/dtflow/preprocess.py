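"""Signal conditioning for trial LFPs.

The pipeline mirrors standard LFP practice: polynomial baseline-drift removal,
a 50 Hz powerline notch, and Chebyshev band-pass extraction of sub-bands.  All
IIR filters are applied forward-backward (zero-phase) so that event-locked
timing is preserved; the fixed stage order is detrend -> notch -> band-pass,
since drift is removed before any filtering assumption is made.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import BandDefinition, LfpRecording

__all__ = [
    "detrend_polynomial",
    "notch_50hz",
    "bandpass",
    "preprocess_recording",
    "notch_attenuation_db",
    "bandpass_attenuation_db",
]

#: Chebyshev type-I design used for all band-pass stages.  Ripple is kept
#: small because forward-backward application doubles it in dB and squares
#: the in-band power loss of repeated passes.
CHEBY_ORDER = 4
CHEBY_RIPPLE_DB = 0.1


def detrend_polynomial(rec: LfpRecording, order: int = 2) -> LfpRecording:
    """Subtract a least-squares polynomial of *order* from every channel.

    Removes slow baseline drift; order 2 is low enough not to attenuate
    theta-band content over second-scale trials.
    """
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    if order + 1 >= rec.n_samples:
        raise ValueError(
            f"polynomial order {order} too high for {rec.n_samples}-sample trial"
        )
    t = np.linspace(-1.0, 1.0, rec.n_samples)  # scaled abscissa for conditioning
    # one Vandermonde solve for all channels
    coeffs = np.polynomial.polynomial.polyfit(t, rec.samples.T, deg=order)
    fitted = np.polynomial.polynomial.polyval(t, coeffs)
    return rec.with_samples(rec.samples - fitted)


def notch_50hz(rec: LfpRecording, quality: float = 30.0, freq: float = 50.0) -> LfpRecording:
    """Remove powerline contamination with a zero-phase IIR notch at *freq*."""
    if rec.sampling_rate <= 2 * freq:
        raise ValueError(f"sampling rate {rec.sampling_rate} Hz too low for {freq} Hz notch")
    b, a = signal.iirnotch(freq, quality, fs=rec.sampling_rate)
    filtered = signal.filtfilt(b, a, rec.samples, axis=1)
    return rec.with_samples(filtered)


def _cheby_sos(band: BandDefinition, sampling_rate: float) -> np.ndarray:
    band.validate_for_rate(sampling_rate)
    return signal.cheby1(
        CHEBY_ORDER,
        CHEBY_RIPPLE_DB,
        [band.low, band.high],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )


def bandpass(rec: LfpRecording, band: BandDefinition) -> LfpRecording:
    """Zero-phase Chebyshev type-I band-pass to the given sub-band."""
    sos = _cheby_sos(band, rec.sampling_rate)
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return rec.with_samples(filtered)


def preprocess_recording(
    rec: LfpRecording,
    detrend_order: int = 2,
    notch_quality: float = 30.0,
    band: BandDefinition | None = None,
) -> LfpRecording:
    """Full conditioning chain: detrend -> 50 Hz notch -> optional band-pass."""
    out = detrend_polynomial(rec, order=detrend_order)
    out = notch_50hz(out, quality=notch_quality)
    if band is not None:
        out = bandpass(out, band)
    out.require_finite()
    return out


# ------------------------------------------------------------------ filter QC
def notch_attenuation_db(
    freq_eval: float, sampling_rate: float = 1000.0, quality: float = 30.0, freq: float = 50.0
) -> float:
    """Attenuation (positive dB) of the zero-phase notch at *freq_eval*."""
    b, a = signal.iirnotch(freq, quality, fs=sampling_rate)
    _, h = signal.freqz(b, a, worN=[freq_eval], fs=sampling_rate)
    mag = np.abs(h[0]) ** 2  # forward-backward doubles the dB attenuation
    return float(-20 * np.log10(max(mag, 1e-300)))


def bandpass_attenuation_db(
    freq_eval: float, band: BandDefinition, sampling_rate: float = 1000.0
) -> float:
    """Attenuation (positive dB) of the zero-phase Chebyshev band-pass."""
    sos = _cheby_sos(band, sampling_rate)
    _, h = signal.sosfreqz(sos, worN=[freq_eval], fs=sampling_rate)
    mag = np.abs(h[0]) ** 2
    return float(-20 * np.log10(max(mag, 1e-300)))
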