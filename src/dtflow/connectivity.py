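"""Frequency-domain directed connectivity: transfer function and DTF.

Given MVAR coefficients A_1..A_p, the coefficient polynomial on the frequency
grid is

    A(f) = sum_{i=0..p} A(i) exp(-j 2 pi f i dt),   A(0) = -I,  A(i) = A_i,

and the transfer function is its matrix inverse, H(f) = A(f)^-1.  The directed
transfer function normalises the squared transfer magnitudes over all sources
feeding each sink channel i:

    gamma^2_ij(f) = |H_ij(f)|^2 / sum_m |H_im(f)|^2

so each sink row of gamma^2 sums to one at every frequency, and gamma^2_ij
quantifies the directed influence of channel j on channel i at frequency f.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mvar import MvarProcess

__all__ = [
    "TransferFunction",
    "DtfSpectrum",
    "NetworkDtf",
    "default_frequency_grid",
    "transfer_function",
    "dtf",
    "network_dtf",
]


def default_frequency_grid() -> np.ndarray:
    """1-100 Hz at 1 Hz steps; 0 Hz excluded (detrending removes it)."""
    return np.arange(1.0, 101.0)


@dataclass
class TransferFunction:
    """Complex transfer matrices H(f) on a frequency grid.

    ``h`` has shape ``(n_freqs, N, N)``; ``h[k, i, j]`` maps innovation j to
    signal i at ``frequency_grid[k]``.
    """

    h: np.ndarray
    frequency_grid: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=complex)
        self.frequency_grid = np.asarray(self.frequency_grid, dtype=float)
        if self.h.ndim != 3 or self.h.shape[1] != self.h.shape[2]:
            raise ValueError("h must have shape (n_freqs, N, N)")
        if self.h.shape[0] != self.frequency_grid.size:
            raise ValueError("frequency grid length mismatch")
        if not np.all(np.isfinite(self.h)):
            raise ValueError("transfer function contains non-finite entries")

    @property
    def n_channels(self) -> int:
        return self.h.shape[1]


@dataclass
class DtfSpectrum:
    """Normalised DTF gamma^2_ij(f); ``gamma_sq[k, i, j]`` is source j -> sink i."""

    gamma_sq: np.ndarray
    frequency_grid: np.ndarray
    node_regions: list[str] | None = None

    def __post_init__(self) -> None:
        self.gamma_sq = np.asarray(self.gamma_sq, dtype=float)
        self.frequency_grid = np.asarray(self.frequency_grid, dtype=float)
        g = self.gamma_sq
        if g.ndim != 3 or g.shape[1] != g.shape[2]:
            raise ValueError("gamma_sq must have shape (n_freqs, N, N)")
        if np.any(g < -1e-12) or np.any(g > 1 + 1e-12):
            raise ValueError("gamma_sq entries must lie in [0, 1]")
        rows = g.sum(axis=2)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("each sink row of gamma_sq must sum to 1 at every frequency")
        if self.node_regions is not None and len(self.node_regions) != g.shape[1]:
            raise ValueError("node_regions length mismatch")

    @property
    def n_channels(self) -> int:
        return self.gamma_sq.shape[1]

    def region_channels(self, region: str) -> np.ndarray:
        if self.node_regions is None:
            raise ValueError("DtfSpectrum carries no region labels")
        idx = np.flatnonzero(np.asarray(self.node_regions) == region)
        if idx.size == 0:
            raise KeyError(
                f"no nodes labelled {region!r}; have {sorted(set(self.node_regions))}"
            )
        return idx


@dataclass
class NetworkDtf:
    """Mean off-diagonal DTF over a node set, per frequency."""

    values: np.ndarray
    frequency_grid: np.ndarray
    nodes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("network DTF values must lie in [0, 1]")


def transfer_function(
    model: MvarProcess | np.ndarray,
    frequency_grid: np.ndarray | None = None,
    delta_t: float | None = None,
) -> TransferFunction:
    """H(f) = A(f)^-1 for an MVAR system on a frequency grid.

    ``model`` is an :class:`~dtflow.mvar.MvarProcess` (or fitted results), or a
    raw ``(p, N, N)`` coefficient array with ``delta_t`` given explicitly.
    """
    if isinstance(model, MvarProcess):
        coefs, dt = model.coefs, model.delta_t
    else:
        coefs = np.asarray(model, dtype=float)
        if delta_t is None:
            raise ValueError("delta_t required when passing raw coefficients")
        dt = float(delta_t)
    if frequency_grid is None:
        frequency_grid = default_frequency_grid()
    freqs = np.asarray(frequency_grid, dtype=float)
    p = coefs.shape[0]
    n = coefs.shape[1]
    if n == 0:
        raise ValueError("coefficient array has zero channels")
    lags = np.arange(0, p + 1)
    # phase[k, i] = exp(-j 2 pi f_k * i * dt)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) * dt)
    a_mats = np.concatenate([-np.eye(n)[None], coefs])  # A(0) = -I
    a_f = np.tensordot(phase, a_mats, axes=(1, 0))
    h = np.empty_like(a_f)
    for k in range(freqs.size):
        try:
            h[k] = np.linalg.inv(a_f[k])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"A(f) singular at f = {freqs[k]:g} Hz"
            ) from exc
    return TransferFunction(h=h, frequency_grid=freqs)


def dtf(tf: TransferFunction, node_regions: Sequence[str] | None = None) -> DtfSpectrum:
    """Sink-normalised DTF from a transfer function."""
    mag_sq = np.abs(tf.h) ** 2
    denom = mag_sq.sum(axis=2, keepdims=True)
    if np.any(denom == 0):
        raise ArithmeticError("all-zero sink row in |H|^2; transfer function invalid")
    gamma = mag_sq / denom
    return DtfSpectrum(
        gamma_sq=gamma,
        frequency_grid=tf.frequency_grid,
        node_regions=list(node_regions) if node_regions is not None else None,
    )


def windowed_dtf(
    rec,
    window: float = 0.5,
    step: float = 0.125,
    order: int | str = "bic",
    max_order: int = 20,
    frequency_grid: np.ndarray | None = None,
) -> tuple[list[DtfSpectrum], np.ndarray]:
    """Per-trial sliding-window DTF on the same window/step grid as the
    spectrogram.  Returns the DTF of each window and the window centres (s).
    """
    from .mvar import Mvar

    win_n = int(round(window * rec.sampling_rate))
    step_n = int(round(step * rec.sampling_rate))
    if win_n > rec.n_samples:
        raise ValueError("window longer than recording")
    n_bins = (rec.n_samples - win_n) // step_n + 1
    out: list[DtfSpectrum] = []
    centers = np.empty(n_bins)
    for b in range(n_bins):
        seg = rec.samples[:, b * step_n : b * step_n + win_n]
        model = Mvar(seg.T, delta_t=1.0 / rec.sampling_rate, node_regions=rec.channel_regions)
        res = model.fit(order=order, max_order=max_order)
        out.append(res.dtf(frequency_grid))
        centers[b] = (b * step_n + win_n / 2) / rec.sampling_rate
    return out, centers


def network_dtf(d: DtfSpectrum, nodes: Sequence[int] | None = None) -> NetworkDtf:
    """Mean off-diagonal gamma^2 over node set G, per frequency."""
    if nodes is None:
        nodes = list(range(d.n_channels))
    nodes = list(nodes)
    if len(nodes) < 2:
        raise ValueError("network DTF needs at least 2 nodes")
    sub = d.gamma_sq[:, np.ix_(nodes, nodes)[0], np.ix_(nodes, nodes)[1]]
    n = len(nodes)
    off_sum = sub.sum(axis=(1, 2)) - np.trace(sub, axis1=1, axis2=2)
    return NetworkDtf(
        values=off_sum / (n * (n - 1)),
        frequency_grid=d.frequency_grid,
        nodes=nodes,
    )
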