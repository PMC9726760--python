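"""Multivariate autoregressive (MVAR) modelling of multichannel LFP windows.

The model is

    X(t) = sum_{n=1..p} A_n X(t-n) + E(t)

with ``X(t)`` the N-channel signal vector, ``A_n`` the N x N lag-n coefficient
matrices and ``E(t)`` zero-mean white innovations with covariance Sigma.  The
lag order p is either given or selected by the Bayesian information criterion.

Organisation follows the familiar model/results split: :class:`Mvar` holds the
data and produces an :class:`MvarResults` from :meth:`Mvar.fit`;
:class:`MvarProcess` is the shared known-coefficient object (ground-truth
generators use it directly, fitted results inherit from it) exposing
stability diagnostics, the spectral transfer function, the directed transfer
function and simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import LfpRecording

__all__ = ["MvarProcess", "Mvar", "MvarResults", "fit_mvar"]


class MvarProcess:
    """An MVAR system with known coefficients.

    Parameters
    ----------
    coefs
        Array of shape ``(p, N, N)``; ``coefs[n-1]`` is A_n.
    noise_cov
        Innovation covariance Sigma, ``(N, N)``, symmetric PSD.
    delta_t
        Sampling interval in seconds (1/sampling_rate).
    node_regions
        Optional region label per channel, forwarded to DTF spectra.
    """

    def __init__(
        self,
        coefs: np.ndarray,
        noise_cov: np.ndarray | None = None,
        delta_t: float = 1e-3,
        node_regions: Sequence[str] | None = None,
    ) -> None:
        coefs = np.asarray(coefs, dtype=float)
        if coefs.ndim != 3 or coefs.shape[1] != coefs.shape[2]:
            raise ValueError("coefs must have shape (p, N, N)")
        self.coefs = coefs
        self.n_channels = coefs.shape[1]
        self.order = coefs.shape[0]
        if noise_cov is None:
            noise_cov = np.eye(self.n_channels)
        noise_cov = np.asarray(noise_cov, dtype=float)
        if noise_cov.shape != (self.n_channels, self.n_channels):
            raise ValueError("noise_cov shape mismatch")
        if not np.allclose(noise_cov, noise_cov.T, atol=1e-10):
            raise ValueError("noise_cov must be symmetric")
        if np.any(np.linalg.eigvalsh((noise_cov + noise_cov.T) / 2) < -1e-10):
            raise ValueError("noise_cov must be positive semi-definite")
        self.noise_cov = noise_cov
        self.delta_t = float(delta_t)
        self.node_regions = list(node_regions) if node_regions is not None else None

    # ------------------------------------------------------------ stability
    def companion_matrix(self) -> np.ndarray:
        """Companion form of the lag polynomial, ``(N*p, N*p)``."""
        p, n = self.order, self.n_channels
        if p == 0:
            return np.zeros((0, 0))
        top = self.coefs.transpose(1, 0, 2).reshape(n, n * p)
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = top
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        comp = self.companion_matrix()
        if comp.size == 0:
            return 0.0
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0

    # ---------------------------------------------------------- frequency
    def transfer_function(self, frequency_grid: np.ndarray | None = None):
        """Spectral transfer function H(f) = A(f)^-1 of this system."""
        from .connectivity import transfer_function

        return transfer_function(self, frequency_grid)

    def dtf(self, frequency_grid: np.ndarray | None = None):
        """Sink-normalised directed transfer function gamma^2(f)."""
        from .connectivity import dtf

        return dtf(self.transfer_function(frequency_grid), node_regions=self.node_regions)

    # ---------------------------------------------------------- simulation
    def simulate(
        self,
        n_samples: int,
        rng: np.random.Generator,
        burn_in: int = 500,
        initial_state: np.ndarray | None = None,
        noise_scale: float = 1.0,
    ) -> np.ndarray:
        """Draw one realisation, returned as ``(N, n_samples)``.

        ``initial_state`` is a ``(p, N)`` array of the immediately preceding
        samples (most recent last); when given, ``burn_in`` is ignored so that
        piecewise-stationary simulations can hand the state across segments.
        """
        p, n = self.order, self.n_channels
        if initial_state is not None:
            hist = np.array(initial_state, dtype=float)
            if hist.shape != (p, n):
                raise ValueError(f"initial_state must have shape {(p, n)}")
            burn_in = 0
        else:
            hist = np.zeros((p, n))
        total = burn_in + n_samples
        if noise_scale == 0.0:
            innov = np.zeros((total, n))
        else:
            chol = np.linalg.cholesky(
                self.noise_cov + 1e-15 * np.eye(n)
            )
            innov = rng.standard_normal((total, n)) @ (noise_scale * chol).T
        out = np.empty((total, n))
        buf = np.concatenate([hist, np.zeros((total, n))]) if p else np.zeros((total, n))
        for t in range(total):
            x = innov[t].copy()
            for lag in range(1, p + 1):
                x += self.coefs[lag - 1] @ buf[p + t - lag]
            buf[p + t] = x
            out[t] = x
        return out[burn_in:].T


class Mvar:
    """MVAR model specification bound to one data window.

    Parameters
    ----------
    endog
        ``(n_samples, N)`` array, observations in rows.  Use
        :meth:`from_recording` for channel-major :class:`LfpRecording` data.
    delta_t
        Sampling interval in seconds.
    node_regions
        Optional per-channel region labels, carried into results.
    """

    def __init__(
        self,
        endog: np.ndarray,
        delta_t: float = 1e-3,
        node_regions: Sequence[str] | None = None,
    ) -> None:
        endog = np.asarray(endog, dtype=float)
        if endog.ndim != 2:
            raise ValueError("endog must be 2-D (n_samples, n_channels)")
        if not np.all(np.isfinite(endog)):
            raise ValueError("endog contains non-finite values")
        self.endog = endog
        self.delta_t = float(delta_t)
        self.node_regions = list(node_regions) if node_regions is not None else None
        self.n_obs, self.n_channels = endog.shape

    @classmethod
    def from_recording(
        cls,
        rec: LfpRecording,
        window: tuple[float, float] | None = None,
    ) -> "Mvar":
        """Build the model from a recording, optionally restricted to a
        ``(t_start, t_stop)`` window in seconds."""
        x = rec.samples
        if window is not None:
            t0, t1 = window
            i0 = int(round(t0 * rec.sampling_rate))
            i1 = int(round(t1 * rec.sampling_rate))
            if not (0 <= i0 < i1 <= rec.n_samples):
                raise ValueError(f"window {window} outside recording of {rec.duration} s")
            x = x[:, i0:i1]
        return cls(x.T, delta_t=1.0 / rec.sampling_rate, node_regions=rec.channel_regions)

    # -------------------------------------------------------------- fitting
    def _check_design(self) -> None:
        stds = self.endog.std(axis=0)
        constant = np.flatnonzero(stds == 0)
        if constant.size:
            names = (
                [self.node_regions[i] for i in constant]
                if self.node_regions
                else constant.tolist()
            )
            raise ValueError(
                f"constant channels make the regressor matrix rank-deficient: {names}"
            )

    def _ls_fit(self, order: int, offset: int | None = None):
        """Least-squares fit at a fixed order.

        ``offset`` discards that many leading samples from the response so
        that BIC comparisons across orders share the same effective sample.
        Returns (coefs, sigma_ml, n_eff).
        """
        n, k = self.n_obs, self.n_channels
        p = order
        off = p if offset is None else offset
        if off < p:
            raise ValueError("offset must be >= order")
        n_eff = n - off
        if p > 0 and n_eff < 10 * k * p:
            raise ValueError(
                f"window too short: {n} samples for order {p} with {k} channels "
                f"(need >= {off + 10 * k * p})"
            )
        if n_eff < max(1, k):
            raise ValueError("window too short")
        y = self.endog[off:]
        if p == 0:
            resid = y
            coefs = np.zeros((0, k, k))
        else:
            # regressors: [X(t-1), ..., X(t-p)] stacked columnwise
            z = np.concatenate(
                [self.endog[off - lag : n - lag] for lag in range(1, p + 1)], axis=1
            )
            rank = np.linalg.matrix_rank(z)
            if rank < z.shape[1]:
                raise ValueError(
                    f"rank-deficient regressor matrix (rank {rank} < {z.shape[1]}); "
                    "check for duplicated or constant channels"
                )
            b, *_ = np.linalg.lstsq(z, y, rcond=None)
            coefs = b.reshape(p, k, k).transpose(0, 2, 1)
            resid = y - z @ b
        sigma_ml = resid.T @ resid / n_eff
        return coefs, sigma_ml, n_eff

    def _bic(self, sigma_ml: np.ndarray, order: int, n_eff: int) -> float:
        sign, logdet = np.linalg.slogdet(sigma_ml)
        if sign <= 0:
            return np.inf
        return logdet + np.log(n_eff) * order * self.n_channels**2 / n_eff

    def select_order(self, max_order: int = 20) -> dict[int, float]:
        """BIC per candidate order 1..max_order on a common sample."""
        self._check_design()
        table: dict[int, float] = {}
        for p in range(1, max_order + 1):
            try:
                _, sigma, n_eff = self._ls_fit(p, offset=max_order)
            except ValueError:
                break
            table[p] = self._bic(sigma, p, n_eff)
        if not table:
            raise ValueError(
                f"window of {self.n_obs} samples too short for any order up to {max_order}"
            )
        return table

    def fit(self, order: int | str = "bic", max_order: int = 20) -> "MvarResults":
        """Estimate coefficients and innovation covariance.

        ``order`` is a fixed lag count, or ``"bic"`` to minimise the Bayesian
        information criterion over 1..max_order (ties broken by smaller p).
        """
        self._check_design()
        if order == "bic":
            table = self.select_order(max_order)
            best = min(table, key=lambda p: (table[p], p))
            order = best
        elif not isinstance(order, (int, np.integer)) or order < 1:
            raise ValueError(f"order must be a positive integer or 'bic', got {order!r}")
        coefs, sigma_ml, n_eff = self._ls_fit(int(order))
        # small-sample bias correction for the reported covariance
        dof = max(n_eff - self.n_channels * int(order), 1)
        sigma = sigma_ml * n_eff / dof
        sigma = (sigma + sigma.T) / 2
        return MvarResults(
            model=self,
            coefs=coefs,
            noise_cov=sigma,
            n_samples_used=n_eff,
            bic=self._bic(sigma_ml, int(order), n_eff),
        )


class MvarResults(MvarProcess):
    """Fitted MVAR model: coefficients, innovation covariance, diagnostics."""

    def __init__(
        self,
        model: Mvar,
        coefs: np.ndarray,
        noise_cov: np.ndarray,
        n_samples_used: int,
        bic: float,
    ) -> None:
        super().__init__(
            coefs,
            noise_cov,
            delta_t=model.delta_t,
            node_regions=model.node_regions,
        )
        self.model = model
        self.n_samples_used = int(n_samples_used)
        self.bic = float(bic)

    def summary(self) -> str:
        lines = [
            "MVAR model results",
            "==================",
            f"channels:        {self.n_channels}",
            f"order p:         {self.order}",
            f"samples used:    {self.n_samples_used}",
            f"delta_t:         {self.delta_t:g} s",
            f"BIC:             {self.bic:.4f}",
            f"spectral radius: {self.spectral_radius():.4f} "
            f"({'stable' if self.is_stable else 'UNSTABLE'})",
        ]
        if self.node_regions:
            lines.append(f"regions:         {self.node_regions}")
        for n in range(self.order):
            lines.append(f"A_{n + 1} =")
            lines.append(np.array2string(self.coefs[n], precision=4))
        lines.append("noise covariance =")
        lines.append(np.array2string(self.noise_cov, precision=4))
        return "\n".join(lines)


def fit_mvar(
    rec: LfpRecording,
    window: tuple[float, float] | None = None,
    order: int | str = "bic",
    max_order: int = 20,
) -> MvarResults:
    """Fit an MVAR model to (a window of) a recording.

    Convenience wrapper around ``Mvar.from_recording(...).fit(...)``.
    """
    return Mvar.from_recording(rec, window=window).fit(order=order, max_order=max_order)
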