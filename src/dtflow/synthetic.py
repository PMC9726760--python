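"""Ground-truth two-region LFP simulator.

Generates trial-structured multichannel signals from a stable MVAR system —
the model class the downstream estimator assumes — so that directed coupling,
its frequency band, its epoch timing and its outcome dependence are all known
exactly and every pipeline stage can be validated against them.

Each channel is a stochastically driven damped resonator (an AR(2) pair on the
diagonal) tuned to the oscillation frequency, which concentrates power in the
theta range.  Cross-region coupling enters as lag-1 off-diagonal coefficients
from source-region channels to sink-region channels; because the directed
transfer from source to sink inherits the source pole, the induced DTF peak
sits at the source channels' resonance frequency.  Coupling can be boosted
within a within-trial epoch window (piecewise-stationary simulation with state
hand-over), scaled up on correct trials, and scaled down or off for rest
periods.  Measurement realism: slow polynomial baseline drift, 50 Hz line
contamination, and broadband innovation noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TRIAL_TABLE_COLUMNS, LfpRecording, TrialTable
from .mvar import MvarProcess

__all__ = ["CouplingSpec", "SimulationConfig", "GroundTruth", "build_generator", "simulate_trials"]

MPFC = "mPFC"
MD = "MD"


@dataclass(frozen=True)
class CouplingSpec:
    """One directed cross-region coupling.

    ``gain`` is the total lag-1 influence of the source region on each sink
    channel (split evenly across source channels); ``band_center`` sets the
    resonance of the source channels involved, hence the frequency at which
    the directed transfer peaks; ``epoch_window`` is the fraction-of-trial
    interval in which correct trials receive the outcome boost.
    """

    source: str
    sink: str
    gain: float
    band_center: float = 8.0
    epoch_window: tuple[float, float] = (0.3, 0.6)

    def __post_init__(self) -> None:
        if self.source == self.sink:
            raise ValueError("coupling must be cross-region")
        w0, w1 = self.epoch_window
        if not (0.0 <= w0 < w1 <= 1.0):
            raise ValueError(f"epoch_window must be a fraction interval, got {self.epoch_window}")


def _default_couplings() -> list[CouplingSpec]:
    return [CouplingSpec(source=MPFC, sink=MD, gain=0.3)]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the recorded conditions: 1 kHz sampling, theta-band
    (8 Hz) oscillations, four channels per region, directed mPFC->MD theta
    coupling boosted in the pre-turn epoch of correct trials, and per-subject
    trial counts on the scale of the study's per-animal sessions.

    Amplitudes are expressed relative to the oscillation: ``oscillation_sd``
    is the stationary RMS of the base-condition oscillatory process in signal
    units, and ``noise_sd``, ``drift_amplitude`` and ``line_amplitude`` are
    additive measurement components on the same scale.  Coupling ``gain`` is
    dimensionless: the standard deviation of the summed cross-region drive
    into each sink channel in units of that channel's intrinsic innovation.
    """

    n_mpfc_channels: int = 4
    n_md_channels: int = 4
    sampling_rate: float = 1000.0
    trial_duration: float = 2.0
    true_order: int = 2
    coupling_spec: list[CouplingSpec] = field(default_factory=_default_couplings)
    oscillation_freq: float = 8.0
    oscillation_sd: float = 1.0
    noise_sd: float = 0.02
    drift_amplitude: float = 1.0
    line_amplitude: float = 0.3
    n_correct: int = 37
    n_incorrect: int = 15
    outcome_effect: float = 3.0
    seed: int = 0
    # extensions beyond the task trials
    n_rest: int = 0
    rest_coupling_scale: float = 0.0
    phase: str = "choice"
    subject_id: int = 1
    event_fractions: tuple[float, float, float] = (0.0, 0.6, 1.0)
    pole_radius: float = 0.99
    duration_jitter: float = 0.15
    speed_mean: float = 0.15
    speed_sd: float = 0.02

    def validate(self) -> None:
        if min(self.n_mpfc_channels, self.n_md_channels) < 1:
            raise ValueError("each region needs at least one channel")
        if self.n_correct < 0 or self.n_incorrect < 0 or self.n_rest < 0:
            raise ValueError("trial counts must be non-negative")
        if self.true_order < 2:
            raise ValueError("true_order must be >= 2 to support oscillatory dynamics")
        edges = [self.oscillation_freq] + [c.band_center for c in self.coupling_spec]
        if self.sampling_rate <= 2 * max(edges):
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz must exceed twice the highest "
                f"band edge ({max(edges)} Hz)"
            )
        if not (0 < self.pole_radius < 1):
            raise ValueError("pole_radius must lie in (0, 1)")
        f0, f1, f2 = self.event_fractions
        if not (f0 == 0.0 and f0 < f1 < f2 == 1.0):
            raise ValueError("event_fractions must be (0, turn, 1) with 0 < turn < 1")

    @property
    def n_channels(self) -> int:
        return self.n_mpfc_channels + self.n_md_channels

    @property
    def regions(self) -> list[str]:
        return [MPFC] * self.n_mpfc_channels + [MD] * self.n_md_channels


@dataclass
class GroundTruth:
    """True generating system per trial condition, plus its analytic DTF.

    ``coefs`` maps condition name ('base', 'boosted', 'rest') to the
    ``(p, N, N)`` coefficient stack; 'boosted' is the correct-trial epoch
    system with outcome-scaled coupling.
    """

    coefs: dict[str, np.ndarray]
    regions: list[str]
    delta_t: float
    innovation_sd: float
    event_fractions: tuple[float, float, float]
    coupling_spec: list[CouplingSpec]

    def process(self, condition: str = "base") -> MvarProcess:
        sigma = self.innovation_sd**2 * np.eye(len(self.regions))
        return MvarProcess(
            self.coefs[condition],
            noise_cov=sigma,
            delta_t=self.delta_t,
            node_regions=self.regions,
        )

    def analytic_dtf(self, condition: str = "base", frequency_grid: np.ndarray | None = None):
        """DTF of the true coefficients, via the same connectivity formulas
        applied to estimated models."""
        return self.process(condition).dtf(frequency_grid)


def _region_indices(regions: list[str], name: str) -> np.ndarray:
    idx = np.flatnonzero(np.asarray(regions) == name)
    if idx.size == 0:
        raise ValueError(f"unknown region {name!r} in coupling spec")
    return idx


def _coefficients(config: SimulationConfig, gain_scale: dict[str, float] | float) -> np.ndarray:
    """Assemble (p, N, N) coefficients; gain_scale multiplies coupling gains
    (a mapping keyed by 'source->sink' or one scalar for all)."""
    n, p = config.n_channels, config.true_order
    regions = config.regions
    coefs = np.zeros((p, n, n))
    dt = 1.0 / config.sampling_rate
    r = config.pole_radius

    resonance = np.full(n, config.oscillation_freq)
    for c in config.coupling_spec:
        src = _region_indices(regions, c.source)
        if c.band_center != config.oscillation_freq:
            if not np.allclose(resonance[src], config.oscillation_freq) and not np.allclose(
                resonance[src], c.band_center
            ):
                warnings.warn(
                    f"conflicting band_center values for {c.source} channels; "
                    f"using {c.band_center} Hz",
                    stacklevel=3,
                )
            resonance[src] = c.band_center
    for ch in range(n):
        w = 2 * np.pi * resonance[ch] * dt
        coefs[0, ch, ch] = 2 * r * np.cos(w)
        coefs[1, ch, ch] = -(r**2)

    # stationary SD of a unit-innovation AR(2) resonator per distinct resonance,
    # used to express coupling gains relative to the sink's intrinsic drive
    sd_cache: dict[float, float] = {}

    def resonator_sd(freq: float) -> float:
        if freq not in sd_cache:
            w = 2 * np.pi * freq * dt
            a1, a2 = 2 * r * np.cos(w), -(r**2)
            comp = np.array([[a1, a2], [1.0, 0.0]])
            from scipy import linalg

            q = np.array([[1.0, 0.0], [0.0, 0.0]])
            sd_cache[freq] = float(np.sqrt(linalg.solve_discrete_lyapunov(comp, q)[0, 0]))
        return sd_cache[freq]

    for c in config.coupling_spec:
        src = _region_indices(regions, c.source)
        snk = _region_indices(regions, c.sink)
        scale = (
            gain_scale
            if np.isscalar(gain_scale)
            else gain_scale.get(f"{c.source}->{c.sink}", 1.0)
        )
        # gain is dimensionless: the SD of the summed cross-region drive into
        # each sink channel, in units of the sink's own innovation SD
        g = c.gain * float(scale) / (src.size * resonator_sd(float(resonance[src[0]])))
        for i in snk:
            coefs[0, i, src] += g
    return coefs


def _base_process_rms(coefs: np.ndarray) -> float:
    """Mean stationary channel SD of the MVAR system under unit innovations,
    from the discrete Lyapunov equation on the companion form."""
    from scipy import linalg

    p, n = coefs.shape[0], coefs.shape[1]
    proc = MvarProcess(coefs)
    comp = proc.companion_matrix()
    q = np.zeros((n * p, n * p))
    q[:n, :n] = np.eye(n)
    cov = linalg.solve_discrete_lyapunov(comp, q)
    return float(np.sqrt(np.mean(np.diag(cov)[:n])))


def build_generator(config: SimulationConfig) -> GroundTruth:
    """Construct the ground-truth MVAR systems for every trial condition.

    The innovation variance is normalised so that the base-condition process
    has mean channel RMS equal to ``config.oscillation_sd`` — a single global
    scale shared by all conditions, which leaves the DTF untouched but makes
    ``noise_sd``, ``drift_amplitude`` and ``line_amplitude`` directly
    comparable to the oscillation amplitude.

    Raises a configuration error naming the offending gain when any
    condition's system is unstable (companion spectral radius >= 1).
    """
    config.validate()
    sets = {
        "base": _coefficients(config, 1.0),
        "boosted": _coefficients(config, config.outcome_effect),
        "rest": _coefficients(config, config.rest_coupling_scale),
    }
    if config.oscillation_sd > 0:
        if MvarProcess(sets["base"]).spectral_radius() >= 1.0:
            gains = ", ".join(
                f"{c.source}->{c.sink} gain={c.gain}" for c in config.coupling_spec
            )
            raise ValueError(
                f"unstable generator in condition 'base'; offending couplings: {gains}"
            )
        innovation_sd = config.oscillation_sd / _base_process_rms(sets["base"])
    else:
        innovation_sd = 0.0
    gt = GroundTruth(
        coefs=sets,
        regions=config.regions,
        delta_t=1.0 / config.sampling_rate,
        innovation_sd=innovation_sd,
        event_fractions=config.event_fractions,
        coupling_spec=list(config.coupling_spec),
    )
    for name in ("base", "boosted", "rest"):
        rho = gt.process(name).spectral_radius()
        if rho >= 1.0:
            gains = ", ".join(
                f"{c.source}->{c.sink} gain={c.gain}" for c in config.coupling_spec
            )
            raise ValueError(
                f"unstable generator in condition {name!r} "
                f"(spectral radius {rho:.4f} >= 1); offending couplings: {gains}"
            )
    return gt


def _trial_schedule(
    config: SimulationConfig, gt: GroundTruth, outcome: str, n_samples: int
) -> list[tuple[int, str]]:
    """Piecewise-stationary schedule: list of (segment length, condition)."""
    if outcome == "rest":
        return [(n_samples, "rest")]
    if outcome != "correct" or not config.coupling_spec:
        return [(n_samples, "base")]
    # boost window: union span of the coupling epoch windows (they coincide by
    # default); piecewise-constant within it
    w0 = min(c.epoch_window[0] for c in config.coupling_spec)
    w1 = max(c.epoch_window[1] for c in config.coupling_spec)
    i0, i1 = int(round(w0 * n_samples)), int(round(w1 * n_samples))
    segs = []
    if i0 > 0:
        segs.append((i0, "base"))
    segs.append((i1 - i0, "boosted"))
    if n_samples - i1 > 0:
        segs.append((n_samples - i1, "base"))
    return segs


def _simulate_one(
    config: SimulationConfig,
    gt: GroundTruth,
    outcome: str,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    p, n = config.true_order, config.n_channels
    out = np.empty((n, n_samples))
    state: np.ndarray | None = None
    filled = 0
    for seg_len, condition in _trial_schedule(config, gt, outcome, n_samples):
        if seg_len <= 0:
            continue
        proc = gt.process(condition)
        seg = proc.simulate(
            seg_len,
            rng,
            burn_in=0 if state is not None else max(500, 5 * p),
            initial_state=state,
            noise_scale=1.0 if gt.innovation_sd > 0 else 0.0,
        )
        out[:, filled : filled + seg_len] = seg
        filled += seg_len
        if p > 0:
            hist = out[:, max(0, filled - p) : filled].T
            if hist.shape[0] < p:
                hist = np.concatenate([np.zeros((p - hist.shape[0], n)), hist])
            state = hist
    return out


def _artifacts(
    config: SimulationConfig, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Additive broadband measurement noise, baseline drift (order-3
    polynomial) and 50 Hz line contamination, per channel."""
    n = config.n_channels
    t = np.linspace(-1.0, 1.0, n_samples)
    out = np.zeros((n, n_samples))
    if config.noise_sd > 0:
        out += config.noise_sd * rng.standard_normal((n, n_samples))
    if config.drift_amplitude > 0:
        coeffs = rng.standard_normal((n, 4))
        drift = np.polynomial.polynomial.polyval(t, coeffs.T)
        peak = np.abs(drift).max(axis=1, keepdims=True)
        peak[peak == 0] = 1.0
        out += config.drift_amplitude * drift / peak
    if config.line_amplitude > 0:
        tt = np.arange(n_samples) / config.sampling_rate
        phases = rng.uniform(0, 2 * np.pi, size=n)
        out += config.line_amplitude * np.sin(
            2 * np.pi * 50.0 * tt[None, :] + phases[:, None]
        )
    return out


def simulate_trials(
    config: SimulationConfig,
) -> tuple[list[LfpRecording], TrialTable, GroundTruth]:
    """Simulate the configured task (and rest) trials.

    Returns one :class:`LfpRecording` per trial, the matching
    :class:`TrialTable` (events, outcome, kinematics) and the
    :class:`GroundTruth` generator.  Fully reproducible from ``config.seed``.
    """
    gt = build_generator(config)
    rng = np.random.default_rng(config.seed)
    outcomes = (
        ["correct"] * config.n_correct
        + ["incorrect"] * config.n_incorrect
        + ["rest"] * config.n_rest
    )
    recordings: list[LfpRecording] = []
    rows = []
    _, f_turn, _ = config.event_fractions
    for trial_id, outcome in enumerate(outcomes):
        duration = config.trial_duration
        if config.duration_jitter > 0:
            duration = float(
                np.clip(
                    rng.normal(config.trial_duration, config.duration_jitter),
                    0.5 * config.trial_duration,
                    1.5 * config.trial_duration,
                )
            )
        n_samples = max(config.true_order + 1, int(round(duration * config.sampling_rate)))
        x = _simulate_one(config, gt, outcome, n_samples, rng)
        x = x + _artifacts(config, n_samples, rng)
        recordings.append(
            LfpRecording(
                samples=x,
                sampling_rate=config.sampling_rate,
                channel_regions=config.regions,
                trial_id=trial_id,
                subject_id=config.subject_id,
            )
        )
        speed = float(max(rng.normal(config.speed_mean, config.speed_sd), 1e-3))
        rows.append(
            {
                "subject": config.subject_id,
                "trial": trial_id,
                "phase": "rest" if outcome == "rest" else config.phase,
                "outcome": outcome,
                "t_start": 0.0,
                "t_turn": f_turn * n_samples / config.sampling_rate,
                "t_reward": n_samples / config.sampling_rate,
                "speed": speed,
                "duration": n_samples / config.sampling_rate,
            }
        )
    table = TrialTable(pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS))
    return recordings, table, gt
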