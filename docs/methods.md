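# Methods

This note records the models, parameter choices and numerical decisions
behind `dtflow`, and what the synthetic benchmark does and does not
demonstrate.

## Estimation model

Each analysis window of the multichannel LFP is treated as a realisation of a
stable MVAR(p) process, `X(t) = Σ Aₙ X(t−n) + E(t)`. Coefficients are
estimated by multichannel least squares (one regression of the stacked lagged
design against all channels); the innovation covariance reported to the user
carries the small-sample degrees-of-freedom correction, while the
maximum-likelihood covariance is used inside the BIC,
`ln det Σ̂ + (ln n) p N² / n`. Order selection scans p = 1..20 on a common
effective sample (the first `max_order` observations are dropped for all
candidates, as in standard VAR order selection) and breaks ties toward the
smaller order. The fit refuses constant channels and rank-deficient designs
by name rather than returning silently unstable estimates, and enforces the
rule of thumb of at least 10·N·p observations per window.

The spectral transfer function is `H(f) = A(f)⁻¹` with
`A(f) = Σᵢ₌₀..p A(i)e^(−j2πfiΔt)`, `A(0) = −I`. Only |H| enters any reported
quantity, so the overall sign convention of A(f) is unobservable. The DTF is
sink-row normalised: `γ²ᵢⱼ(f) = |Hᵢⱼ|²/Σₘ|Hᵢₘ|²`, the fraction of the
spectral inflow to channel i attributable to channel j. Rows therefore sum
to one by construction — this is asserted (tolerance 1e-8) on every
constructed spectrum, and it also means the DTF is invariant to any common
rescaling of the data.

Frequency grid: 1–100 Hz at 1 Hz. 0 Hz is excluded because detrending
removes DC and `A(0)` can be near-singular for near-unit-root fits.

Estimation is per trial and per sliding window (500 ms windows, 125 ms
steps — the same grid as the spectrograms), and information flow is averaged
across trials *after* computation, never computed on trial-averaged signals:
trial-level values are what the statistics operate on.

## Information flow and position mapping

IF(src→snk)(f) is the mean of the cross-region DTF block (sink rows, source
columns); band IF averages over the in-band grid frequencies (theta = 4–12 Hz
fixed; delta 0.5–4, beta 12–30, gamma 30–80 available). A band reaching
beyond the grid is clipped with a warning rather than rejected, so coarse
grids degrade loudly but gracefully.

Trials are mapped from time to a track coordinate assuming uniform speed
within each leg: position runs linearly 0→1 from the start event to the turn
event and 1→2 from turn to reward. Window centres are binned (default 10
bins per leg; group profiles in the tests use 5 for occupancy); empty bins
are NaN and excluded from group means. ΔIF over a segment is the segment
maximum minus the value in the segment's first occupied bin.

## Signal conditioning

Fixed stage order: polynomial detrend → 50 Hz notch → optional band-pass.
Drift is removed first because it violates every subsequent filter's
stationarity assumption most.

* Detrend: least-squares polynomial per channel, default order 2 — high
  enough for slow electrode drift, low enough to leave 4 Hz content intact
  (verified: theta power of a ramp+tone input is preserved to < 1%).
* Notch: second-order IIR, Q = 30 at 50 Hz, applied forward-backward.
  Zero-phase application squares the magnitude response: > 20 dB at exactly
  50 Hz, < 0.1 dB at 40/60 Hz.
* Band-pass: Chebyshev type I, order 4, applied forward-backward for zero
  phase (event alignment is load-bearing for the position mapping). Ripple
  is 0.1 dB: filtfilt doubles ripple in dB, and repeated passes multiply the
  in-band loss, so a larger ripple would visibly erode band power on
  re-filtering. With this design the theta band passes 8 Hz at −0.06 dB,
  rejects 30 Hz at −90 dB, and a second broadband pass changes interior band
  power by ≈ 1%.

Zero-phase behaviour is tested by cross-correlation: the lag of a filtered
in-band tone against its input is exactly 0 samples.

## Spectral estimation

Multitaper spectrograms use DPSS tapers with time–bandwidth NW = 2 and 3
tapers per 500 ms window — the standard compromise at this window length.
The native resolution of a 0.5 s window is 2 Hz; windows are zero-padded to
1 s to evaluate the spectrum on a 1 Hz grid. That grid is interpolated
resolution, not added information, and is labelled as such here once: the
package reports it without further comment. Densities are one-sided and
Parseval-consistent (integrated density within 10% of signal variance for
stationary noise).

## The synthetic generator

The generator produces exactly the process class the estimator assumes — a
stable MVAR system — so ground truth is analytic, not approximate. Design:

* **Oscillators.** Each channel is a unit-innovation AR(2) resonator with
  poles at radius 0.99 and angle 2πf₀Δt (f₀ = 8 Hz by default). At 1 kHz
  this radius gives a theta linewidth of ~2–3 Hz, sharp enough that every
  channel's 4–30 Hz spectral peak lies within ±1 Hz of f₀, broad enough that
  short windows still contain several effective cycles of innovation.
* **Coupling.** Directed influence enters as lag-1 coefficients from source
  channels to sink channels. The directed transfer inherits the source pole,
  so the induced DTF peak sits at the source resonance. Raw lag coefficients
  are badly scaled for high-Q resonators (the resonance amplifies the
  coupled drive by orders of magnitude), so the `gain` parameter is defined
  on the drive scale: the standard deviation of the summed cross-region
  input to each sink channel, in units of that channel's own innovation SD.
  The conversion uses the source resonator's stationary SD from the discrete
  Lyapunov equation. Gains of order 0.1–1 then span weak-to-strong coupling,
  and stability degrades gracefully and detectably (the builder rejects any
  condition whose companion spectral radius reaches 1, naming the offending
  coupling).
* **Conditions.** Correct trials carry the coupling boosted by
  `outcome_effect` (default ×3) inside the epoch window (default 0.3–0.6 of
  the trial, i.e. the approach to the turn; events default to start 0, turn
  0.6, reward 1.0 of the trial). Incorrect trials run at base gain
  throughout; rest periods scale the coupling by `rest_coupling_scale`
  (default 0). Within-trial changes are piecewise-stationary with state
  handed across segment boundaries — matching the windowed estimator's own
  stationarity assumption.
* **Amplitude bookkeeping.** Innovation variance is normalised (again via
  the Lyapunov solution) so the base process's mean channel RMS equals
  `oscillation_sd` — one global factor shared by all conditions, which the
  scale-invariant DTF never sees. Measurement realism is then additive on
  the same scale: broadband white noise (`noise_sd`, default 0.02), slow
  order-3 polynomial drift (`drift_amplitude`, default 1.0) and a 50 Hz line
  component (`line_amplitude`, default 0.3, random phase per channel).
* **Trial structure.** Per-trial durations jitter around `trial_duration`
  (default 2 s ± 0.15 s); running speed is drawn independently of outcome,
  so movement controls are null by construction. Default per-subject counts
  (37 correct / 15 incorrect) sit at the scale of one animal's sessions in a
  typical study of this design.

Determinism: one `default_rng(seed)` drives the whole session in a fixed
order; identical configurations are bit-identical.

### What the benchmark does not show

The generator is the estimator's own model class plus well-behaved additive
contamination. Real LFPs bring volume conduction and shared references
(which inflate zero-lag correlations DTF cannot attribute), observation
noise far above 2% of signal RMS (which biases AR estimates toward white —
visible in this package already at noise_sd ≈ 0.1), nonstationarity inside
windows, and electrode heterogeneity. Passing the synthetic benchmark
demonstrates the *correctness of the computation and the recoverability of
directionality under the model's assumptions*, not robustness to those
violations. Absolute IF magnitudes here (~0.05–0.3) are well above values
typical of noisy in-vivo recordings; only the contrasts (direction, outcome,
epoch, condition ordering) are the meaningful comparanda.

## Statistics

Mann–Whitney U is exact (full null distribution) when both groups have ≤ 20
observations and the pooled sample is tie-free, otherwise the normal
approximation with tie correction — exact enumeration is the reason for the
n = 20 switch. One-way and two-way ANOVA are fixed-effects OLS with Type II
sums of squares (correct for the unbalanced correct/incorrect designs this
pipeline produces); the two-factor model includes the interaction.
Bonferroni post-hoc tests are pairwise equal-variance t tests with
`p_adj = min(1, p·m)`. All-equal inputs short-circuit to F = 0, p = 1 rather
than dividing zero by zero. Repeated-measures structure (trials nested in
subjects) is deliberately not modelled; group means ± SEM are reported at
the trial level, and per-subject aggregation is available by grouping the
tidy output table.

The subsampling control draws, per subject, a uniform random subset of the
majority outcome group sized to that subject's minority group; subjects
missing a group entirely are excluded with a warning.

## Problem sizes

The shipped tests and the acceptance script run the study at desk scale,
chosen as the smallest sizes at which the qualitative results are stable
across seeds: 2 channels per region, 2 s trials; 50 trials/group for the
directional contrast; 20 trials/condition for the epoch and ordering
analyses (sliding-window fits, BIC ≤ 8); 20 seeds × 20 000 samples for
estimator convergence; 100 random systems for normalisation; 2 000
repetitions for Mann–Whitney calibration. Channel counts are configurable —
the per-region default of 4 (2 in the heavy analyses) is a choice, not a
claim about any particular recording array.

## Known limitations

* DTF carries no significance thresholding of individual edges; surrogate
  or bootstrap testing of single connections is out of scope.
* Measurement noise makes the observed process VARMA rather than VAR; the
  estimator is consistent only as noise → 0, and the generator's default
  SNR is chosen inside the well-specified regime (see above).
* The position mapping assumes uniform speed within legs; real kinematics
  would need the tracked trajectory.
* Partial directed coherence and its variants, time-varying (Kalman) MVAR,
  and cross-frequency coupling are not implemented.
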