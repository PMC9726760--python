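# dtflow

Directed information-flow analysis of two-region multichannel local field
potentials (LFPs), built for trial-based electrophysiology experiments such as
simultaneous medial prefrontal cortex (mPFC) / mediodorsal thalamus (MD)
recordings during spatial working-memory tasks.

The pipeline answers a directional question: *how strongly, at which
frequencies, and at which moments of a trial does one region drive the other?*
It fits multivariate autoregressive (MVAR) models to trial windows, forms the
frequency-domain **directed transfer function (DTF)**, aggregates it into
region-level bidirectional **information flow (IF)**, and compares IF across
trial outcomes, task epochs and directions with nonparametric and ANOVA
statistics. Because in-vivo recordings of this kind are rarely shared, the
package includes a first-class synthetic-data generator with exactly known
directional ground truth, so that every stage of the analysis is verifiable.

## The method

An N-channel LFP window `X(t) = [x1(t), ..., xN(t)]ᵀ` is modelled as a
stable MVAR process of order p (selected by BIC):

    X(t) = Σₙ₌₁..p Aₙ X(t−n) + E(t)

with coefficient matrices `Aₙ` and white innovations `E(t)`. On a frequency
grid the coefficient polynomial `A(f) = Σᵢ₌₀..p A(i) e^(−j2πfiΔt)` (with
`A(0) = −I`) inverts to the transfer function `H(f) = A(f)⁻¹`, and the DTF
normalises its squared magnitudes over all sources feeding each sink channel
i:

    γ²ᵢⱼ(f) = |Hᵢⱼ(f)|² / Σₘ |Hᵢₘ(f)|²

so every sink row of `γ²(f)` sums to one. Region-level information flow is
the mean DTF over all cross-region channel pairs,

    IF(src→snk)(f) = 1/(N_src·N_snk) Σᵢ∈snk Σⱼ∈src γ²ᵢⱼ(f)

band-averaged (theta, 4–12 Hz, by default), evaluated per 500 ms window moved
in 125 ms steps, and optionally mapped onto the track coordinate between the
logged position events (start → turn → reward). ΔIF — the peak IF over a
trial segment minus its value at the segment start — summarises the
within-trial dynamics.

Signal conditioning reproduces standard LFP practice: polynomial
baseline-drift removal, a zero-phase 50 Hz notch, and zero-phase Chebyshev
band-pass sub-band extraction; spectra use the multitaper method (DPSS
tapers, 500 ms / 125 ms windows, 1 Hz grid).

## Worked example

Simulate a session with known directional theta coupling (mPFC→MD, boosted in
the pre-turn epoch of correct trials), then recover the direction:

```python
import numpy as np
from dtflow import (SimulationConfig, simulate_trials, preprocess_recording,
                    fit_mvar, mann_whitney, THETA)
from dtflow.information_flow import band_if, region_if

cfg = SimulationConfig(n_correct=20, n_incorrect=10, trial_duration=2.0, seed=42)
recordings, trials, truth = simulate_trials(cfg)
print(f"{trials.n_trials} trials ({trials.n_correct} correct, {trials.n_incorrect} incorrect)")

theta_if = {"mPFC->MD": [], "MD->mPFC": []}
for rec in recordings:
    clean = preprocess_recording(rec)             # detrend + 50 Hz notch
    result = fit_mvar(clean, order="bic", max_order=8)
    d = result.dtf()                              # DTF on the 1-100 Hz grid
    for src, snk in (("mPFC", "MD"), ("MD", "mPFC")):
        theta_if[f"{src}->{snk}"].append(
            band_if(region_if(d, src, snk), d.frequency_grid, THETA))

fwd, rev = theta_if["mPFC->MD"], theta_if["MD->mPFC"]
print(f"theta IF mPFC->MD: {np.mean(fwd):.3f} +/- {np.std(fwd)/np.sqrt(len(fwd)):.3f}")
print(f"theta IF MD->mPFC: {np.mean(rev):.3f} +/- {np.std(rev)/np.sqrt(len(rev)):.3f}")
print(f"Mann-Whitney p = {mann_whitney(fwd, rev).p_value:.2e}")
```

Output:

```
30 trials (20 correct, 10 incorrect)
theta IF mPFC->MD: 0.122 +/- 0.004
theta IF MD->mPFC: 0.042 +/- 0.001
Mann-Whitney p = 3.02e-11
```

The forward theta IF is roughly three times the reverse — the generator's
one-way coupling, recovered from the signals alone. `result.summary()` prints
the fitted coefficient matrices, innovation covariance, BIC and stability
diagnostics of any window's MVAR model.

The same stages are available from the shell:

```bash
dtflow run --config config.yaml --out results/      # full pipeline
dtflow simulate --out sim/                          # or stage by stage:
dtflow preprocess --in sim/ --out clean/
dtflow dtf --in clean/ --out dtf/ --order bic
dtflow infoflow --in dtf/ --out results.csv --band theta
dtflow stats --in results.csv --trials sim/trials.csv --out report/
```

Every output directory carries the effective configuration and its hash;
stages refuse inputs produced under a different configuration.

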