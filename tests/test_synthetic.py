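import numpy as np
import pytest

from dtflow import (
    CouplingSpec,
    SimulationConfig,
    build_generator,
    multitaper_spectrogram,
    simulate_trials,
)


def small_config(**kw):
    base = dict(
        n_mpfc_channels=2,
        n_md_channels=2,
        n_correct=2,
        n_incorrect=1,
        trial_duration=1.0,
        seed=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestBuildGenerator:
    def test_decoupled_system_has_zero_cross_dtf(self):
        cfg = small_config(coupling_spec=[CouplingSpec("mPFC", "MD", gain=0.0)])
        gt = build_generator(cfg)
        d = gt.analytic_dtf("base")
        mpfc = d.region_channels("mPFC")
        md = d.region_channels("MD")
        assert np.all(d.gamma_sq[:, md[:, None], mpfc[None, :]] == 0)
        assert np.all(d.gamma_sq[:, mpfc[:, None], md[None, :]] == 0)

    def test_unidirectional_coupling_has_zero_reverse_transfer(self):
        cfg = small_config(coupling_spec=[CouplingSpec("mPFC", "MD", gain=0.5)])
        gt = build_generator(cfg)
        d = gt.analytic_dtf("base")
        mpfc = d.region_channels("mPFC")
        md = d.region_channels("MD")
        f8 = np.flatnonzero(d.frequency_grid == 8.0)[0]
        # forward transfer present at the coupling frequency
        assert d.gamma_sq[f8, md[:, None], mpfc[None, :]].min() > 0
        # block-triangular system: no reverse transfer at any frequency
        assert np.all(d.gamma_sq[:, mpfc[:, None], md[None, :]] < 1e-12)

    def test_unstable_configuration_rejected_with_named_gain(self):
        # bidirectional feedback destabilises the boosted system (one-way
        # coupling leaves the block-triangular eigenvalues untouched)
        cfg = small_config(
            coupling_spec=[
                CouplingSpec("mPFC", "MD", gain=0.5),
                CouplingSpec("MD", "mPFC", gain=0.5),
            ]
        )
        # brute-force oracle: companion spectral radius of the boosted system
        from dtflow.synthetic import _coefficients

        coefs = _coefficients(cfg, cfg.outcome_effect)
        p, n = coefs.shape[0], coefs.shape[1]
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = coefs.transpose(1, 0, 2).reshape(n, n * p)
        comp[n:, :-n] = np.eye(n * (p - 1))
        assert np.max(np.abs(np.linalg.eigvals(comp))) >= 1.0
        with pytest.raises(ValueError, match="gain=0.5"):
            build_generator(cfg)

    def test_analytic_dtf_rows_sum_to_one(self):
        gt = build_generator(small_config())
        for cond in ("base", "boosted", "rest"):
            rows = gt.analytic_dtf(cond).gamma_sq.sum(axis=2)
            assert np.allclose(rows, 1.0, atol=1e-10)

    def test_analytic_dtf_matches_connectivity_module_on_true_coefficients(self):
        from dtflow import dtf, transfer_function

        gt = build_generator(small_config())
        d_direct = dtf(
            transfer_function(gt.coefs["base"], delta_t=gt.delta_t),
            node_regions=gt.regions,
        )
        assert np.allclose(
            d_direct.gamma_sq, gt.analytic_dtf("base").gamma_sq, atol=1e-10
        )


class TestSimulateTrials:
    def test_study_scale_trial_counts(self):
        cfg = small_config(
            n_correct=295, n_incorrect=117, trial_duration=0.05, duration_jitter=0.0
        )
        recs, table, _ = simulate_trials(cfg)
        assert len(recs) == 412
        assert table.n_trials == 412
        assert table.n_correct == 295
        assert table.n_incorrect == 117

    def test_silent_config_yields_all_zero_signals(self):
        cfg = small_config(
            noise_sd=0.0,
            oscillation_sd=0.0,
            drift_amplitude=0.0,
            line_amplitude=0.0,
            coupling_spec=[CouplingSpec("mPFC", "MD", gain=0.0)],
        )
        recs, _, _ = simulate_trials(cfg)
        for rec in recs:
            assert np.all(rec.samples == 0)

    def test_same_seed_is_bit_identical(self):
        a_recs, a_table, _ = simulate_trials(small_config())
        b_recs, b_table, _ = simulate_trials(small_config())
        assert a_table == b_table
        for ra, rb in zip(a_recs, b_recs):
            assert np.array_equal(ra.samples, rb.samples)

    def test_different_seed_differs(self):
        a, _, _ = simulate_trials(small_config(seed=1))
        b, _, _ = simulate_trials(small_config(seed=2))
        assert not np.array_equal(a[0].samples, b[0].samples)

    def test_oscillation_dominates_low_frequency_spectrum(self):
        cfg = small_config(
            n_correct=1,
            n_incorrect=0,
            trial_duration=4.0,
            duration_jitter=0.0,
            drift_amplitude=0.0,
            line_amplitude=0.0,
        )
        recs, _, _ = simulate_trials(cfg)
        spec = multitaper_spectrogram(recs[0])
        mask = (spec.frequency_grid >= 4) & (spec.frequency_grid <= 30)
        for ch in range(recs[0].n_channels):
            mean_power = spec.power[ch].mean(axis=0)[mask]
            peak = spec.frequency_grid[mask][np.argmax(mean_power)]
            assert abs(peak - cfg.oscillation_freq) <= 1.0

    def test_event_times_follow_configured_fractions(self):
        cfg = small_config(duration_jitter=0.0)
        _, table, _ = simulate_trials(cfg)
        assert np.allclose(table.data["t_turn"], 0.6 * cfg.trial_duration)
        assert np.allclose(table.data["t_reward"], cfg.trial_duration)

    def test_rest_trials_labelled(self):
        cfg = small_config(n_rest=2)
        _, table, _ = simulate_trials(cfg)
        assert (table.data["outcome"] == "rest").sum() == 2
        assert (table.data.loc[table.data.outcome == "rest", "phase"] == "rest").all()


class TestConfigValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            small_config(n_correct=-1).validate()

    def test_sampling_rate_must_exceed_twice_band_edge(self):
        with pytest.raises(ValueError):
            small_config(sampling_rate=15.0).validate()

    def test_order_below_two_rejected(self):
        with pytest.raises(ValueError):
            small_config(true_order=1).validate()
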