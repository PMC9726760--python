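import numpy as np
import pytest

from dtflow import (
    DtfSpectrum,
    InformationFlowSeries,
    MvarProcess,
    THETA,
    band_if,
    delta_if,
    if_timecourse,
    map_to_position,
    region_if,
)
from dtflow.containers import BandDefinition


def tabulated_dtf():
    """2+2-node DTF with hand-checkable cross-region blocks (one frequency)."""
    g = np.array(
        [
            # sinks: rows; sources: columns.  nodes 0,1 = mPFC; 2,3 = MD
            [0.60, 0.20, 0.10, 0.10],
            [0.15, 0.55, 0.20, 0.10],
            [0.30, 0.10, 0.50, 0.10],
            [0.20, 0.20, 0.10, 0.50],
        ]
    )[None]
    return DtfSpectrum(
        gamma_sq=g,
        frequency_grid=np.array([8.0]),
        node_regions=["mPFC", "mPFC", "MD", "MD"],
    )


class TestRegionIf:
    def test_tabulated_cross_block_mean(self):
        d = tabulated_dtf()
        # mPFC -> MD: gamma[MD sinks 2,3; mPFC sources 0,1]
        expected_fwd = (0.30 + 0.10 + 0.20 + 0.20) / 4
        expected_rev = (0.10 + 0.10 + 0.20 + 0.10) / 4
        assert np.isclose(region_if(d, "mPFC", "MD")[0], expected_fwd)
        assert np.isclose(region_if(d, "MD", "mPFC")[0], expected_rev)

    def test_single_node_regions_equal_single_entry(self):
        g = np.array([[[0.7, 0.3], [0.4, 0.6]]])
        d = DtfSpectrum(
            gamma_sq=g, frequency_grid=np.array([8.0]), node_regions=["mPFC", "MD"]
        )
        assert np.isclose(region_if(d, "mPFC", "MD")[0], 0.4)
        assert np.isclose(region_if(d, "MD", "mPFC")[0], 0.3)

    def test_identity_transfer_gives_zero_if_both_directions(self):
        proc = MvarProcess(
            np.zeros((0, 4, 4)), delta_t=1e-3, node_regions=["mPFC", "mPFC", "MD", "MD"]
        )
        d = proc.dtf()
        assert np.allclose(region_if(d, "mPFC", "MD"), 0.0)
        assert np.allclose(region_if(d, "MD", "mPFC"), 0.0)

    def test_unknown_region_rejected(self):
        with pytest.raises(KeyError):
            region_if(tabulated_dtf(), "mPFC", "hippocampus")


class TestBandIf:
    def test_constant_profile_returns_constant(self):
        freqs = np.arange(1.0, 101.0)
        assert np.isclose(band_if(np.full(100, 0.3), freqs, THETA), 0.3)

    def test_theta_mean_of_tabulated_profile(self):
        freqs = np.arange(1.0, 101.0)
        values = np.zeros(100)
        profile = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.4, 0.3, 0.2, 0.1])
        values[3:12] = profile  # 4..12 Hz inclusive = 9 bins
        assert np.isclose(band_if(values, freqs, THETA), profile.mean())

    def test_band_wider_than_grid_clips_with_warning(self):
        freqs = np.arange(5.0, 11.0)
        with pytest.warns(UserWarning, match="clipping"):
            out = band_if(np.linspace(0, 1, 6), freqs, THETA)
        assert np.isclose(out, np.linspace(0, 1, 6).mean())

    def test_disjoint_band_rejected(self):
        with pytest.raises(ValueError):
            band_if(np.ones(3), np.array([50.0, 60.0, 70.0]), BandDefinition("lo", 1, 2))


class TestTimecourse:
    def test_single_window_series_equals_band_if(self):
        d = tabulated_dtf()
        band = BandDefinition("only", 7.0, 9.0)
        series = if_timecourse([d], np.array([0.25]), "mPFC", "MD", band)
        assert series.values.shape == (1,)
        assert np.isclose(series.values[0], region_if(d, "mPFC", "MD")[0])

    def test_empty_window_list_rejected(self):
        with pytest.raises(ValueError):
            if_timecourse([], np.array([]), "mPFC", "MD")


class TestPositionMapping:
    def make_series(self, values, times):
        return InformationFlowSeries(
            direction="mPFC->MD",
            band=THETA,
            values=np.asarray(values, dtype=float),
            bins=np.asarray(times, dtype=float),
        )

    def test_uniform_speed_mapping_places_turn_at_position_one(self):
        times = np.linspace(0.1, 1.9, 10)
        series = self.make_series(np.linspace(0.1, 0.3, 10), times)
        pos = map_to_position(series, (0.0, 1.0, 2.0), n_bins_per_segment=5)
        assert pos.bin_type == "position"
        assert pos.bins.size == 10
        assert pos.bins.max() < 2.0
        # pre-turn windows land in position bins < 1
        pre = times < 1.0
        assert np.nanmean(pos.values[pos.bins < 1.0]) == pytest.approx(
            series.values[pre].mean(), rel=0.2
        )

    def test_missing_event_times_rejected(self):
        series = self.make_series([0.1, 0.2], [0.2, 0.4])
        with pytest.raises(ValueError):
            map_to_position(series, (0.0, np.nan, 2.0))
        with pytest.raises(ValueError):
            map_to_position(series, (0.0, 2.0, 1.0))


class TestDeltaIf:
    def test_flat_series_has_zero_delta(self):
        series = InformationFlowSeries(
            "mPFC->MD", THETA, np.full(10, 0.25), np.linspace(0.05, 0.95, 10), "position"
        )
        assert delta_if(series, (0.0, 1.0)).delta == 0.0

    def test_monotonic_rise_gives_end_minus_start(self):
        series = InformationFlowSeries(
            "mPFC->MD",
            THETA,
            np.linspace(0.2, 0.5, 10),
            np.linspace(0.05, 0.95, 10),
            "position",
        )
        res = delta_if(series, (0.0, 1.0))
        assert np.isclose(res.delta, 0.3)
        assert res.peak_location == series.bins[-1]
        assert res.initial_location == series.bins[0]

    def test_empty_segment_rejected(self):
        series = InformationFlowSeries(
            "mPFC->MD", THETA, np.array([0.1]), np.array([0.5]), "position"
        )
        with pytest.raises(ValueError):
            delta_if(series, (1.5, 2.0))

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            InformationFlowSeries(
                "mPFC->MD", THETA, np.array([1.5]), np.array([0.5]), "time"
            )
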