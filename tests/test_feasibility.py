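"""Gap detection, coverage conservation, SNR estimation and attribution."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neowear.feasibility import (
    Gap,
    GapCause,
    GapThresholds,
    attribute_gaps,
    compare_paired,
    compare_unpaired,
    coverage,
    detect_gaps,
    estimate_snr,
    SNRSeries,
)
from neowear.io_recordings import (
    AnnotationEvent,
    AnnotationLabel,
    ChannelRole,
    DeviceFlag,
    FlagType,
    TimeSeriesChannel,
)


def _ppg64(mask_missing, n=6400):
    v = np.sin(np.arange(n) * 0.3)
    v[mask_missing] = np.nan
    return TimeSeriesChannel(ChannelRole.WIRELESS_PPG, 0.0, 64.0, v)


class TestDetectGaps:
    def test_run_equal_to_threshold_is_not_a_gap(self):
        ch = _ppg64([100, 101])  # 2 samples = 31.25 ms exactly
        assert detect_gaps(ch, GapThresholds(), ch.duration_s) == []

    def test_run_exceeding_threshold_is_one_gap(self):
        ch = _ppg64([100, 101, 102])  # 46.875 ms
        gaps = detect_gaps(ch, GapThresholds(), ch.duration_s)
        assert len(gaps) == 1
        assert gaps[0].duration_s == pytest.approx(3 / 64)

    def test_spo2_gap_and_coverage_example(self):
        v = np.full(3600, 95.0)
        v[1000:1036] = np.nan  # 36 s
        ch = TimeSeriesChannel(ChannelRole.WIRED_SPO2, 0.0, 1.0, v)
        gaps = detect_gaps(ch, GapThresholds(), 3600.0)
        assert len(gaps) == 1 and gaps[0].duration_s == 36.0
        cov = coverage(ch, GapThresholds(), 3600.0)
        assert cov.coverage_pct == pytest.approx(99.0)

    def test_leading_and_trailing_time_count_as_gaps(self):
        ch = TimeSeriesChannel(ChannelRole.WIRED_SPO2, 10.0, 1.0,
                               np.full(100, 95.0))
        gaps = detect_gaps(ch, GapThresholds(), 200.0)
        assert [(g.start_s, g.end_s) for g in gaps] == [(0.0, 10.0), (110.0, 200.0)]

    def test_single_valid_sample_separates_gaps(self):
        v = np.full(100, 95.0)
        v[10:20] = np.nan
        v[21:30] = np.nan
        ch = TimeSeriesChannel(ChannelRole.WIRED_SPO2, 0.0, 1.0, v)
        gaps = detect_gaps(ch, GapThresholds(), 100.0)
        assert len(gaps) == 2

    def test_fully_missing_channel_has_zero_coverage(self):
        ch = TimeSeriesChannel(ChannelRole.WIRED_SPO2, 0.0, 1.0,
                               np.full(100, np.nan))
        assert coverage(ch, GapThresholds(), 100.0).coverage_pct == 0.0

    def test_gap_free_channel_has_full_coverage(self):
        ch = TimeSeriesChannel(ChannelRole.WIRED_SPO2, 0.0, 1.0,
                               np.full(100, 95.0))
        assert coverage(ch, GapThresholds(), 100.0).coverage_pct == 100.0

    @given(st.lists(st.booleans(), min_size=1, max_size=400))
    def test_coverage_plus_gap_fraction_is_conserved(self, missing):
        v = np.where(np.array(missing), np.nan, 95.0)
        ch = TimeSeriesChannel(ChannelRole.WIRED_SPO2, 0.0, 1.0, v)
        planned = float(len(missing))
        cov = coverage(ch, GapThresholds(), planned)
        assert cov.coverage_pct + 100.0 * cov.total_gap_time_s / planned == (
            pytest.approx(100.0, abs=1e-9)
        )


class TestEstimateSnr:
    def _tone(self, f=2.5, fs=64.0, dur=120.0, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(dur * fs)) / fs
        v = np.sin(2 * np.pi * f * t) + noise_sd * rng.standard_normal(t.size)
        return TimeSeriesChannel(ChannelRole.WIRELESS_PPG, 0.0, 64.0, v)

    def test_pure_tone_hits_positive_cap(self):
        snr = estimate_snr(self._tone())
        assert np.nanmin(snr.snr_db) == 40.0

    def test_constructed_equal_power_ratio_is_near_zero_db(self):
        # white-noise power in the 8.7 Hz noise band equal to tone power:
        # sd^2 * 8.7/32 = 0.5  =>  sd = sqrt(0.5 * 32 / 8.7)
        sd = np.sqrt(0.5 * 32.0 / 8.7)
        snr = estimate_snr(self._tone(noise_sd=sd, seed=4))
        assert abs(np.nanmedian(snr.snr_db)) < 1.0

    def test_all_missing_window_yields_missing_value(self):
        ch = self._tone()
        ch.values[:] = np.nan
        snr = estimate_snr(ch)
        assert np.isnan(snr.snr_db).all()

    def test_amplitude_scaling_invariance(self):
        ch = self._tone(noise_sd=0.8, seed=9)
        scaled = TimeSeriesChannel(ch.channel_id, 0.0, 64.0, ch.values * 1024.0)
        a, b = estimate_snr(ch), estimate_snr(scaled)
        assert np.allclose(a.snr_db, b.snr_db, atol=1e-9, equal_nan=True)

    def test_constant_signal_has_no_peak(self):
        ch = TimeSeriesChannel(ChannelRole.WIRELESS_PPG, 0.0, 64.0,
                               np.full(64 * 60, 3.0))
        assert np.isnan(estimate_snr(ch).snr_db).all()


class TestAttribution:
    def _gap(self, role=ChannelRole.WIRELESS_SPO2, s=100.0, e=130.0):
        return Gap(role, s, e)

    def test_bt_flag_wins(self):
        gaps = attribute_gaps(
            [self._gap()],
            flags=[DeviceFlag(FlagType.BT_DISCONNECT, 95.0, 135.0)],
            annotations=[AnnotationEvent(AnnotationLabel.SA, 90.0, 140.0)],
        )
        assert gaps[0].cause is GapCause.BD

    def test_sensor_annotation_beats_low_snr(self):
        snr = SNRSeries(np.array([85.0, 145.0]), np.array([5.0, 5.0]), 30.0, 0.5)
        gaps = attribute_gaps(
            [self._gap()],
            flags=[],
            annotations=[AnnotationEvent(AnnotationLabel.SA, 120.0, 140.0)],
            snr=snr,
        )
        assert gaps[0].cause is GapCause.SR_SA

    def test_low_snr_with_activity_context(self):
        snr = SNRSeries(np.array([85.0, 145.0]), np.array([-5.0, -5.0]), 30.0, 0.5)
        gaps = attribute_gaps(
            [self._gap()],
            flags=[],
            annotations=[AnnotationEvent(AnnotationLabel.KC, 50.0, 200.0)],
            snr=snr,
        )
        assert gaps[0].cause is GapCause.LOW_SNR
        assert gaps[0].activity == "KC"

    def test_unexplained_wired_ppg_gap_is_cable(self):
        gaps = attribute_gaps([self._gap(role=ChannelRole.WIRED_PPG)], [], [])
        assert gaps[0].cause is GapCause.CABLE

    def test_unexplained_wireless_gap_is_unknown(self):
        gaps = attribute_gaps([self._gap()], [], [])
        assert gaps[0].cause is GapCause.UNKNOWN


class TestRankTests:
    def test_identical_paired_vectors_report_no_usable_pairs(self):
        res = compare_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.all_zero and res.n_used == 0
        assert res.p_two_sided > 0.999

    def test_rank_sum_statistic_matches_hand_enumeration(self):
        res = compare_unpaired([1, 2, 3], [4, 5, 6])
        assert res.statistic == 6.0
        # z = (6 - 10.5) / sqrt(5.25)
        assert res.z == pytest.approx(-4.5 / np.sqrt(5.25))

    def test_paired_lengths_must_match(self):
        with pytest.raises(ValueError):
            compare_paired([1, 2], [1, 2, 3])

    def test_minimum_sample_sizes(self):
        with pytest.raises(ValueError):
            compare_unpaired([1], [2, 3])
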