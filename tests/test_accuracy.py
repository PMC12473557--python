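"""Agreement metrics, oxygen grouping and the modified error grid."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neowear.accuracy import (
    AgreementSummary,
    DiffDirection,
    OxygenGroup,
    OxygenTargets,
    PairedSpO2Series,
    Region,
    aggregate_daily,
    bland_altman,
    classify_oxygen_group,
    ega_classify,
    ega_summary,
    error_by_snr,
    pair_samples,
)
from neowear.feasibility import SNRSeries
from neowear.io_recordings import ChannelRole, TimeSeriesChannel


def _spo2(values, role=ChannelRole.WIRED_SPO2, start=0.0):
    return TimeSeriesChannel(role, start, 1.0, np.asarray(values, dtype=float))


def _pairs(wired, wireless):
    w = np.asarray(wired, dtype=float)
    return PairedSpO2Series(np.arange(w.size, dtype=float), w,
                            np.asarray(wireless, dtype=float))


class TestPairSamples:
    def test_fully_valid_retains_all_instants(self):
        p = pair_samples(_spo2(np.full(100, 95.0)),
                         _spo2(np.full(100, 94.0), ChannelRole.WIRELESS_SPO2))
        assert p.n_pairs == 100

    def test_missing_wireless_samples_are_dropped(self):
        wl = np.full(100, 94.0)
        wl[:30] = np.nan
        p = pair_samples(_spo2(np.full(100, 95.0)),
                         _spo2(wl, ChannelRole.WIRELESS_SPO2))
        assert p.n_pairs == 70

    def test_disjoint_validity_gives_empty_series(self):
        a = np.full(100, 95.0)
        a[50:] = np.nan
        b = np.full(100, 94.0)
        b[:50] = np.nan
        p = pair_samples(_spo2(a), _spo2(b, ChannelRole.WIRELESS_SPO2))
        assert p.n_pairs == 0

    def test_misaligned_grids_raise(self):
        with pytest.raises(ValueError, match="synchronize"):
            pair_samples(_spo2(np.full(10, 95.0)),
                         _spo2(np.full(10, 94.0), ChannelRole.WIRELESS_SPO2,
                               start=0.3))


class TestBlandAltman:
    def test_identical_series_have_zero_bias_and_loa(self):
        s = bland_altman(_pairs([95, 96, 97], [95, 96, 97]))
        assert s.bias == 0.0 and s.loa_low == 0.0 and s.loa_high == 0.0
        assert s.mae == 0.0

    def test_hand_computed_example(self):
        # differences {1, 1, 1, 3}
        s = bland_altman(_pairs([95, 95, 95, 95], [94, 94, 94, 92]))
        assert s.bias == pytest.approx(1.5)
        assert s.sd_d == pytest.approx(1.0)
        assert s.loa_low == pytest.approx(-0.46)
        assert s.loa_high == pytest.approx(3.46)
        assert s.moe == pytest.approx(1.96)
        assert s.mae == pytest.approx(1.5)

    def test_direction_swap_negates_bias_and_mirrors_loa(self):
        p = _pairs([95, 93, 97, 96], [94, 95, 92, 96])
        a = bland_altman(p, DiffDirection.WIRED_MINUS_WIRELESS)
        b = bland_altman(p, DiffDirection.WIRELESS_MINUS_WIRED)
        assert a.bias == -b.bias
        assert a.loa_low == pytest.approx(-b.loa_high)
        assert a.loa_high == pytest.approx(-b.loa_low)

    def test_single_pair_is_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(_pairs([95], [94]))

    @given(
        st.lists(
            st.tuples(st.floats(50, 100), st.floats(50, 100)),
            min_size=2, max_size=50,
        )
    )
    def test_structural_invariants(self, pts):
        wired, wireless = zip(*pts)
        s = bland_altman(_pairs(wired, wireless))
        assert s.loa_high - s.loa_low == pytest.approx(2 * s.moe, abs=1e-9)
        assert s.mae >= abs(s.bias) - 1e-12
        assert s.mae >= 0.0


class TestAggregateDaily:
    def _summary(self, bias):
        return AgreementSummary(10, bias, 1.0, bias - 1.96, bias + 1.96,
                                1.96, abs(bias))

    def test_single_day_is_degenerate(self):
        agg = aggregate_daily([self._summary(1.5)])
        assert agg.loc["bias", "median"] == 1.5
        assert agg.loc["bias", "q1"] == agg.loc["bias", "q3"] == 1.5

    def test_median_of_three(self):
        agg = aggregate_daily([self._summary(b) for b in (1.0, 2.0, 3.0)])
        assert agg.loc["bias", "median"] == 2.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_daily([])


class TestOxygenGroup:
    def _fio2(self, values):
        return TimeSeriesChannel(ChannelRole.FIO2, 0.0, 1.0,
                                 np.asarray(values, dtype=float))

    def test_constant_room_air(self):
        assert classify_oxygen_group(self._fio2([0.21] * 100)) is (
            OxygenGroup.ROOM_AIR
        )

    def test_supplemental_for_majority_of_day(self):
        v = [0.30] * 60 + [0.21] * 40
        assert classify_oxygen_group(self._fio2(v)) is OxygenGroup.SUPPLEMENTAL

    def test_exactly_half_is_room_air(self):
        v = [0.30] * 50 + [0.21] * 50
        assert classify_oxygen_group(self._fio2(v)) is OxygenGroup.ROOM_AIR

    def test_fraction_uses_valid_samples_only(self):
        v = np.array([0.30] * 30 + [0.21] * 20 + [np.nan] * 50)
        assert classify_oxygen_group(self._fio2(v)) is OxygenGroup.SUPPLEMENTAL

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            classify_oxygen_group(self._fio2([np.nan] * 10))


# ---------------------------------------------------------------------------
# Modified error grid
# ---------------------------------------------------------------------------

# Independent oracle: clinical decision per value, then a decision table.
def _decision(v, group):
    if group is OxygenGroup.ROOM_AIR:
        return "treat_low" if v <= 91 else "none"
    if v <= 88:
        return "treat_low"
    if v > 95:
        return "treat_high"
    return "none"


_DECISION_TABLE = {
    ("none", "treat_low"): Region.C,
    ("none", "treat_high"): Region.C,
    ("treat_low", "none"): Region.D,
    ("treat_high", "none"): Region.D,
    ("treat_low", "treat_high"): Region.E,
    ("treat_high", "treat_low"): Region.E,
}


def oracle_region(ref, test, group):
    dr, dt = _decision(ref, group), _decision(test, group)
    if dr == dt:
        return Region.A if abs(test - ref) <= 5 else Region.B
    return _DECISION_TABLE[(dr, dt)]


class TestErrorGrid:
    def test_both_low_and_close_is_region_a(self):
        assert ega_classify(90, 89, OxygenGroup.ROOM_AIR) is Region.A

    def test_missed_high_is_failure_to_treat(self):
        assert ega_classify(97, 92, OxygenGroup.SUPPLEMENTAL) is Region.D

    def test_opposite_states_is_region_e(self):
        assert ega_classify(98, 85, OxygenGroup.SUPPLEMENTAL) is Region.E

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            ega_classify(101, 95, OxygenGroup.ROOM_AIR)

    @pytest.mark.parametrize("group", list(OxygenGroup))
    def test_matches_brute_force_oracle_on_full_integer_grid(self, group):
        for ref in range(50, 101):
            for test in range(50, 101):
                assert ega_classify(ref, test, group) is oracle_region(
                    ref, test, group
                ), (ref, test, group)

    def test_region_e_unreachable_in_room_air(self):
        regions = {
            ega_classify(r, t, OxygenGroup.ROOM_AIR)
            for r in range(50, 101)
            for t in range(50, 101)
        }
        assert Region.E not in regions

    def test_summary_of_identical_series_is_all_region_a(self):
        s = ega_summary(_pairs([95] * 10, [95] * 10), OxygenGroup.ROOM_AIR)
        assert s.region_proportions[Region.A] == 1.0

    def test_summary_matches_hand_labels(self):
        wired = [97, 97, 90, 90, 85, 98, 93, 93, 96, 89]
        wireless = [96, 90, 89, 97, 96, 85, 92, 85, 91, 88]
        labels = [oracle_region(r, t, OxygenGroup.SUPPLEMENTAL)
                  for r, t in zip(wired, wireless)]
        s = ega_summary(_pairs(wired, wireless), OxygenGroup.SUPPLEMENTAL)
        for region in Region:
            assert s.region_counts[region] == labels.count(region)
        assert sum(s.region_proportions.values()) == pytest.approx(1.0)

    def test_all_missed_highs_are_100_percent_region_d(self):
        s = ega_summary(_pairs([97] * 20, [92] * 20), OxygenGroup.SUPPLEMENTAL)
        assert s.region_proportions[Region.D] == 1.0


class TestErrorBySnr:
    def _snr(self, centers, vals):
        return SNRSeries(np.asarray(centers, dtype=float),
                         np.asarray(vals, dtype=float), 30.0, 0.5)

    def test_single_bin_reproduces_global_mae(self):
        p = _pairs([95, 95, 95, 95], [94, 94, 94, 92])
        snr = self._snr([0, 2], [5.0, 5.0])
        m = error_by_snr(p, snr, snr, bin_edges_db=[-10, 10])
        assert m.mae[0, 0] == pytest.approx(1.5)
        assert m.counts[0, 0] == 4
        assert m.low_n[0, 0]

    def test_bin_edges_are_left_inclusive(self):
        p = _pairs([95, 95], [94, 94])
        snr_on_edge = self._snr([0, 1], [0.0, 0.0])  # exactly on the edge
        m = error_by_snr(p, snr_on_edge, snr_on_edge, bin_edges_db=[-10, 0, 10])
        assert m.counts[1, 1] == 2
        assert m.counts[0, 0] == 0

    def test_mae_decreases_with_wireless_snr_in_simulation(self):
        # device noise rises as scheduled SNR falls: MAE per wireless-SNR
        # bin must be non-increasing left to right
        rng = np.random.default_rng(5)
        n = 3000
        snr_vals = np.repeat([-5.0, 0.0, 5.0], n)
        noise_sd = np.repeat([3.0, 2.0, 1.0], n)
        wired = np.full(3 * n, 95.0)
        wireless = wired - 1.0 + noise_sd * rng.standard_normal(3 * n)
        p = PairedSpO2Series(np.arange(3 * n, dtype=float), wired,
                             np.clip(wireless, 0, 100))
        centers = np.arange(3 * n, dtype=float)
        snr_wl = self._snr(centers, snr_vals)
        snr_wd = self._snr(centers, np.full(3 * n, 7.0))
        m = error_by_snr(p, snr_wd, snr_wl, bin_edges_db=[-10, -2.5, 2.5, 10])
        row = m.mae[2]  # wired bin containing 7 dB
        assert row[0] >= row[1] >= row[2]
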