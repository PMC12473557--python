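"""Sample-to-sample SpO2 agreement and the modified Clarke Error Grid.

The wired bedside monitor is the reference throughout. Differences are
oriented ``d = wired - wireless`` by default, so a positive bias means the
wireless sensor reads low. Agreement per recording day is summarised by
the Bland-Altman bias (mean difference), the 95% limits of agreement
``bias +/- 1.96 sd``, the margin of error ``MoE = 1.96 sd`` and the mean
absolute error; days are aggregated by median and IQR.

Clinical relevance is judged with a modified Clarke Error Grid whose
state boundaries follow neonatal oxygen-saturation alarm targets:
infants off supplemental oxygen target SpO2 > 91% (alarm at <= 91), and
infants on supplemental oxygen target > 88% and <= 95% (low at <= 88,
high at > 95). Region A pairs agree within 5 percentage points and imply
the same clinical action; B agrees on the action but differs by more
than 5 points; C would trigger unnecessary treatment (false positive);
D would fail to treat (false negative); E would reverse treatment.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feasibility import SNRSeries
from .io_recordings import ChannelRole, TimeSeriesChannel

__all__ = [
    "OxygenGroup",
    "Region",
    "DiffDirection",
    "OxygenTargets",
    "PairedSpO2Series",
    "AgreementSummary",
    "EGASummary",
    "SNRErrorMap",
    "pair_samples",
    "bland_altman",
    "aggregate_daily",
    "classify_oxygen_group",
    "ega_classify",
    "ega_summary",
    "error_by_snr",
    "experimental_effect_size",
]


class OxygenGroup(str, enum.Enum):
    ROOM_AIR = "ROOM_AIR"
    SUPPLEMENTAL = "SUPPLEMENTAL"


class Region(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"


class DiffDirection(str, enum.Enum):
    WIRED_MINUS_WIRELESS = "WIRED_MINUS_WIRELESS"
    WIRELESS_MINUS_WIRED = "WIRELESS_MINUS_WIRED"


@dataclass(frozen=True)
class OxygenTargets:
    """Alarm-threshold boundaries for the two oxygen groups."""

    room_air_low: float = 91.0   # alarm at values <= room_air_low
    supp_low: float = 88.0       # low at values <= supp_low
    supp_high: float = 95.0      # high at values > supp_high
    within_band: float = 5.0     # region-A agreement band, percentage points

    def __post_init__(self):
        if not self.supp_low < self.supp_high:
            raise ValueError("supp_low must be below supp_high")
        if self.within_band <= 0:
            raise ValueError("within_band must be positive")


@dataclass
class PairedSpO2Series:
    """Instants where both the wired and wireless SpO2 values are valid."""

    times_s: np.ndarray
    wired_pct: np.ndarray
    wireless_pct: np.ndarray

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.wired_pct = np.asarray(self.wired_pct, dtype=float)
        self.wireless_pct = np.asarray(self.wireless_pct, dtype=float)
        if not (self.times_s.size == self.wired_pct.size == self.wireless_pct.size):
            raise ValueError("paired series arrays must have equal lengths")

    @property
    def n_pairs(self) -> int:
        return int(self.times_s.size)


@dataclass(frozen=True)
class AgreementSummary:
    n_pairs: int
    bias: float       # mean difference d-bar, percentage points
    sd_d: float       # sample SD of differences (n-1)
    loa_low: float    # bias - 1.96 sd
    loa_high: float   # bias + 1.96 sd
    moe: float        # 1.96 sd
    mae: float        # mean absolute difference


@dataclass
class EGASummary:
    group: OxygenGroup
    region_counts: dict[Region, int]
    region_proportions: dict[Region, float]

    @property
    def n_pairs(self) -> int:
        return sum(self.region_counts.values())


def pair_samples(
    wired_spo2: TimeSeriesChannel,
    wireless_spo2: TimeSeriesChannel,
) -> PairedSpO2Series:
    """Retain exactly the instants where both 1 Hz channels are valid.

    Both channels must sit on the common synchronized 1 Hz grid (equal
    rates, start times differing by an integer number of periods).
    """
    a, b = wired_spo2, wireless_spo2
    if not math.isclose(a.nominal_rate, b.nominal_rate):
        raise ValueError("channels have different rates; synchronize/resample first")
    p = a.period_s
    shift = (b.start_time - a.start_time) / p
    if abs(shift - round(shift)) > 1e-6:
        raise ValueError("channel grids are misaligned; synchronize first")
    shift = int(round(shift))
    # overlap in a's index space
    lo = max(0, shift)
    hi = min(a.n_samples, shift + b.n_samples)
    if hi <= lo:
        return PairedSpO2Series(np.empty(0), np.empty(0), np.empty(0))
    ia = np.arange(lo, hi)
    ib = ia - shift
    va, vb = a.values[ia], b.values[ib]
    both = ~np.isnan(va) & ~np.isnan(vb)
    times = a.start_time + ia[both] * p
    return PairedSpO2Series(times, va[both], vb[both])


def bland_altman(
    pairs: PairedSpO2Series,
    direction: DiffDirection = DiffDirection.WIRED_MINUS_WIRELESS,
) -> AgreementSummary:
    """Bland-Altman agreement summary of a paired series."""
    if pairs.n_pairs < 2:
        raise ValueError("need at least two pairs for agreement analysis")
    if direction is DiffDirection.WIRED_MINUS_WIRELESS:
        d = pairs.wired_pct - pairs.wireless_pct
    else:
        d = pairs.wireless_pct - pairs.wired_pct
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    moe = 1.96 * sd
    return AgreementSummary(
        n_pairs=pairs.n_pairs,
        bias=bias,
        sd_d=sd,
        loa_low=bias - moe,
        loa_high=bias + moe,
        moe=moe,
        mae=float(np.abs(d).mean()),
    )


_METRICS = ("bias", "sd_d", "loa_low", "loa_high", "moe", "mae")


def aggregate_daily(summaries: list[AgreementSummary]) -> pd.DataFrame:
    """Median and IQR of each agreement metric across recording days.

    Quantiles use linear interpolation. Returns a DataFrame indexed by
    metric with columns ``median``, ``q1``, ``q3``.
    """
    if not summaries:
        raise ValueError("need at least one daily summary")
    rows = {}
    for m in _METRICS:
        v = np.array([getattr(s, m) for s in summaries], dtype=float)
        rows[m] = {
            "median": float(np.quantile(v, 0.5)),
            "q1": float(np.quantile(v, 0.25)),
            "q3": float(np.quantile(v, 0.75)),
        }
    return pd.DataFrame(rows).T[["median", "q1", "q3"]]


def classify_oxygen_group(fio2: TimeSeriesChannel) -> OxygenGroup:
    """Supplemental oxygen iff FiO2 > 0.21 for strictly more than half of
    the valid samples; the fraction is computed over valid samples only."""
    if fio2.channel_id is not ChannelRole.FIO2:
        raise ValueError("expected the FiO2 channel")
    v = fio2.values[~np.isnan(fio2.values)]
    if v.size == 0:
        raise ValueError("no valid FiO2 samples")
    frac = float((v > 0.21 + 1e-12).mean())
    return OxygenGroup.SUPPLEMENTAL if frac > 0.5 else OxygenGroup.ROOM_AIR


# clinical states
_LOW, _IN_RANGE, _HIGH = -1, 0, 1


def _state(value: float, group: OxygenGroup, targets: OxygenTargets) -> int:
    if group is OxygenGroup.ROOM_AIR:
        return _LOW if value <= targets.room_air_low else _IN_RANGE
    if value <= targets.supp_low:
        return _LOW
    if value > targets.supp_high:
        return _HIGH
    return _IN_RANGE


def ega_classify(
    ref_pct: float,
    test_pct: float,
    group: OxygenGroup,
    targets: OxygenTargets = OxygenTargets(),
) -> Region:
    """Region of one (reference, test) pair on the modified error grid.

    State agreement takes precedence over the 5-point band: pairs in the
    same clinical state are A/B depending on |test - ref|; pairs in
    different states are C (test falsely actionable), D (test misses an
    actionable reference) or E (opposite actionable states).
    """
    for v in (ref_pct, test_pct):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"SpO2 value {v} outside [0, 100]")
    s_ref = _state(ref_pct, group, targets)
    s_test = _state(test_pct, group, targets)
    if s_ref == s_test:
        return Region.A if abs(test_pct - ref_pct) <= targets.within_band else Region.B
    if s_ref != _IN_RANGE and s_test != _IN_RANGE:
        return Region.E  # opposite actionable states
    if s_ref != _IN_RANGE:  # reference actionable, test in range
        return Region.D
    return Region.C  # reference in range, test actionable


def ega_summary(
    pairs: PairedSpO2Series,
    group: OxygenGroup,
    targets: OxygenTargets = OxygenTargets(),
) -> EGASummary:
    """Per-sample grid classification (wired as reference) with counts and
    proportions per region."""
    if pairs.n_pairs < 1:
        raise ValueError("need at least one pair")
    counts = {r: 0 for r in Region}
    for ref, test in zip(pairs.wired_pct, pairs.wireless_pct):
        counts[ega_classify(float(ref), float(test), group, targets)] += 1
    n = pairs.n_pairs
    props = {r: c / n for r, c in counts.items()}
    return EGASummary(group=group, region_counts=counts, region_proportions=props)


@dataclass
class SNRErrorMap:
    """Per-cell MAE/MoE stratified by wired and wireless PPG SNR bins.

    Bins follow the right-open convention: edge ``e_i`` belongs to the
    cell ``[e_i, e_{i+1})``. ``low_n`` flags cells with fewer than 30
    pairs.
    """

    bin_edges_db: np.ndarray
    mae: np.ndarray     # shape (n_bins, n_bins): wired rows, wireless cols
    moe: np.ndarray
    counts: np.ndarray
    low_n: np.ndarray


def _nearest_snr(times_s: np.ndarray, snr: SNRSeries) -> np.ndarray:
    centers = snr.window_centers_s
    if centers.size == 0:
        return np.full(times_s.size, np.nan)
    idx = np.clip(np.searchsorted(centers, times_s), 1, centers.size - 1)
    left = idx - 1
    pick = np.where(
        np.abs(times_s - centers[left]) <= np.abs(times_s - centers[idx]), left, idx
    )
    return snr.snr_db[pick]


def error_by_snr(
    pairs: PairedSpO2Series,
    snr_wired: SNRSeries,
    snr_wireless: SNRSeries,
    bin_edges_db,
    direction: DiffDirection = DiffDirection.WIRED_MINUS_WIRELESS,
    low_n_threshold: int = 30,
) -> SNRErrorMap:
    """Bivariate MAE/MoE map over (wired-SNR, wireless-SNR) bins.

    Each pair is assigned the SNR of the nearest estimation window on each
    device; pairs whose SNR is missing or outside the outer edges are
    dropped. Empty cells hold NaN.
    """
    edges = np.asarray(bin_edges_db, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges_db must be increasing with >= 2 edges")
    nb = edges.size - 1
    mae = np.full((nb, nb), np.nan)
    moe = np.full((nb, nb), np.nan)
    counts = np.zeros((nb, nb), dtype=int)

    if pairs.n_pairs:
        sw = _nearest_snr(pairs.times_s, snr_wired)
        sl = _nearest_snr(pairs.times_s, snr_wireless)
        if direction is DiffDirection.WIRED_MINUS_WIRELESS:
            d = pairs.wired_pct - pairs.wireless_pct
        else:
            d = pairs.wireless_pct - pairs.wired_pct
        ok = np.isfinite(sw) & np.isfinite(sl)
        # right-open binning: edges[i] <= x < edges[i+1]
        bi = np.digitize(sw[ok], edges) - 1
        bj = np.digitize(sl[ok], edges) - 1
        dd = d[ok]
        inside = (bi >= 0) & (bi < nb) & (bj >= 0) & (bj < nb)
        for i, j, dv in zip(bi[inside], bj[inside], dd[inside]):
            counts[i, j] += 1
        for i in range(nb):
            for j in range(nb):
                cell = dd[inside & (bi == i) & (bj == j)]
                if cell.size:
                    mae[i, j] = float(np.abs(cell).mean())
                    if cell.size >= 2:
                        moe[i, j] = 1.96 * float(cell.std(ddof=1))
    return SNRErrorMap(
        bin_edges_db=edges,
        mae=mae,
        moe=moe,
        counts=counts,
        low_n=counts < low_n_threshold,
    )


def experimental_effect_size(
    sd_d: float, n: int, alpha: float = 0.05, power: float = 0.90
) -> float:
    """Minimally detectable mean difference (EXPERIMENTAL, unverified).

    ``(z_{1-alpha/2} + z_{power}) * sd_d / sqrt(n)``. Provided behind this
    clearly labelled helper only; its correspondence to any published
    effect-size column is not established.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    return float(
        (stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)) * sd_d / math.sqrt(n)
    )
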