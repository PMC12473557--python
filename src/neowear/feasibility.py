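"""Signal coverage, gap detection, PPG signal-to-noise and gap-cause attribution.

Feasibility of a wireless sensor is judged against the planned monitoring
period: a *gap* is a maximal missing-data run whose duration strictly
exceeds a channel-specific threshold (31.25 ms for PPG, 2 s for SpO2), and
*coverage* is the percentage of the planned period not taken up by gaps.
Detected gaps are attributed to one of four causes with a fixed-precedence
decision tree — Bluetooth disconnection (device flag), sensor
removal/adjustment (bedside annotation), low PPG signal quality
(flanking-window SNR below 0 dB), or unknown — and tagged with the care
activity in progress at the gap midpoint.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal
from scipy import stats

from .io_recordings import (
    ACTIVITY_LABELS,
    PPG_ROLES,
    SENSOR_EVENT_LABELS,
    AnnotationEvent,
    ChannelRole,
    DeviceFlag,
    FlagType,
    TimeSeriesChannel,
)
from .safety import Direction, SignedRankResult, ZeroHandling, wilcoxon_signed_rank

__all__ = [
    "GapCause",
    "GapThresholds",
    "Gap",
    "SNRSeries",
    "CoverageResult",
    "RankSumResult",
    "detect_gaps",
    "coverage",
    "estimate_snr",
    "attribute_gaps",
    "compare_paired",
    "compare_unpaired",
]


class GapCause(str, enum.Enum):
    BD = "BD"            # Bluetooth disconnection
    SR_SA = "SR_SA"      # sensor removed or adjusted
    LOW_SNR = "LOW_SNR"  # PPG noise exceeded signal (< 0 dB)
    UNKNOWN = "UNKNOWN"
    CABLE = "CABLE"      # wired-line disconnection


@dataclass(frozen=True)
class GapThresholds:
    """Minimum missing-run durations (strictly exceeded) that count as gaps."""

    ppg_gap_s: float = 0.03125  # two samples at 64 Hz
    spo2_gap_s: float = 2.0

    def __post_init__(self):
        if self.ppg_gap_s <= 0 or self.spo2_gap_s <= 0:
            raise ValueError("gap thresholds must be positive")

    def for_channel(self, role: ChannelRole) -> float:
        return self.ppg_gap_s if role in PPG_ROLES else self.spo2_gap_s


@dataclass
class Gap:
    channel_id: ChannelRole
    start_s: float
    end_s: float
    cause: GapCause = GapCause.UNKNOWN
    activity: str = "NONE"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass
class SNRSeries:
    """Windowed PPG signal-to-noise estimates on the decibel scale."""

    window_centers_s: np.ndarray
    snr_db: np.ndarray
    window_length_s: float
    overlap_fraction: float

    def median_db(self) -> float:
        v = self.snr_db[np.isfinite(self.snr_db)]
        return float(np.median(v)) if v.size else float("nan")


@dataclass(frozen=True)
class CoverageResult:
    channel_id: ChannelRole
    coverage_pct: float
    total_gap_time_s: float
    n_gaps: int


def _missing_intervals(
    channel: TimeSeriesChannel, planned_duration_s: float
) -> list[tuple[float, float]]:
    """Maximal missing intervals over [0, planned_duration_s)."""
    if planned_duration_s <= 0:
        raise ValueError("planned_duration_s must be positive")
    p = channel.period_s
    intervals: list[tuple[float, float]] = []
    if channel.n_samples == 0:
        return [(0.0, planned_duration_s)]
    if channel.start_time > 1e-9:
        intervals.append((0.0, channel.start_time))
    miss = channel.is_missing()
    if miss.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([False], miss, [False]))))
        starts, ends = edges[::2], edges[1::2]
        for i0, i1 in zip(starts, ends):
            intervals.append(
                (channel.start_time + i0 * p, channel.start_time + i1 * p)
            )
    grid_end = channel.end_time
    if grid_end < planned_duration_s - 1e-9:
        intervals.append((grid_end, planned_duration_s))
    # merge intervals that touch (shared endpoint from the same arithmetic)
    intervals.sort()
    merged: list[tuple[float, float]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] <= 1e-9:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def detect_gaps(
    channel: TimeSeriesChannel,
    thresholds: GapThresholds,
    planned_duration_s: float,
) -> list[Gap]:
    """Missing runs strictly longer than the channel's threshold.

    Leading and trailing time not covered by the sample grid counts as
    missing relative to the planned monitoring period. A run whose
    duration equals the threshold exactly is not a gap.
    """
    thr = thresholds.for_channel(channel.channel_id)
    gaps = []
    for s, e in _missing_intervals(channel, planned_duration_s):
        if (e - s) > thr * (1 + 1e-12) + 1e-12:
            gaps.append(Gap(channel.channel_id, s, e))
    return gaps


def coverage(
    channel: TimeSeriesChannel,
    thresholds: GapThresholds,
    planned_duration_s: float,
) -> CoverageResult:
    """Percentage of the planned period not occupied by detected gaps."""
    gaps = detect_gaps(channel, thresholds, planned_duration_s)
    gap_time = float(sum(g.duration_s for g in gaps))
    return CoverageResult(
        channel_id=channel.channel_id,
        coverage_pct=100.0 * (planned_duration_s - gap_time) / planned_duration_s,
        total_gap_time_s=gap_time,
        n_gaps=len(gaps),
    )


def estimate_snr(
    ppg: TimeSeriesChannel,
    window_s: float = 30.0,
    overlap: float = 0.5,
    peak_band_hz: tuple[float, float] = (1.0, 4.0),
    band_halfwidth_hz: float = 0.3,
    noise_band_hz: tuple[float, float] = (0.1, 10.0),
    cap_db: float = 40.0,
    min_valid_frac: float = 0.5,
) -> SNRSeries:
    """Windowed periodogram SNR of a PPG channel, in dB.

    Per window: the periodogram of the mean-removed samples is searched
    for the cardiac peak in ``peak_band_hz``; signal power is the power
    within ``band_halfwidth_hz`` of the peak and of its first harmonic,
    noise power is the remaining power inside ``noise_band_hz``, and
    ``snr_db = 10 log10(signal/noise)`` capped at ``+/-cap_db``. Windows
    with fewer than ``min_valid_frac`` valid samples, or with no spectral
    peak, yield NaN. Missing samples inside an accepted window are
    zero-filled after mean removal, which attenuates signal and noise
    alike and leaves the ratio approximately unchanged.

    The estimate is invariant to overall amplitude scaling.
    """
    fs = ppg.nominal_rate
    nwin = int(round(window_s * fs))
    if nwin < 8:
        raise ValueError("window too short for spectral estimation")
    hop = max(1, int(round(nwin * (1.0 - overlap))))
    starts = np.arange(0, max(ppg.n_samples - nwin + 1, 0), hop)
    centers = ppg.start_time + (starts + nwin / 2.0) / fs
    out = np.full(starts.size, np.nan)

    f = np.fft.rfftfreq(nwin, d=1.0 / fs)
    in_peak = (f >= peak_band_hz[0]) & (f <= peak_band_hz[1])
    in_noise_band = (f >= noise_band_hz[0]) & (f <= noise_band_hz[1])

    for k, i0 in enumerate(starts):
        seg = ppg.values[i0:i0 + nwin]
        valid = ~np.isnan(seg)
        if valid.mean() < min_valid_frac:
            continue
        x = seg - np.nanmean(seg)
        x = np.where(valid, x, 0.0)
        _, pxx = sp_signal.periodogram(x, fs=fs, window="boxcar", detrend=False)
        if not in_peak.any() or pxx[in_peak].max() <= 0:
            continue
        f_peak = f[in_peak][int(np.argmax(pxx[in_peak]))]
        sig_mask = (np.abs(f - f_peak) <= band_halfwidth_hz) | (
            np.abs(f - 2 * f_peak) <= band_halfwidth_hz
        )
        p_sig = float(pxx[sig_mask & in_noise_band].sum())
        p_noise = float(pxx[in_noise_band & ~sig_mask].sum())
        if p_noise <= 0:
            out[k] = cap_db
        elif p_sig <= 0:
            out[k] = -cap_db
        else:
            out[k] = float(np.clip(10.0 * math.log10(p_sig / p_noise),
                                   -cap_db, cap_db))
    return SNRSeries(
        window_centers_s=np.asarray(centers, dtype=float),
        snr_db=out,
        window_length_s=window_s,
        overlap_fraction=overlap,
    )


def _flanking_snr_db(gap: Gap, snr: SNRSeries, flank_s: float) -> float:
    c = snr.window_centers_s
    mask = ((c >= gap.start_s - flank_s) & (c <= gap.start_s)) | (
        (c >= gap.end_s) & (c <= gap.end_s + flank_s)
    )
    vals = snr.snr_db[mask]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def attribute_gaps(
    gaps: list[Gap],
    flags: list[DeviceFlag],
    annotations: list[AnnotationEvent],
    snr: SNRSeries | None = None,
    context_pad_s: float = 5.0,
    flank_s: float = 30.0,
) -> list[Gap]:
    """Fill gap causes with the fixed-precedence decision tree.

    Per gap, the first matching rule wins:

    1. overlaps a Bluetooth-disconnect flag (padded by ``context_pad_s``)
       → ``BD``;
    2. overlaps a sensor removed/adjusted annotation (padded) → ``SR_SA``;
    3. mean SNR of the windows flanking the gap within ``flank_s`` is
       below 0 dB → ``LOW_SNR``;
    4. otherwise ``UNKNOWN`` — except on the wired PPG channel, where an
       unexplained hard dropout can only be a cable disconnection and is
       labelled ``CABLE``.

    The activity tag is the annotated care activity covering the gap
    midpoint, else ``NONE``.
    """
    bt_flags = [fl for fl in flags if fl.flag_type is FlagType.BT_DISCONNECT]
    sensor_events = [a for a in annotations if a.label in SENSOR_EVENT_LABELS]
    activities = [a for a in annotations if a.label in ACTIVITY_LABELS]
    out = []
    for gap in gaps:
        lo, hi = gap.start_s - context_pad_s, gap.end_s + context_pad_s
        if any(fl.overlaps(lo, hi) for fl in bt_flags):
            cause = GapCause.BD
        elif any(a.overlaps(lo, hi) for a in sensor_events):
            cause = GapCause.SR_SA
        elif snr is not None and _flanking_snr_db(gap, snr, flank_s) < 0.0:
            cause = GapCause.LOW_SNR
        elif gap.channel_id is ChannelRole.WIRED_PPG:
            cause = GapCause.CABLE
        else:
            cause = GapCause.UNKNOWN
        activity = "NONE"
        for a in activities:
            if a.covers(gap.midpoint_s):
                activity = a.label.value
                break
        out.append(replace(gap, cause=cause, activity=activity))
    return out


# ---------------------------------------------------------------------------
# Per-day statistical comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first sample
    z: float
    p_two_sided: float
    n1: int
    n2: int


def compare_paired(
    metric_a,
    metric_b,
    zero_handling: ZeroHandling = ZeroHandling.DROP,
    tie_correction: bool = False,
) -> SignedRankResult:
    """Wilcoxon signed-rank test on per-day paired metrics (a - b)."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired comparison requires equal-length vectors")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    return wilcoxon_signed_rank(
        a - b,
        zero_handling=zero_handling,
        tie_correction=tie_correction,
        direction=Direction.AFTER_MINUS_BEFORE,  # test the differences as given
    )


def compare_unpaired(
    samples_a,
    samples_b,
    tie_correction: bool = False,
) -> RankSumResult:
    """Wilcoxon rank-sum test; statistic is the rank sum of the first group.

    Normal approximation without continuity correction; mid-ranks on ties,
    with the tie term subtracted from the variance only on request.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    var = n1 * n2 * (n + 1) / 12.0
    if tie_correction:
        _, counts = np.unique(pooled, return_counts=True)
        var -= n1 * n2 * float((counts.astype(float) ** 3 - counts).sum()) / (
            12.0 * n * (n - 1)
        )
    if var <= 0:
        return RankSumResult(w, float("nan"), float("nan"), n1, n2)
    z = (w - mean) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return RankSumResult(w, float(z), float(p), n1, n2)
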