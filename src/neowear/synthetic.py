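"""Synthetic dual-device recording generator with ground truth.

The generator emulates the statistical structure the analysis modules
assume: a pulsatile PPG at each device's native rate with a scheduled
band-power SNR, a slowly wandering paired SpO2 trace with a constant
device bias and white device noise, Bluetooth-dropout and sensor-removal
gap processes with matching device flags and bedside annotations, an FiO2
profile, and before/after skin-condition scores. Every injected
interruption is recorded in a :class:`GroundTruth` object so downstream
estimators (gap detection, cause attribution, Bland-Altman, oxygen
grouping, SNR estimation) can be closed-loop tested against the
generator's settings.

Identifiability guards: cause attribution is only testable when causes
are separated in time, so randomly drawn dropout intervals falling within
a guard distance of a different-cause interruption are discarded at draw
time, and SpO2 missingness driven by low signal quality is inset inside
each low-SNR schedule segment so the flanking windows used by the
attribution tree sample the degraded signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .feasibility import GapCause
from .io_recordings import (
    AnnotationEvent,
    AnnotationLabel,
    ChannelRole,
    DeviceFlag,
    DualDayRecording,
    FlagType,
    TimeSeriesChannel,
)

__all__ = [
    "DesaturationSpec",
    "BtDropoutSpec",
    "WiredDropoutSpec",
    "SimulationSpec",
    "InjectedGap",
    "GroundTruth",
    "default_wireless_snr_schedule",
    "simulate_ppg",
    "simulate_spo2_pair",
    "inject_gaps",
    "simulate_day",
    "simulate_study",
]

# rng stream labels, so standalone calls stay deterministic per purpose
_STREAMS = {
    "ppg_wired": 1,
    "ppg_wireless": 2,
    "spo2": 3,
    "bd": 4,
    "wired_drops": 5,
    "nscs": 6,
}


def _rng(seed: int, purpose: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[purpose]])


@dataclass(frozen=True)
class DesaturationSpec:
    rate_per_hour: float = 2.0
    depth_pct: float = 10.0
    duration_s: float = 45.0


@dataclass(frozen=True)
class BtDropoutSpec:
    rate_per_hour: float = 0.8
    mean_duration_s: float = 30.0
    min_duration_s: float = 3.0


@dataclass(frozen=True)
class WiredDropoutSpec:
    """Short hard dropouts on the wired channels (cable events etc.)."""

    ppg_rate_per_hour: float = 0.07
    ppg_mean_duration_s: float = 0.7
    spo2_rate_per_hour: float = 3.6
    spo2_mean_duration_s: float = 35.0


def default_wireless_snr_schedule(
    duration_s: float = 8 * 3600.0,
    base_db: float = 5.0,
    low_db: float = -5.0,
    low_minutes_per_hour: float = 20.0,
) -> tuple[tuple[float, float], ...]:
    """Piecewise-constant wireless SNR: the last ``low_minutes_per_hour``
    of each hour degrade to ``low_db``, emulating recurrent episodes of
    poor sensor coupling."""
    sched: list[tuple[float, float]] = []
    t = 0.0
    while t < duration_s:
        sched.append((t, base_db))
        lo = t + 3600.0 - low_minutes_per_hour * 60.0
        if lo < duration_s:
            sched.append((lo, low_db))
        t += 3600.0
    return tuple(sched)


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic infant-day.

    Defaults follow the evaluated study design: 8 h of monitoring, a
    neonatal heart rate of 150 bpm, a wired PPG at its typical signal
    quality, a wireless PPG alternating between good coupling and
    sub-zero-dB episodes, an SpO2 device bias of 1.34 percentage points
    (wired minus wireless) with 2.0 points of device noise, sparse
    Bluetooth dropouts, one sensor adjustment, and room-air FiO2.
    """

    duration_s: float = 8 * 3600.0
    heart_rate_bpm: float = 150.0
    #: piecewise-constant (start_s, snr_db) schedules
    wired_snr_db: tuple[tuple[float, float], ...] = ((0.0, 7.35),)
    wireless_snr_db: tuple[tuple[float, float], ...] = field(
        default_factory=default_wireless_snr_schedule
    )
    spo2_baseline_pct: float = 96.0
    desaturation: DesaturationSpec = DesaturationSpec()
    device_bias_pct: float = 1.34
    device_noise_sd_pct: float = 2.0
    bt_dropout: BtDropoutSpec = BtDropoutSpec()
    wired_dropout: WiredDropoutSpec = WiredDropoutSpec()
    #: (label, start_s, end_s) sensor removal/adjustment intervals
    sensor_removal_events: tuple[tuple[str, float, float], ...] = (
        ("SA", 14400.0, 14520.0),
    )
    #: (label, start_s, end_s) care-activity annotations (no gaps implied)
    care_annotations: tuple[tuple[str, float, float], ...] = (
        ("RC", 7200.0, 8400.0),
        ("KC", 18000.0, 21600.0),
    )
    #: piecewise-constant (start_s, fraction) FiO2 profile
    fio2_profile: tuple[tuple[float, float], ...] = ((0.0, 0.21),)
    #: inset of SpO2 low-SNR missingness inside each low-SNR segment
    low_snr_gap_margin_s: float = 60.0
    #: exclusion distance between randomly drawn and other-cause intervals
    cause_guard_s: float = 40.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart_rate_bpm must be positive")
        for name in ("desaturation", "bt_dropout"):
            obj = getattr(self, name)
            if obj.rate_per_hour < 0:
                raise ValueError(f"{name}.rate_per_hour must be >= 0")
        if self.device_noise_sd_pct < 0:
            raise ValueError("device_noise_sd_pct must be >= 0")
        for sched in (self.wired_snr_db, self.wireless_snr_db, self.fio2_profile):
            starts = [s for s, _ in sched]
            if starts != sorted(starts) or (starts and starts[0] != 0.0):
                raise ValueError("schedules must start at 0 and be sorted")


@dataclass(frozen=True)
class InjectedGap:
    channel_id: ChannelRole
    start_s: float
    end_s: float
    cause: GapCause

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class GroundTruth:
    true_bias_pct: float
    injected_gaps: list[InjectedGap]
    snr_schedule: dict[str, tuple[tuple[float, float], ...]]
    oxygen_group_truth: str
    nscs_before: int | None = None
    nscs_after: int | None = None

    def gaps_for(self, role: ChannelRole) -> list[InjectedGap]:
        return [g for g in self.injected_gaps if g.channel_id is role]


def _schedule_value(schedule, t: np.ndarray) -> np.ndarray:
    starts = np.array([s for s, _ in schedule], dtype=float)
    vals = np.array([v for _, v in schedule], dtype=float)
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, starts.size - 1)
    return vals[idx]


# spectral geometry shared with feasibility.estimate_snr defaults
_BAND_HALFWIDTH = 0.3
_NOISE_BAND = (0.1, 10.0)
_SIG_BANDWIDTH = 4 * _BAND_HALFWIDTH  # fundamental + first harmonic
_NOISE_BANDWIDTH = (_NOISE_BAND[1] - _NOISE_BAND[0]) - _SIG_BANDWIDTH


def _noise_sd_for_snr(snr_db: float, pulse_power: float, fs: float) -> float:
    """White-noise SD realising the scheduled band-power SNR.

    Solves for the noise variance such that, under the periodogram
    band-power estimator (signal = cardiac bands, noise = rest of
    0.1-10 Hz), the expected estimate equals ``snr_db``, accounting for
    the white-noise power that falls inside the cardiac bands. Scheduled
    values below the estimator's white-noise floor (about -8.6 dB) fall
    back to the uncompensated calibration and saturate at the floor.
    """
    if math.isinf(snr_db) and snr_db > 0:
        return 0.0
    ratio = 10.0 ** (snr_db / 10.0)
    half_fs = fs / 2.0
    denom = _NOISE_BANDWIDTH * ratio - _SIG_BANDWIDTH
    if denom > 1e-3:
        var = pulse_power * half_fs / denom
    else:
        var = pulse_power * half_fs / (_NOISE_BANDWIDTH * ratio)
    return math.sqrt(var)


def simulate_ppg(
    spec: SimulationSpec,
    channel_role: ChannelRole,
    rng: np.random.Generator | None = None,
) -> TimeSeriesChannel:
    """Pulsatile PPG waveform with a scheduled band-power SNR.

    The waveform is a fundamental at the heart rate plus one harmonic at
    half amplitude; white noise is scaled per schedule segment so that
    the windowed periodogram SNR matches the scheduled value.
    """
    spec.validate()
    if channel_role not in (ChannelRole.WIRED_PPG, ChannelRole.WIRELESS_PPG):
        raise ValueError("channel_role must be a PPG role")
    wired = channel_role is ChannelRole.WIRED_PPG
    fs = 75.0 if wired else 64.0
    schedule = spec.wired_snr_db if wired else spec.wireless_snr_db
    if rng is None:
        rng = _rng(spec.seed, "ppg_wired" if wired else "ppg_wireless")
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    f0 = spec.heart_rate_bpm / 60.0
    pulse = np.sin(2 * np.pi * f0 * t) + 0.5 * np.sin(4 * np.pi * f0 * t)
    pulse_power = 0.5 * (1.0 + 0.25)
    snr_t = _schedule_value(schedule, t)
    sd = np.array([_noise_sd_for_snr(s, pulse_power, fs)
                   for s in np.unique(snr_t)])
    sd_t = np.zeros(n)
    for s, sdev in zip(np.unique(snr_t), sd):
        sd_t[snr_t == s] = sdev
    values = pulse + sd_t * rng.standard_normal(n)
    return TimeSeriesChannel(channel_role, 0.0, fs, values)


def simulate_spo2_pair(
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[TimeSeriesChannel, TimeSeriesChannel]:
    """Paired 1 Hz SpO2 traces: wired reference and biased/noisy wireless.

    The wired trace is a mean-reverting (Ornstein-Uhlenbeck-style) walk
    around the baseline with a ~5 min relaxation time, emulating the
    autocorrelation left by the monitor's 8 s averaging, plus
    raised-cosine desaturation excursions whose trough reaches exactly
    ``baseline - depth``. The wireless trace is the wired trace minus the
    device bias plus Gaussian device noise, both clipped to [0, 100].
    """
    spec.validate()
    if rng is None:
        rng = _rng(spec.seed, "spo2")
    n = int(round(spec.duration_s))
    theta = 1.0 / 300.0       # 5 min relaxation
    stat_sd = 0.6             # stationary SD of the baseline walk, pct points
    a = math.exp(-theta)
    innov_sd = stat_sd * math.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = stat_sd * rng.standard_normal()
    eps = rng.standard_normal(n)
    for i in range(1, n):
        x[i] = a * x[i - 1] + innov_sd * eps[i]
    wired = spec.spo2_baseline_pct + x

    des = spec.desaturation
    if des.rate_per_hour > 0 and des.duration_s > 0:
        n_events = rng.poisson(des.rate_per_hour * spec.duration_s / 3600.0)
        starts = np.sort(rng.uniform(0, max(spec.duration_s - des.duration_s, 0),
                                     size=n_events))
        floor = spec.spo2_baseline_pct - des.depth_pct
        for s0 in starts:
            i0 = int(round(s0))
            i1 = min(n, i0 + int(round(des.duration_s)))
            tt = np.arange(i1 - i0)
            profile = np.sin(np.pi * (tt + 0.5) / (i1 - i0)) ** 2
            # blend toward the trough so the dip depth is exact
            wired[i0:i1] = (1 - profile) * wired[i0:i1] + profile * floor

    wired = np.clip(wired, 0.0, 100.0)
    wireless = wired - spec.device_bias_pct
    if spec.device_noise_sd_pct > 0:
        wireless = wireless + spec.device_noise_sd_pct * rng.standard_normal(n)
    wireless = np.clip(wireless, 0.0, 100.0)
    return (
        TimeSeriesChannel(ChannelRole.WIRED_SPO2, 0.0, 1.0, wired),
        TimeSeriesChannel(ChannelRole.WIRELESS_SPO2, 0.0, 1.0, wireless),
    )


# ---------------------------------------------------------------------------
# Gap injection
# ---------------------------------------------------------------------------


def _snap(interval: tuple[float, float], rate: float) -> tuple[float, float]:
    a, b = interval
    i0 = math.ceil(a * rate - 1e-9)
    i1 = math.ceil(b * rate - 1e-9)
    return i0 / rate, i1 / rate


_CAUSE_PRECEDENCE = {GapCause.BD: 0, GapCause.SR_SA: 1, GapCause.LOW_SNR: 2,
                     GapCause.CABLE: 3, GapCause.UNKNOWN: 4}


def _merge_causes(
    intervals: list[tuple[float, float, GapCause]], min_sep_s: float
) -> list[tuple[float, float, GapCause]]:
    """Merge overlapping or near-adjacent intervals; the highest-precedence
    cause (BD > SR/SA > LOW_SNR) wins."""
    out: list[list] = []
    for s, e, c in sorted(intervals, key=lambda x: x[0]):
        if out and s - out[-1][1] < min_sep_s:
            out[-1][1] = max(out[-1][1], e)
            if _CAUSE_PRECEDENCE[c] < _CAUSE_PRECEDENCE[out[-1][2]]:
                out[-1][2] = c
        else:
            out.append([s, e, c])
    return [(s, e, c) for s, e, c in out]


def _poisson_intervals(
    rng: np.random.Generator,
    duration_s: float,
    rate_per_hour: float,
    mean_duration_s: float,
    min_duration_s: float,
    blocked: list[tuple[float, float]],
    guard_s: float,
) -> list[tuple[float, float]]:
    """Poisson starts with exponential durations; draws whose guarded span
    intersects a blocked interval are discarded."""
    if rate_per_hour <= 0:
        return []
    out: list[tuple[float, float]] = []
    t = 0.0
    lam = rate_per_hour / 3600.0
    while True:
        t += rng.exponential(1.0 / lam)
        if t >= duration_s:
            break
        dur = max(min_duration_s, rng.exponential(mean_duration_s))
        e = min(t + dur, duration_s)
        lo, hi = t - guard_s, e + guard_s
        if any(b0 < hi and lo < b1 for b0, b1 in blocked):
            continue
        if out and lo < out[-1][1] + guard_s:
            continue
        out.append((t, e))
    return out


def _low_snr_missing_intervals(spec: SimulationSpec) -> list[tuple[float, float]]:
    sched = list(spec.wireless_snr_db) + [(spec.duration_s, 0.0)]
    out = []
    for (s0, v), (s1, _) in zip(sched[:-1], sched[1:]):
        if v < 0:
            lo = s0 + spec.low_snr_gap_margin_s
            hi = min(s1, spec.duration_s) - spec.low_snr_gap_margin_s
            if hi > lo:
                out.append((lo, hi))
    return out


@dataclass
class InjectionResult:
    channel: TimeSeriesChannel
    gaps: list[InjectedGap]
    flags: list[DeviceFlag]
    annotations: list[AnnotationEvent]


def _apply_intervals(
    channel: TimeSeriesChannel,
    intervals: list[tuple[float, float, GapCause]],
) -> tuple[TimeSeriesChannel, list[InjectedGap]]:
    rate = channel.nominal_rate
    values = channel.values.copy()
    lo, hi = channel.start_time, channel.end_time
    clipped = [(max(s, lo), min(e, hi), c) for s, e, c in intervals]
    snapped = [(*_snap((s, e), rate), c) for s, e, c in clipped if e > s]
    snapped = [(s, e, c) for s, e, c in snapped if e > s]
    snapped = _merge_causes(snapped, min_sep_s=2.0 / rate)
    gaps = []
    for s, e, c in snapped:
        i0 = int(round(s * rate))
        i1 = int(round(e * rate))
        values[i0:i1] = np.nan
        gaps.append(InjectedGap(channel.channel_id, s, e, c))
    return (
        TimeSeriesChannel(channel.channel_id, channel.start_time, rate, values),
        gaps,
    )


def inject_gaps(
    channel: TimeSeriesChannel,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    bd_intervals: list[tuple[float, float]] | None = None,
) -> InjectionResult:
    """Inject Bluetooth-dropout and sensor-removal gaps into one channel.

    Bluetooth dropouts are a Poisson process with exponential durations
    (drawn here unless pre-drawn intervals are passed, so a day-level
    simulation can share one draw across channels); sensor events use the
    spec's listed intervals. Matching device flags and annotations are
    emitted so the attribution tree can recover the causes. Overlapping
    injections merge, with cause precedence BD > SR/SA.
    """
    spec.validate()
    sr = [(lbl, s, e) for lbl, s, e in spec.sensor_removal_events]
    if bd_intervals is None:
        if rng is None:
            rng = _rng(spec.seed, "bd")
        bd_intervals = _poisson_intervals(
            rng,
            spec.duration_s,
            spec.bt_dropout.rate_per_hour,
            spec.bt_dropout.mean_duration_s,
            spec.bt_dropout.min_duration_s,
            blocked=[(s, e) for _, s, e in sr]
            + _low_snr_missing_intervals(spec),
            guard_s=spec.cause_guard_s,
        )
    intervals = [(s, e, GapCause.BD) for s, e in bd_intervals]
    intervals += [(s, e, GapCause.SR_SA) for _, s, e in sr]
    new_channel, gaps = _apply_intervals(channel, intervals)
    flags = [DeviceFlag(FlagType.BT_DISCONNECT, s, e) for s, e in bd_intervals]
    annotations = [
        AnnotationEvent(AnnotationLabel(lbl), s, e) for lbl, s, e in sr
    ]
    return InjectionResult(new_channel, gaps, flags, annotations)


# ---------------------------------------------------------------------------
# Day-level composition
# ---------------------------------------------------------------------------


def _fio2_channel(spec: SimulationSpec) -> TimeSeriesChannel:
    t = np.arange(int(round(spec.duration_s)), dtype=float)
    return TimeSeriesChannel(
        ChannelRole.FIO2, 0.0, 1.0, _schedule_value(spec.fio2_profile, t)
    )


def _oxygen_truth(spec: SimulationSpec) -> str:
    sched = list(spec.fio2_profile) + [(spec.duration_s, 0.21)]
    supp = sum(
        max(0.0, min(s1, spec.duration_s) - s0)
        for (s0, v), (s1, _) in zip(sched[:-1], sched[1:])
        if v > 0.21
    )
    return "SUPPLEMENTAL" if supp > 0.5 * spec.duration_s else "ROOM_AIR"


_NSCS_BEFORE = ((3, 74 / 77), (4, 3 / 77))
_NSCS_DELTA = ((-1, 3 / 73), (0, 63 / 73), (1, 7 / 73))


def _draw_nscs(rng: np.random.Generator) -> tuple[int, int]:
    before = int(rng.choice([v for v, _ in _NSCS_BEFORE],
                            p=[p for _, p in _NSCS_BEFORE]))
    delta = int(rng.choice([v for v, _ in _NSCS_DELTA],
                           p=[p for _, p in _NSCS_DELTA]))
    after = int(np.clip(before + delta, 3, 9))
    return before, after


def simulate_day(
    spec: SimulationSpec,
    infant_id: str = "sim",
    day_index: int = 1,
) -> tuple[DualDayRecording, GroundTruth]:
    """Compose one synthetic infant-day with full ground truth.

    All stochastic draws flow from ``spec.seed`` through per-purpose
    substreams, so repeated calls are identical.
    """
    spec.validate()
    wired_ppg = simulate_ppg(spec, ChannelRole.WIRED_PPG,
                             rng=_rng(spec.seed, "ppg_wired"))
    wireless_ppg = simulate_ppg(spec, ChannelRole.WIRELESS_PPG,
                                rng=_rng(spec.seed, "ppg_wireless"))
    wired_spo2, wireless_spo2 = simulate_spo2_pair(spec, rng=_rng(spec.seed, "spo2"))

    sr = [(lbl, s, e) for lbl, s, e in spec.sensor_removal_events]
    sr_intervals = [(s, e) for _, s, e in sr]
    low_snr = _low_snr_missing_intervals(spec)

    bd_rng = _rng(spec.seed, "bd")
    bd_intervals = _poisson_intervals(
        bd_rng,
        spec.duration_s,
        spec.bt_dropout.rate_per_hour,
        spec.bt_dropout.mean_duration_s,
        spec.bt_dropout.min_duration_s,
        blocked=sr_intervals + low_snr,
        guard_s=spec.cause_guard_s,
    )

    wd = spec.wired_dropout
    wired_rng = _rng(spec.seed, "wired_drops")
    blocked_for_wired = bd_intervals + sr_intervals
    wired_ppg_drops = _poisson_intervals(
        wired_rng, spec.duration_s, wd.ppg_rate_per_hour, wd.ppg_mean_duration_s,
        3.0 / 75.0, blocked_for_wired, spec.cause_guard_s,
    )
    wired_spo2_drops = _poisson_intervals(
        wired_rng, spec.duration_s, wd.spo2_rate_per_hour, wd.spo2_mean_duration_s,
        3.0, blocked_for_wired + wired_ppg_drops, spec.cause_guard_s,
    )

    injected: list[InjectedGap] = []

    wireless_ppg, g = _apply_intervals(
        wireless_ppg,
        [(s, e, GapCause.BD) for s, e in bd_intervals]
        + [(s, e, GapCause.SR_SA) for s, e in sr_intervals],
    )
    injected += g
    wireless_spo2, g = _apply_intervals(
        wireless_spo2,
        [(s, e, GapCause.BD) for s, e in bd_intervals]
        + [(s, e, GapCause.SR_SA) for s, e in sr_intervals]
        + [(s, e, GapCause.LOW_SNR) for s, e in low_snr],
    )
    injected += g
    wired_ppg, g = _apply_intervals(
        wired_ppg, [(s, e, GapCause.CABLE) for s, e in wired_ppg_drops]
    )
    injected += g
    wired_spo2, g = _apply_intervals(
        wired_spo2, [(s, e, GapCause.UNKNOWN) for s, e in wired_spo2_drops]
    )
    injected += g

    flags = [DeviceFlag(FlagType.BT_DISCONNECT, s, e) for s, e in bd_intervals]
    annotations = [
        AnnotationEvent(AnnotationLabel(lbl), s, e) for lbl, s, e in sr
    ] + [
        AnnotationEvent(AnnotationLabel(lbl), s, e)
        for lbl, s, e in spec.care_annotations
    ]

    before, after = _draw_nscs(_rng(spec.seed, "nscs"))

    rec = DualDayRecording(
        infant_id=infant_id,
        day_index=day_index,
        channels={
            ChannelRole.WIRED_PPG: wired_ppg,
            ChannelRole.WIRELESS_PPG: wireless_ppg,
            ChannelRole.WIRED_SPO2: wired_spo2,
            ChannelRole.WIRELESS_SPO2: wireless_spo2,
            ChannelRole.FIO2: _fio2_channel(spec),
        },
        annotations=annotations,
        flags=flags,
        planned_duration_s=spec.duration_s,
    )
    rec.validate()
    gt = GroundTruth(
        true_bias_pct=spec.device_bias_pct,
        injected_gaps=injected,
        snr_schedule={
            "wired": tuple(spec.wired_snr_db),
            "wireless": tuple(spec.wireless_snr_db),
        },
        oxygen_group_truth=_oxygen_truth(spec),
        nscs_before=before,
        nscs_after=after,
    )
    return rec, gt


def simulate_study(
    n_days: int = 96,
    n_supplemental_days: int = 15,
    base_spec: SimulationSpec | None = None,
    seed: int = 0,
    days_per_infant: int = 4,
) -> list[tuple[DualDayRecording, GroundTruth]]:
    """Simulate a study of ``n_days`` infant-days.

    The first ``n_supplemental_days`` days receive a constant FiO2 of
    0.30 (supplemental oxygen); the rest stay on room air. Each day gets
    its own seed derived from ``seed``.
    """
    from dataclasses import replace as dc_replace

    if base_spec is None:
        base_spec = SimulationSpec()
    out = []
    for d in range(n_days):
        fio2 = ((0.0, 0.30),) if d < n_supplemental_days else ((0.0, 0.21),)
        spec = dc_replace(
            base_spec,
            fio2_profile=fio2,
            seed=int(np.random.SeedSequence([seed, d]).generate_state(1)[0] % (2**31)),
        )
        infant = f"infant{d // days_per_infant + 1:02d}"
        day = d % days_per_infant + 1
        out.append(simulate_day(spec, infant_id=infant, day_index=day))
    return out
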