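"""Data model and I/O for paired wired/wireless infant-day recordings.

A recording day pairs a standard wired bedside monitor (PPG nominally at
75 Hz, SpO2 at 1 Hz) with a wireless limb oximeter (PPG at 64 Hz, SpO2 at
1 Hz), plus an FiO2 trace, bedside annotations and device alert flags.
Time is seconds from the recording epoch, 0-based; every interval in the
package is half-open ``[start_s, end_s)``.

Missingness is explicit: a missing sample is NaN in the value array, never
a sentinel physiological value, so downstream gap analysis can distinguish
"absent" from "zero".
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChannelRole",
    "AnnotationLabel",
    "FlagType",
    "AnnotationEvent",
    "DeviceFlag",
    "TimeSeriesChannel",
    "DualDayRecording",
    "LoadReport",
    "RecordingSchemaError",
    "MissingChannelError",
    "SynchronizationError",
    "NOMINAL_RATE_HZ",
    "PPG_ROLES",
    "write_recording",
    "load_recording",
    "resample_channel",
    "estimate_offset",
    "synchronize",
]


class ChannelRole(str, enum.Enum):
    """The five signal roles present in every recording day."""

    WIRED_PPG = "WIRED_PPG"
    WIRELESS_PPG = "WIRELESS_PPG"
    WIRED_SPO2 = "WIRED_SPO2"
    WIRELESS_SPO2 = "WIRELESS_SPO2"
    FIO2 = "FIO2"


#: Nominal per-role sampling rates (Hz) after ingestion.
NOMINAL_RATE_HZ: dict[ChannelRole, float] = {
    ChannelRole.WIRED_PPG: 75.0,
    ChannelRole.WIRELESS_PPG: 64.0,
    ChannelRole.WIRED_SPO2: 1.0,
    ChannelRole.WIRELESS_SPO2: 1.0,
    ChannelRole.FIO2: 1.0,
}

PPG_ROLES = frozenset({ChannelRole.WIRED_PPG, ChannelRole.WIRELESS_PPG})

#: Physiological range of present (non-missing) values; PPG is unbounded.
VALUE_RANGE: dict[ChannelRole, tuple[float, float]] = {
    ChannelRole.WIRED_SPO2: (0.0, 100.0),
    ChannelRole.WIRELESS_SPO2: (0.0, 100.0),
    ChannelRole.FIO2: (0.21, 1.0),
}


class AnnotationLabel(str, enum.Enum):
    KC = "KC"    # kangaroo care
    RC = "RC"    # routine care
    PAU = "PAU"  # pause
    SR = "SR"    # sensor removed
    SA = "SA"    # sensor adjusted
    O = "O"      # other
    NONE = "NONE"


#: Labels that describe a care activity (as opposed to a sensor event).
ACTIVITY_LABELS = frozenset(
    {AnnotationLabel.KC, AnnotationLabel.RC, AnnotationLabel.PAU, AnnotationLabel.O}
)
SENSOR_EVENT_LABELS = frozenset({AnnotationLabel.SR, AnnotationLabel.SA})


class FlagType(str, enum.Enum):
    BT_DISCONNECT = "BT_DISCONNECT"
    POOR_CONTACT = "POOR_CONTACT"


class RecordingSchemaError(ValueError):
    """The on-disk tables do not match the documented schema."""


class MissingChannelError(RecordingSchemaError):
    def __init__(self, role: ChannelRole):
        self.role = role
        super().__init__(f"recording is missing required channel role {role.value}")


class SynchronizationError(RuntimeError):
    """Offset estimation failed; pass an explicit offset instead."""


@dataclass(frozen=True)
class AnnotationEvent:
    label: AnnotationLabel
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.end_s < self.start_s:
            raise ValueError(f"annotation end {self.end_s} < start {self.start_s}")

    def overlaps(self, start_s: float, end_s: float) -> bool:
        return self.start_s < end_s and start_s < self.end_s

    def covers(self, t_s: float) -> bool:
        return self.start_s <= t_s < self.end_s


@dataclass(frozen=True)
class DeviceFlag:
    flag_type: FlagType
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.end_s < self.start_s:
            raise ValueError(f"flag end {self.end_s} < start {self.start_s}")

    def overlaps(self, start_s: float, end_s: float) -> bool:
        return self.start_s < end_s and start_s < self.end_s


@dataclass
class TimeSeriesChannel:
    """One uniform-rate signal with explicit missingness.

    ``values[i]`` is the sample at ``start_time + i / nominal_rate``;
    NaN marks a missing sample.
    """

    channel_id: ChannelRole
    start_time: float
    nominal_rate: float
    values: np.ndarray

    def __post_init__(self):
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def period_s(self) -> float:
        return 1.0 / self.nominal_rate

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.nominal_rate

    @property
    def end_time(self) -> float:
        """End of the sample grid (half-open)."""
        return self.start_time + self.duration_s

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.nominal_rate

    def is_missing(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(~np.isnan(self.values)))

    def copy(self) -> "TimeSeriesChannel":
        return replace(self, values=self.values.copy())

    def validate(self) -> None:
        rng = VALUE_RANGE.get(self.channel_id)
        if rng is not None:
            v = self.values[~np.isnan(self.values)]
            if v.size and (v.min() < rng[0] - 1e-9 or v.max() > rng[1] + 1e-9):
                raise ValueError(
                    f"{self.channel_id.value} has present values outside {rng}"
                )


@dataclass
class DualDayRecording:
    """All channels, annotations and flags for one infant-day."""

    infant_id: str
    day_index: int
    channels: dict[ChannelRole, TimeSeriesChannel]
    annotations: list[AnnotationEvent] = field(default_factory=list)
    flags: list[DeviceFlag] = field(default_factory=list)
    planned_duration_s: float = 8 * 3600.0

    def validate(self) -> None:
        if not 1 <= self.day_index <= 4:
            raise ValueError("day_index must be 1..4")
        for role in ChannelRole:
            if role not in self.channels:
                raise MissingChannelError(role)
        for ch in self.channels.values():
            if ch.n_samples and (
                ch.start_time < -1e-9
                or ch.end_time > self.planned_duration_s + 1e-6
            ):
                raise ValueError(
                    f"{ch.channel_id.value} span [{ch.start_time}, {ch.end_time})"
                    f" exceeds [0, {self.planned_duration_s})"
                )
            ch.validate()

    def channel(self, role: ChannelRole) -> TimeSeriesChannel:
        return self.channels[role]


@dataclass
class LoadReport:
    """Bookkeeping produced by :func:`load_recording`."""

    n_rejected: dict[str, int] = field(default_factory=dict)

    @property
    def total_rejected(self) -> int:
        return sum(self.n_rejected.values())


# ---------------------------------------------------------------------------
# File round trip
#
# Long-format samples table (infant_id, day_index, channel_id, t_s, value,
# missing) plus annotation and flag tables and a small JSON meta file
# carrying the planned duration and the exact channel start times/rates.
# CSV and Parquet dialects share the schema.
# ---------------------------------------------------------------------------

_SAMPLE_COLS = ["infant_id", "day_index", "channel_id", "t_s", "value", "missing"]


def _tables(rec: DualDayRecording) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    frames = []
    for role in ChannelRole:
        ch = rec.channels.get(role)
        if ch is None:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "infant_id": rec.infant_id,
                    "day_index": rec.day_index,
                    "channel_id": role.value,
                    "t_s": ch.times(),
                    "value": ch.values,
                    "missing": np.isnan(ch.values),
                }
            )
        )
    samples = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_SAMPLE_COLS)
    )
    annotations = pd.DataFrame(
        [(a.label.value, a.start_s, a.end_s) for a in rec.annotations],
        columns=["label", "start_s", "end_s"],
    )
    flags = pd.DataFrame(
        [(f.flag_type.value, f.start_s, f.end_s) for f in rec.flags],
        columns=["flag_type", "start_s", "end_s"],
    )
    return samples, annotations, flags


def write_recording(rec: DualDayRecording, out_dir: str | Path, dialect: str = "csv") -> Path:
    """Write one recording to ``out_dir`` in the documented column schema.

    Returns the directory path. The write→load round trip is bit-exact.
    """
    if dialect not in ("csv", "parquet"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, annotations, flags = _tables(rec)
    if dialect == "csv":
        samples.to_csv(out / "samples.csv", index=False)
    else:
        samples.to_parquet(out / "samples.parquet", index=False)
    annotations.to_csv(out / "annotations.csv", index=False)
    flags.to_csv(out / "flags.csv", index=False)
    meta = {
        "infant_id": rec.infant_id,
        "day_index": rec.day_index,
        "planned_duration_s": rec.planned_duration_s,
        "channels": {
            role.value: {
                "start_time": rec.channels[role].start_time,
                "nominal_rate": rec.channels[role].nominal_rate,
            }
            for role in rec.channels
        },
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def load_recording(
    path: str | Path, dialect: str = "csv"
) -> tuple[DualDayRecording, LoadReport]:
    """Load a recording written by :func:`write_recording`.

    Out-of-range SpO2/FiO2 values are converted to missing and counted in
    the load report. Non-monotone timestamps within a channel raise
    :class:`RecordingSchemaError`; an absent channel role raises
    :class:`MissingChannelError`.
    """
    root = Path(path)
    if dialect == "csv":
        # round_trip parsing keeps the write->load cycle bit-exact
        samples = pd.read_csv(root / "samples.csv", float_precision="round_trip")
    elif dialect == "parquet":
        samples = pd.read_parquet(root / "samples.parquet")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing_cols = set(_SAMPLE_COLS) - set(samples.columns)
    if missing_cols:
        raise RecordingSchemaError(f"samples table lacks columns {sorted(missing_cols)}")
    meta = json.loads((root / "meta.json").read_text())

    report = LoadReport()
    channels: dict[ChannelRole, TimeSeriesChannel] = {}
    for role in ChannelRole:
        sub = samples[samples["channel_id"] == role.value]
        if sub.empty and role.value not in meta["channels"]:
            raise MissingChannelError(role)
        t = sub["t_s"].to_numpy(dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise RecordingSchemaError(f"{role.value}: timestamps are not monotone")
        values = sub["value"].to_numpy(dtype=float)
        miss = sub["missing"].to_numpy(dtype=bool)
        values = np.where(miss, np.nan, values)
        rng = VALUE_RANGE.get(role)
        if rng is not None:
            bad = ~np.isnan(values) & ((values < rng[0]) | (values > rng[1]))
            if np.any(bad):
                report.n_rejected[role.value] = int(bad.sum())
                values = np.where(bad, np.nan, values)
        ch_meta = meta["channels"].get(role.value, {})
        channels[role] = TimeSeriesChannel(
            channel_id=role,
            start_time=float(ch_meta.get("start_time", t[0] if t.size else 0.0)),
            nominal_rate=float(ch_meta.get("nominal_rate", NOMINAL_RATE_HZ[role])),
            values=values,
        )

    ann_df = pd.read_csv(root / "annotations.csv")
    annotations = [
        AnnotationEvent(AnnotationLabel(r.label), float(r.start_s), float(r.end_s))
        for r in ann_df.itertuples()
    ]
    flag_df = pd.read_csv(root / "flags.csv")
    flags = [
        DeviceFlag(FlagType(r.flag_type), float(r.start_s), float(r.end_s))
        for r in flag_df.itertuples()
    ]
    rec = DualDayRecording(
        infant_id=str(meta["infant_id"]),
        day_index=int(meta["day_index"]),
        channels=channels,
        annotations=annotations,
        flags=flags,
        planned_duration_s=float(meta["planned_duration_s"]),
    )
    rec.validate()
    return rec, report


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample_channel(channel: TimeSeriesChannel, target_rate: float) -> TimeSeriesChannel:
    """Resample onto a uniform grid at ``target_rate`` from ``start_time``.

    PPG channels use linear interpolation between neighbouring samples, but
    never across missing data: an output instant whose enclosing input
    interval touches a missing sample stays missing. SpO2 and FiO2 use
    nearest-neighbour assignment within +/-0.5 s (half the 1 Hz interval).
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if channel.n_samples == 0:
        return replace(channel, nominal_rate=target_rate, values=np.empty(0))
    if math.isclose(target_rate, channel.nominal_rate):
        out = channel.copy()
        out.nominal_rate = target_rate
        return out

    n_out = int(round(channel.duration_s * target_rate))
    t_out = channel.start_time + np.arange(n_out) / target_rate
    valid = ~np.isnan(channel.values)
    out_vals = np.full(n_out, np.nan)

    if channel.channel_id in PPG_ROLES:
        t_in = channel.times()
        if valid.any():
            interp = np.interp(t_out, t_in[valid], channel.values[valid])
            # position of each output instant on the input grid
            pos = (t_out - channel.start_time) * channel.nominal_rate
            left = np.floor(pos + 1e-9).astype(int)
            on_node = np.abs(pos - np.round(pos)) < 1e-9
            left = np.clip(left, 0, channel.n_samples - 1)
            right = np.clip(left + 1, 0, channel.n_samples - 1)
            ok = np.where(on_node, valid[np.clip(np.round(pos).astype(int), 0,
                                                 channel.n_samples - 1)],
                          valid[left] & valid[right])
            ok &= (t_out >= t_in[valid][0] - 1e-9) & (t_out <= t_in[valid][-1] + 1e-9)
            out_vals[ok] = interp[ok]
    else:
        t_in = channel.times()
        idx = np.clip(np.round((t_out - channel.start_time) * channel.nominal_rate)
                      .astype(int), 0, channel.n_samples - 1)
        near = np.abs(t_out - t_in[idx]) <= 0.5 + 1e-9
        ok = near & valid[idx]
        out_vals[ok] = channel.values[idx[ok]]

    return TimeSeriesChannel(
        channel_id=channel.channel_id,
        start_time=channel.start_time,
        nominal_rate=target_rate,
        values=out_vals,
    )


# ---------------------------------------------------------------------------
# Two-stream synchronization
# ---------------------------------------------------------------------------


def estimate_offset(
    wired_spo2: TimeSeriesChannel,
    wireless_spo2: TimeSeriesChannel,
    max_lag_s: float = 60.0,
    min_overlap_s: float = 60.0,
) -> float:
    """Estimate the constant wireless-minus-wired clock offset in seconds.

    The offset maximises the cross-correlation of the mean-removed 1 Hz
    SpO2 traces over integer lags in ``[-max_lag_s, +max_lag_s]``. A
    positive offset means the wireless stream is delayed: sample pairs
    align after shifting the wireless channels earlier by the offset.
    """
    a, b = wired_spo2, wireless_spo2
    if not (math.isclose(a.nominal_rate, 1.0) and math.isclose(b.nominal_rate, 1.0)):
        raise ValueError("offset estimation expects 1 Hz SpO2 channels")
    lags = np.arange(-int(round(max_lag_s)), int(round(max_lag_s)) + 1)
    # place both on a shared integer-second grid
    t0 = min(a.start_time, b.start_time) - max_lag_s
    t1 = max(a.end_time, b.end_time) + max_lag_s
    n = int(math.ceil(t1 - t0)) + 1

    def gridded(ch: TimeSeriesChannel) -> np.ndarray:
        g = np.full(n, np.nan)
        idx = np.round(ch.times() - t0).astype(int)
        g[idx] = ch.values
        return g

    ga, gb = gridded(a), gridded(b)
    best_lag, best_r = None, -np.inf
    for lag in lags:
        gb_shift = np.roll(gb, -lag)
        if lag > 0:
            gb_shift[-lag:] = np.nan
        elif lag < 0:
            gb_shift[:-lag] = np.nan
        both = ~np.isnan(ga) & ~np.isnan(gb_shift)
        if both.sum() < min_overlap_s:
            continue
        x = ga[both] - ga[both].mean()
        y = gb_shift[both] - gb_shift[both].mean()
        denom = math.sqrt((x * x).sum() * (y * y).sum())
        if denom <= 0:
            continue
        r = float((x * y).sum() / denom)
        if r > best_r:
            best_lag, best_r = int(lag), r
    if best_lag is None or not np.isfinite(best_r):
        raise SynchronizationError(
            "could not identify an offset (insufficient overlap or flat traces); "
            "pass offset_s explicitly"
        )
    return float(best_lag)


def _shift_and_trim(ch: TimeSeriesChannel, shift_s: float, planned_s: float) -> TimeSeriesChannel:
    start = ch.start_time + shift_s
    values = ch.values
    if start < 0:
        drop = int(math.ceil(-start * ch.nominal_rate - 1e-9))
        values = values[drop:]
        start += drop / ch.nominal_rate
    end = start + values.size / ch.nominal_rate
    if end > planned_s + 1e-9:
        keep = int(math.floor((planned_s - start) * ch.nominal_rate + 1e-9))
        values = values[:max(keep, 0)]
    return TimeSeriesChannel(ch.channel_id, start, ch.nominal_rate, values.copy())


def synchronize(
    rec: DualDayRecording,
    max_lag_s: float = 60.0,
    offset_s: float | None = None,
) -> tuple[float, DualDayRecording]:
    """Align the wireless channels onto the wired clock.

    Returns ``(offset_s, aligned recording)`` where the wireless channels
    have been shifted earlier by ``offset_s`` and trimmed to the planned
    monitoring window.
    """
    if offset_s is None:
        offset_s = estimate_offset(
            rec.channels[ChannelRole.WIRED_SPO2],
            rec.channels[ChannelRole.WIRELESS_SPO2],
            max_lag_s=max_lag_s,
        )
    wireless_roles = {ChannelRole.WIRELESS_PPG, ChannelRole.WIRELESS_SPO2}
    channels = {
        role: (
            _shift_and_trim(ch, -offset_s, rec.planned_duration_s)
            if role in wireless_roles
            else ch.copy()
        )
        for role, ch in rec.channels.items()
    }
    aligned = DualDayRecording(
        infant_id=rec.infant_id,
        day_index=rec.day_index,
        channels=channels,
        annotations=list(rec.annotations),
        flags=list(rec.flags),
        planned_duration_s=rec.planned_duration_s,
    )
    return float(offset_s), aligned
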