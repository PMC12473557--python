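"""Study-level orchestration: simulate/load -> synchronize -> analyse -> report.

``run_pipeline`` drives the three evaluation axes (feasibility, safety,
accuracy) over a set of infant-days under one configuration, writing a
JSON summary, per-day CSV tables and a checksum manifest. Every analysis
constant appears in :class:`StudyConfig` with its default; outputs carry
no timestamps, so a fixed configuration and seed reproduce byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accuracy, feasibility, safety, synthetic
from .io_recordings import (
    ChannelRole,
    DualDayRecording,
    load_recording,
    resample_channel,
    synchronize,
)

__all__ = ["StudyConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger("neowear")

_ANALYSED_ROLES = [
    ChannelRole.WIRED_PPG,
    ChannelRole.WIRELESS_PPG,
    ChannelRole.WIRED_SPO2,
    ChannelRole.WIRELESS_SPO2,
]


@dataclass
class StudyConfig:
    """One self-describing configuration for a full pipeline run."""

    mode: str = "simulate"                      # "simulate" or "files"
    input_dirs: list[str] = field(default_factory=list)  # mode == "files"
    dialect: str = "csv"
    n_days: int = 2                             # mode == "simulate"
    n_supplemental_days: int = 0
    simulation: synthetic.SimulationSpec = field(
        default_factory=synthetic.SimulationSpec
    )
    thresholds: feasibility.GapThresholds = field(
        default_factory=feasibility.GapThresholds
    )
    targets: accuracy.OxygenTargets = field(default_factory=accuracy.OxygenTargets)
    snr_window_s: float = 30.0
    snr_overlap: float = 0.5
    context_pad_s: float = 5.0
    max_lag_s: float = 60.0
    alpha: float = 0.001
    zero_handling: safety.ZeroHandling = safety.ZeroHandling.DROP
    tie_correction: bool = False
    direction: safety.Direction = safety.Direction.BEFORE_MINUS_AFTER
    out_dir: str = "neowear_report"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_plain(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return _from_plain(cls, raw)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "value") and not isinstance(obj, (int, float)):
        return obj.value  # enums
    return obj


def _from_plain(cls, raw: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in raw:
            continue
        v = raw[f.name]
        if f.name == "simulation":
            v = _from_plain(synthetic.SimulationSpec, v)
        elif f.name == "thresholds":
            v = feasibility.GapThresholds(**v)
        elif f.name == "targets":
            v = accuracy.OxygenTargets(**v)
        elif f.name == "zero_handling":
            v = safety.ZeroHandling(v)
        elif f.name == "direction":
            v = safety.Direction(v)
        elif f.name in ("desaturation",):
            v = synthetic.DesaturationSpec(**v)
        elif f.name == "bt_dropout":
            v = synthetic.BtDropoutSpec(**v)
        elif f.name == "wired_dropout":
            v = synthetic.WiredDropoutSpec(**v)
        elif isinstance(v, list) and f.name in (
            "wired_snr_db", "wireless_snr_db", "fio2_profile",
            "sensor_removal_events", "care_annotations",
        ):
            v = tuple(tuple(x) for x in v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class ReportBundle:
    summary: dict
    out_dir: Path
    files: list[Path]


def _analyse_day(
    rec: DualDayRecording,
    cfg: StudyConfig,
    ground_truth: synthetic.GroundTruth | None,
) -> tuple[dict, list[feasibility.Gap], accuracy.AgreementSummary | None]:
    """Feasibility + accuracy for one recording day."""
    offset_s, rec = synchronize(rec, max_lag_s=cfg.max_lag_s, offset_s=0.0
                                if cfg.mode == "simulate" else None)
    # common time base: both PPG streams at 64 Hz, SpO2 at 1 Hz
    channels = dict(rec.channels)
    channels[ChannelRole.WIRED_PPG] = resample_channel(
        channels[ChannelRole.WIRED_PPG], 64.0
    )

    snr = {
        role: feasibility.estimate_snr(
            channels[role], window_s=cfg.snr_window_s, overlap=cfg.snr_overlap
        )
        for role in (ChannelRole.WIRED_PPG, ChannelRole.WIRELESS_PPG)
    }
    day = {
        "infant_id": rec.infant_id,
        "day_index": rec.day_index,
        "offset_s": offset_s,
        "channels": {},
    }
    all_gaps: list[feasibility.Gap] = []
    for role in _ANALYSED_ROLES:
        ch = channels[role]
        gaps = feasibility.detect_gaps(ch, cfg.thresholds, rec.planned_duration_s)
        cov = feasibility.coverage(ch, cfg.thresholds, rec.planned_duration_s)
        device_snr = snr[
            ChannelRole.WIRED_PPG if role.value.startswith("WIRED")
            else ChannelRole.WIRELESS_PPG
        ]
        gaps = feasibility.attribute_gaps(
            gaps, rec.flags, rec.annotations, device_snr,
            context_pad_s=cfg.context_pad_s,
        )
        all_gaps.extend(gaps)
        day["channels"][role.value] = {
            "coverage_pct": cov.coverage_pct,
            "total_gap_time_s": cov.total_gap_time_s,
            "n_gaps": cov.n_gaps,
            "median_snr_db": (
                device_snr.median_db() if role in
                (ChannelRole.WIRED_PPG, ChannelRole.WIRELESS_PPG) else None
            ),
        }

    pairs = accuracy.pair_samples(
        channels[ChannelRole.WIRED_SPO2], channels[ChannelRole.WIRELESS_SPO2]
    )
    group = accuracy.classify_oxygen_group(channels[ChannelRole.FIO2])
    day["oxygen_group"] = group.value
    day["n_pairs"] = pairs.n_pairs
    agreement = None
    if pairs.n_pairs >= 2:
        agreement = accuracy.bland_altman(pairs)
        ega = accuracy.ega_summary(pairs, group, cfg.targets)
        day["agreement"] = dataclasses.asdict(agreement)
        day["ega_proportions"] = {r.value: p for r, p in
                                  ega.region_proportions.items()}
    if ground_truth is not None:
        day["ground_truth"] = {
            "true_bias_pct": ground_truth.true_bias_pct,
            "oxygen_group": ground_truth.oxygen_group_truth,
            "n_injected_gaps": len(ground_truth.injected_gaps),
        }
    return day, all_gaps, agreement


def run_pipeline(config: StudyConfig) -> ReportBundle:
    """Run the full framework and write the consolidated report.

    Any stage failure raises with the stage name and offending recording
    attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info(
        "conventions: zero_handling=%s tie_correction=%s direction=%s alpha=%s",
        config.zero_handling.value, config.tie_correction,
        config.direction.value, config.alpha,
    )

    if config.mode == "simulate":
        sims = synthetic.simulate_study(
            n_days=config.n_days,
            n_supplemental_days=config.n_supplemental_days,
            base_spec=config.simulation,
            seed=config.seed,
        )
        days_in = [(rec, gt) for rec, gt in sims]
    elif config.mode == "files":
        days_in = []
        for d in config.input_dirs:
            rec, _ = load_recording(d, dialect=config.dialect)
            days_in.append((rec, None))
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    per_day = []
    gap_rows = []
    agreements = []
    skin: list[safety.SkinAssessment] = []
    for rec, gt in days_in:
        try:
            day, gaps, agreement = _analyse_day(rec, config, gt)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'analyse_day' failed for recording "
                f"{rec.infant_id}/day{rec.day_index}: {exc}"
            ) from exc
        per_day.append(day)
        gap_rows += [
            {
                "infant_id": rec.infant_id,
                "day_index": rec.day_index,
                "channel_id": g.channel_id.value,
                "start_s": g.start_s,
                "end_s": g.end_s,
                "duration_s": g.duration_s,
                "cause": g.cause.value,
                "activity": g.activity,
            }
            for g in gaps
        ]
        if agreement is not None:
            agreements.append(agreement)
        if gt is not None and gt.nscs_before is not None:
            skin.append(safety.SkinAssessment(rec.infant_id, rec.day_index,
                                              safety.Phase.BEFORE, gt.nscs_before))
            skin.append(safety.SkinAssessment(rec.infant_id, rec.day_index,
                                              safety.Phase.AFTER, gt.nscs_after))

    summary: dict = {
        "conventions": {
            "zero_handling": config.zero_handling.value,
            "tie_correction": config.tie_correction,
            "direction": config.direction.value,
            "alpha": config.alpha,
            "snr_window_s": config.snr_window_s,
            "thresholds": dataclasses.asdict(config.thresholds),
            "oxygen_targets": dataclasses.asdict(config.targets),
        },
        "n_days": len(per_day),
        "per_day": per_day,
    }

    # feasibility aggregation: per-channel coverage medians and the paired test
    cov_table = {}
    for role in _ANALYSED_ROLES:
        v = np.array([d["channels"][role.value]["coverage_pct"] for d in per_day])
        cov_table[role.value] = {
            "median": float(np.median(v)),
            "q1": float(np.quantile(v, 0.25)),
            "q3": float(np.quantile(v, 0.75)),
        }
    summary["coverage"] = cov_table
    if len(per_day) >= 2:
        for kind, a_role, b_role in (
            ("ppg", ChannelRole.WIRED_PPG, ChannelRole.WIRELESS_PPG),
            ("spo2", ChannelRole.WIRED_SPO2, ChannelRole.WIRELESS_SPO2),
        ):
            a = [d["channels"][a_role.value]["coverage_pct"] for d in per_day]
            b = [d["channels"][b_role.value]["coverage_pct"] for d in per_day]
            res = feasibility.compare_paired(
                a, b, zero_handling=config.zero_handling,
                tie_correction=config.tie_correction,
            )
            summary[f"coverage_test_{kind}"] = {
                "z": res.z, "p_two_sided": res.p_two_sided, "n_used": res.n_used,
            }

    if skin:
        pairs, unpaired = safety.pair_scores(skin)
        res = safety.wilcoxon_signed_rank(
            [p.delta for p in pairs],
            zero_handling=config.zero_handling,
            tie_correction=config.tie_correction,
            direction=config.direction,
        )
        n_pairs = len(pairs)
        delta_counts = pd.Series([p.delta for p in pairs]).value_counts().to_dict()
        summary["safety"] = {
            "n_pairs": n_pairs,
            "n_unpaired": len(unpaired),
            "delta_counts": {str(k): int(v) for k, v in sorted(delta_counts.items())},
            "z": res.z,
            "p_two_sided": res.p_two_sided,
            "n_used": res.n_used,
        }

    if agreements:
        agg = accuracy.aggregate_daily(agreements)
        summary["accuracy_aggregate"] = {
            m: {k: float(agg.loc[m, k]) for k in ("median", "q1", "q3")}
            for m in agg.index
        }

    files = []
    report_path = out / "report.json"
    report_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    files.append(report_path)
    gaps_path = out / "gaps.csv"
    pd.DataFrame(
        gap_rows,
        columns=["infant_id", "day_index", "channel_id", "start_s", "end_s",
                 "duration_s", "cause", "activity"],
    ).to_csv(gaps_path, index=False)
    files.append(gaps_path)
    per_day_path = out / "per_day.csv"
    pd.DataFrame(
        [
            {
                "infant_id": d["infant_id"],
                "day_index": d["day_index"],
                "oxygen_group": d["oxygen_group"],
                "n_pairs": d["n_pairs"],
                **{
                    f"coverage_{r.value}": d["channels"][r.value]["coverage_pct"]
                    for r in _ANALYSED_ROLES
                },
                **(
                    {f"agreement_{k}": v for k, v in d["agreement"].items()}
                    if "agreement" in d
                    else {}
                ),
            }
            for d in per_day
        ]
    ).to_csv(per_day_path, index=False)
    files.append(per_day_path)

    manifest = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in files
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    files.append(manifest_path)
    return ReportBundle(summary=summary, out_dir=out, files=files)
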