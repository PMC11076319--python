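"""Analysis configuration: one JSON document holding thresholds, the
time-block scheme, day rollover, sufficiency policy, pattern parameters and
CV cutpoints. Unknown keys are rejected with the full list of offenders."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import time
from pathlib import Path
from typing import Any, Optional

from .core import GlycemicThresholds, Tag, TimeBlockScheme, TimeBlock
from .patterns import (
    AdherenceParams,
    LevelParams,
    PairingParams,
    PatternParams,
    TimeBlockParams,
    TrendParams,
)
from .sufficiency import SufficiencyPolicy
from .variability import CvCutpoints


class ConfigError(ValueError):
    """Malformed configuration; message lists every offending key."""


def _parse_time(s: str) -> time:
    try:
        h, m = s.split(":")
        return time(int(h) % 24, int(m))
    except Exception as exc:
        raise ConfigError(f"invalid clock time {s!r} (expected HH:MM)") from exc


def _fmt_time(t: time) -> str:
    return f"{t.hour:02d}:{t.minute:02d}"


@dataclass(frozen=True)
class AnalysisConfig:
    thresholds: GlycemicThresholds = GlycemicThresholds()
    scheme: TimeBlockScheme = field(default_factory=TimeBlockScheme.default)
    day_start: time = time(0, 0)
    sufficiency: SufficiencyPolicy = SufficiencyPolicy()
    patterns: PatternParams = PatternParams()
    cv_cutpoints: CvCutpoints = CvCutpoints()
    cv_gate_basis: str = "overall"

    @classmethod
    def default(cls) -> "AnalysisConfig":
        return cls()

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        p = self.patterns
        return {
            "day_start": _fmt_time(self.day_start),
            "thresholds": {
                "very_low_limit": self.thresholds.very_low_limit,
                "hypo_limit": self.thresholds.hypo_limit,
                "hyper_premeal_limit": self.thresholds.hyper_premeal_limit,
                "hyper_postmeal_limit": self.thresholds.hyper_postmeal_limit,
                "very_high_limit": self.thresholds.very_high_limit,
            },
            "time_blocks": [
                {
                    "name": b.name,
                    "start": f"{b.start_min // 60:02d}:{b.start_min % 60:02d}",
                    "end": f"{b.end_min // 60:02d}:{b.end_min % 60:02d}"
                    if b.end_min < 1440
                    else "24:00",
                }
                for b in self.scheme.blocks
            ],
            "sufficiency": {
                "min_tests_activation": self.sufficiency.min_tests_activation,
                "activation_horizon_days": self.sufficiency.activation_horizon_days,
                "min_tests_step1": self.sufficiency.min_tests_step1,
                "step1_horizon_days": self.sufficiency.step1_horizon_days,
                "required_tag_coverage": [t.value for t in self.sufficiency.required_tag_coverage],
                "min_per_tag": self.sufficiency.min_per_tag,
                "coverage_horizon_days": self.sufficiency.coverage_horizon_days,
            },
            "patterns": {
                "hyper_trend": {"tests_per_day": p.hyper_trend.count, "consecutive_days": p.hyper_trend.consecutive_days},
                "very_high_trend": {"tests": p.very_high_trend.tests, "level": p.very_high_trend.level},
                "hypo_trend": {"events_per_day": p.hypo_trend.count, "consecutive_days": p.hypo_trend.consecutive_days},
                "hypo_time_block": {"events_in_block": p.hypo_time_block.events_in_block, "days": p.hypo_time_block.days},
                "hyper_time_block": {"events_in_block": p.hyper_time_block.events_in_block, "days": p.hyper_time_block.days},
                "very_low_trend": {"tests": p.very_low_trend.tests, "level": p.very_low_trend.level},
                "hypo_after_hyper": {"enabled": p.hypo_after_hyper.enabled, "pattern_count": p.hypo_after_hyper.pattern_count, "pairing_window_hours": p.hypo_after_hyper.pairing_window_hours},
                "hyper_after_hypo": {"enabled": p.hyper_after_hypo.enabled, "pattern_count": p.hyper_after_hypo.pattern_count, "pairing_window_hours": p.hyper_after_hypo.pairing_window_hours},
                "missed_bolus": {"enabled": p.missed_bolus.enabled, "pattern_count": p.missed_bolus.pattern_count},
                "adherence": {"prescribed_tests_per_day": p.adherence.prescribed_tests_per_day, "red_threshold": p.adherence.red_threshold},
            },
            "cv_cutpoints": {
                "low_upper": self.cv_cutpoints.low_upper,
                "acceptable_upper": self.cv_cutpoints.acceptable_upper,
            },
            "cv_gate_basis": self.cv_gate_basis,
        }

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a JSON object")
        base = cls.default().to_dict()
        bad = _unknown_keys(data, base)
        if bad:
            raise ConfigError("unknown config keys: " + ", ".join(sorted(bad)))

        cfg = cls.default()
        if "day_start" in data:
            cfg = replace(cfg, day_start=_parse_time(data["day_start"]))
        if "thresholds" in data:
            cfg = replace(
                cfg,
                thresholds=GlycemicThresholds(
                    **{**base["thresholds"], **data["thresholds"]}
                ),
            )
        if "time_blocks" in data:
            pairs = [
                (b["name"], _parse_time(b["start"]),
                 time(0, 0) if b["end"] == "24:00" else _parse_time(b["end"]))
                for b in data["time_blocks"]
            ]
            cfg = replace(cfg, scheme=TimeBlockScheme.from_pairs(pairs))
        if "sufficiency" in data:
            merged = {**base["sufficiency"], **data["sufficiency"]}
            merged["required_tag_coverage"] = tuple(
                Tag(t) for t in merged["required_tag_coverage"]
            )
            cfg = replace(cfg, sufficiency=SufficiencyPolicy(**merged))
        if "patterns" in data:
            merged = {
                k: {**base["patterns"][k], **data["patterns"].get(k, {})}
                for k in base["patterns"]
            }
            cfg = replace(
                cfg,
                patterns=PatternParams(
                    hyper_trend=TrendParams(merged["hyper_trend"]["tests_per_day"], merged["hyper_trend"]["consecutive_days"]),
                    very_high_trend=LevelParams(merged["very_high_trend"]["tests"], merged["very_high_trend"]["level"]),
                    hypo_trend=TrendParams(merged["hypo_trend"]["events_per_day"], merged["hypo_trend"]["consecutive_days"]),
                    hypo_time_block=TimeBlockParams(**merged["hypo_time_block"]),
                    hyper_time_block=TimeBlockParams(**merged["hyper_time_block"]),
                    very_low_trend=LevelParams(merged["very_low_trend"]["tests"], merged["very_low_trend"]["level"]),
                    hypo_after_hyper=PairingParams(**merged["hypo_after_hyper"]),
                    hyper_after_hypo=PairingParams(**merged["hyper_after_hypo"]),
                    missed_bolus=PairingParams(**merged["missed_bolus"]),
                    adherence=AdherenceParams(**merged["adherence"]),
                ),
            )
        if "cv_cutpoints" in data:
            cfg = replace(
                cfg,
                cv_cutpoints=CvCutpoints(**{**base["cv_cutpoints"], **data["cv_cutpoints"]}),
            )
        if "cv_gate_basis" in data:
            if data["cv_gate_basis"] not in ("overall", "daily_means"):
                raise ConfigError(f"cv_gate_basis must be 'overall' or 'daily_means'")
            cfg = replace(cfg, cv_gate_basis=data["cv_gate_basis"])
        return cfg

    @classmethod
    def from_json_file(cls, path: str | Path) -> "AnalysisConfig":
        try:
            with open(path, encoding="utf-8") as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
        return cls.from_dict(data)


def _unknown_keys(data: dict, reference: dict, prefix: str = "") -> list[str]:
    """Recursively collect keys in data that have no counterpart in the
    default-config shape (lists are treated as opaque)."""
    bad = []
    for key, value in data.items():
        if key not in reference:
            bad.append(prefix + key)
        elif isinstance(value, dict) and isinstance(reference[key], dict):
            bad.extend(_unknown_keys(value, reference[key], prefix + key + "."))
    return bad
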