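"""Step 1: quantity/quality assessment of SMBG data and the pattern-analysis gate.

The activation count (default 72 tests per 4 weeks, settable 30-120) and the
step-1 quantity minimum (default 28 tests per 2 weeks) are stated for fixed
horizons; for other window lengths the thresholds scale linearly by days and
round up, preserving the stated test densities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from datetime import time
from typing import Iterable, Sequence

from .core import (
    AnalysisWindow,
    GlucoseReading,
    Tag,
    TimeBlockScheme,
    count_by_block,
    readings_in_window,
)

logger = logging.getLogger(__name__)

ACTIVATION_SETTABLE_RANGE = (30, 120)

DEFAULT_REQUIRED_TAGS = (
    Tag.PRE_BREAKFAST,
    Tag.POST_BREAKFAST,
    Tag.PRE_DINNER,
    Tag.POST_DINNER,
    Tag.BEDTIME,
)


@dataclass(frozen=True)
class SufficiencyPolicy:
    """Thresholds gating pattern analysis.

    ``min_tests_activation`` applies over ``activation_horizon_days`` (4 weeks),
    ``min_tests_step1`` over ``step1_horizon_days`` (2 weeks). Tag coverage is
    the concrete quality criterion: each required tag must appear at least
    ``min_per_tag`` times per ``coverage_horizon_days``.
    """

    min_tests_activation: int = 72
    activation_horizon_days: int = 28
    min_tests_step1: int = 28
    step1_horizon_days: int = 14
    required_tag_coverage: tuple[Tag, ...] = DEFAULT_REQUIRED_TAGS
    min_per_tag: int = 3
    coverage_horizon_days: int = 14

    def __post_init__(self) -> None:
        if self.min_tests_step1 < 1:
            raise ValueError("min_tests_step1 must be >= 1")
        for name in ("activation_horizon_days", "step1_horizon_days", "coverage_horizon_days"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def clamp_policy(requested: SufficiencyPolicy) -> SufficiencyPolicy:
    """Clamp the activation count into its settable range; never reject."""
    lo, hi = ACTIVATION_SETTABLE_RANGE
    clamped = min(max(requested.min_tests_activation, lo), hi)
    if clamped != requested.min_tests_activation:
        logger.warning(
            "min_tests_activation %d outside settable range [%d, %d]; clamped to %d",
            requested.min_tests_activation,
            lo,
            hi,
            clamped,
        )
        return replace(requested, min_tests_activation=clamped)
    return requested


def prorate(count: int, horizon_days: int, window_days: int) -> int:
    """Scale a fixed-horizon threshold to a window length, rounding up."""
    return math.ceil(count * window_days / horizon_days)


@dataclass(frozen=True)
class SufficiencyResult:
    window: AnalysisWindow
    total_tests: int
    mean_tests_per_day: float
    per_block_counts: dict[str, int]
    per_tag_counts: dict[str, int]
    quantity_ok: bool
    quality_ok: bool
    pattern_analysis_active: bool
    deficiencies: list[str]
    thresholds_applied: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "window": {"start": self.window.start.isoformat(), "end": self.window.end.isoformat()},
            "total_tests": self.total_tests,
            "mean_tests_per_day": round(self.mean_tests_per_day, 6),
            "per_block_counts": dict(self.per_block_counts),
            "per_tag_counts": dict(self.per_tag_counts),
            "quantity_ok": self.quantity_ok,
            "quality_ok": self.quality_ok,
            "pattern_analysis_active": self.pattern_analysis_active,
            "deficiencies": list(self.deficiencies),
            "thresholds_applied": dict(self.thresholds_applied),
        }


def assess_sufficiency(
    readings: Iterable[GlucoseReading],
    window: AnalysisWindow,
    policy: SufficiencyPolicy,
    scheme: TimeBlockScheme,
    day_start: time = time(0, 0),
) -> SufficiencyResult:
    """Assess quantity and quality of data in the window and set the gates.

    Zero readings yield a valid result with every gate false (the insufficient
    branch of the flowchart is a legitimate clinical outcome, not an error).
    """
    policy = clamp_policy(policy)
    in_window = readings_in_window(readings, window, day_start)
    n = len(in_window)
    days = window.n_days

    need_step1 = prorate(policy.min_tests_step1, policy.step1_horizon_days, days)
    need_activation = prorate(
        policy.min_tests_activation, policy.activation_horizon_days, days
    )
    need_per_tag = prorate(policy.min_per_tag, policy.coverage_horizon_days, days)

    per_tag = {t.value: 0 for t in Tag}
    for r in in_window:
        per_tag[r.tag.value] += 1

    deficiencies: list[str] = []
    quantity_ok = n >= need_step1
    if not quantity_ok:
        deficiencies.append(f"quantity_below_minimum:{n}<{need_step1}")
    quality_ok = True
    for tag in policy.required_tag_coverage:
        covered = per_tag[tag.value]
        if tag is Tag.PRE_BREAKFAST:
            # a fasting reading is the morning pre-breakfast test
            covered += per_tag[Tag.FASTING.value]
        if covered < need_per_tag:
            quality_ok = False
            deficiencies.append(f"tag_coverage:{tag.value}:{covered}<{need_per_tag}")
    active = n >= need_activation
    if not active:
        deficiencies.append(f"activation_count_not_met:{n}<{need_activation}")

    return SufficiencyResult(
        window=window,
        total_tests=n,
        mean_tests_per_day=n / days,
        per_block_counts=count_by_block(in_window, scheme),
        per_tag_counts=per_tag,
        quantity_ok=quantity_ok,
        quality_ok=quality_ok,
        pattern_analysis_active=active,
        deficiencies=deficiencies,
        thresholds_applied={
            "min_tests_step1": need_step1,
            "min_tests_activation": need_activation,
            "min_per_tag": need_per_tag,
        },
    )
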