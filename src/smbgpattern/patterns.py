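"""Step 2: rule-based pattern detectors.

Five detectors carry published rule constants and settable ranges
(hyperglycemia trend, very-high trend, hypoglycemia trend, hypoglycemia in
time block, very-low trend). The time-block rule is mirrored for
hyperglycemia, and three declared heuristics (overcorrection pairs, missed
bolus) are off by default. Each detector returns a red/clear
:class:`PatternFinding` carrying the exact triggering evidence.

Conventions:
 - "consecutive days" means calendar-consecutive analysis days each meeting
   the per-day count; a day with no qualifying readings breaks a run.
 - "over N days" is a sliding window of N consecutive analysis days placed
   anywhere in the analysis period.
 - ties between qualifying runs/windows are broken by earliest position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from datetime import date, time, timedelta
from typing import Iterable, Optional, Sequence

from .core import (
    AnalysisWindow,
    GlucoseReading,
    GlycemicClass,
    GlycemicThresholds,
    POST_MEAL_TAGS,
    MEAL_PAIRS,
    Tag,
    TimeBlockScheme,
    analysis_day,
    assign_block,
    classify_reading,
    is_hyper_event,
    is_hypo_event,
    readings_in_window,
)

logger = logging.getLogger(__name__)

RED = "red"
CLEAR = "clear"
INACTIVE = "inactive"

BLOCK_HYPO = "hypoglycemia"
BLOCK_HYPER = "hyperglycemia"
BLOCK_VARIABILITY = "variability"
BLOCK_ADHERENCE = "adherence"

#: Printed settable ranges, keyed by (detector, parameter).
SETTABLE_RANGES: dict[tuple[str, str], tuple[float, float]] = {
    ("hyper_trend", "tests_per_day"): (1, 5),
    ("hyper_trend", "consecutive_days"): (1, 10),
    ("very_high_trend", "tests"): (1, 10),
    ("very_high_trend", "level"): (140, 300),
    ("hypo_trend", "events_per_day"): (1, 5),
    ("hypo_trend", "consecutive_days"): (2, 10),
    ("hypo_time_block", "events_in_block"): (2, 10),
    ("hypo_time_block", "days"): (2, 10),
    ("hyper_time_block", "events_in_block"): (2, 10),
    ("hyper_time_block", "days"): (2, 10),
    ("very_low_trend", "tests"): (1, 10),
    ("very_low_trend", "level"): (50, 80),
}


def _clamp(detector: str, param: str, value):
    lo, hi = SETTABLE_RANGES[(detector, param)]
    clamped = min(max(value, lo), hi)
    if clamped != value:
        logger.warning(
            "%s.%s=%s outside settable range [%s, %s]; clamped to %s",
            detector, param, value, lo, hi, clamped,
        )
    return type(value)(clamped)


@dataclass(frozen=True)
class TrendParams:
    count: int
    consecutive_days: int


@dataclass(frozen=True)
class LevelParams:
    tests: int
    level: float


@dataclass(frozen=True)
class TimeBlockParams:
    events_in_block: int
    days: int


@dataclass(frozen=True)
class PairingParams:
    """Declared heuristic (no published rule); disabled unless configured."""

    enabled: bool = False
    pattern_count: int = 1
    pairing_window_hours: float = 5.0


@dataclass(frozen=True)
class AdherenceParams:
    prescribed_tests_per_day: float = 4.0
    red_threshold: float = 0.7


@dataclass(frozen=True)
class PatternParams:
    """All detector parameters; defaults are the published rule constants."""

    hyper_trend: TrendParams = TrendParams(count=2, consecutive_days=3)
    very_high_trend: LevelParams = LevelParams(tests=1, level=250.0)
    hypo_trend: TrendParams = TrendParams(count=1, consecutive_days=2)
    hypo_time_block: TimeBlockParams = TimeBlockParams(events_in_block=2, days=7)
    hyper_time_block: TimeBlockParams = TimeBlockParams(events_in_block=2, days=7)
    very_low_trend: LevelParams = LevelParams(tests=1, level=54.0)
    hypo_after_hyper: PairingParams = PairingParams()
    hyper_after_hypo: PairingParams = PairingParams()
    missed_bolus: PairingParams = PairingParams()
    adherence: AdherenceParams = AdherenceParams()

    def clamped(self) -> "PatternParams":
        """Clamp every tunable into its printed settable range (never reject)."""
        return replace(
            self,
            hyper_trend=TrendParams(
                _clamp("hyper_trend", "tests_per_day", self.hyper_trend.count),
                _clamp("hyper_trend", "consecutive_days", self.hyper_trend.consecutive_days),
            ),
            very_high_trend=LevelParams(
                _clamp("very_high_trend", "tests", self.very_high_trend.tests),
                _clamp("very_high_trend", "level", self.very_high_trend.level),
            ),
            hypo_trend=TrendParams(
                _clamp("hypo_trend", "events_per_day", self.hypo_trend.count),
                _clamp("hypo_trend", "consecutive_days", self.hypo_trend.consecutive_days),
            ),
            hypo_time_block=TimeBlockParams(
                _clamp("hypo_time_block", "events_in_block", self.hypo_time_block.events_in_block),
                _clamp("hypo_time_block", "days", self.hypo_time_block.days),
            ),
            hyper_time_block=TimeBlockParams(
                _clamp("hyper_time_block", "events_in_block", self.hyper_time_block.events_in_block),
                _clamp("hyper_time_block", "days", self.hyper_time_block.days),
            ),
            very_low_trend=LevelParams(
                _clamp("very_low_trend", "tests", self.very_low_trend.tests),
                _clamp("very_low_trend", "level", self.very_low_trend.level),
            ),
        )


@dataclass(frozen=True)
class Evidence:
    """Reference to one triggering reading."""

    index: int  # position in the timestamp-sorted window readings
    timestamp: str
    day: str
    block: str
    value: float

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "timestamp": self.timestamp,
            "day": self.day,
            "block": self.block,
            "value": round(self.value, 6),
        }


@dataclass(frozen=True)
class PatternFinding:
    detector: str
    block: str
    status: str
    evidence: tuple[Evidence, ...]
    window: AnalysisWindow
    params_used: dict
    extra: dict = field(default_factory=dict)

    @property
    def is_red(self) -> bool:
        return self.status == RED

    def to_dict(self) -> dict:
        return {
            "detector": self.detector,
            "block": self.block,
            "status": self.status,
            "evidence": [e.to_dict() for e in self.evidence],
            "params_used": dict(self.params_used),
            "extra": dict(self.extra),
        }


@dataclass(frozen=True)
class _Annotated:
    index: int
    reading: GlucoseReading
    cls: GlycemicClass
    day: date
    block: str

    def evidence(self) -> Evidence:
        return Evidence(
            index=self.index,
            timestamp=self.reading.timestamp.isoformat(timespec="minutes"),
            day=self.day.isoformat(),
            block=self.block,
            value=self.reading.value,
        )


def annotate(
    readings: Sequence[GlucoseReading],
    window: AnalysisWindow,
    thresholds: GlycemicThresholds,
    scheme: TimeBlockScheme,
    day_start: time = time(0, 0),
) -> list[_Annotated]:
    """Restrict to the window, sort, classify and block-assign each reading."""
    in_window = readings_in_window(readings, window, day_start)
    return [
        _Annotated(
            index=i,
            reading=r,
            cls=classify_reading(r, thresholds),
            day=analysis_day(r.timestamp, day_start),
            block=assign_block(r, scheme),
        )
        for i, r in enumerate(in_window)
    ]


def _finding(detector, block, red, evidence, window, params, extra=None) -> PatternFinding:
    return PatternFinding(
        detector=detector,
        block=block,
        status=RED if red else CLEAR,
        evidence=tuple(evidence) if red else (),
        window=window,
        params_used=params,
        extra=extra or {},
    )


def _scan_day_runs(
    annotated: Sequence[_Annotated],
    window: AnalysisWindow,
    qualifies,
    per_day_count: int,
    run_days: int,
    all_runs: bool = False,
) -> list[list[_Annotated]]:
    """Runs of >= run_days consecutive days each holding >= per_day_count
    qualifying readings. Returns qualifying-reading lists, earliest run first;
    only the first unless all_runs. Runs of exactly run_days are reported."""
    days = window.days()
    by_day: dict[date, list[_Annotated]] = {d: [] for d in days}
    for a in annotated:
        if qualifies(a):
            by_day[a.day].append(a)
    hits: list[list[_Annotated]] = []
    for start in range(len(days) - run_days + 1):
        run = days[start : start + run_days]
        if all(len(by_day[d]) >= per_day_count for d in run):
            hits.append([a for d in run for a in by_day[d]])
            if not all_runs:
                break
    return hits


def detect_hyper_trend(
    annotated: Sequence[_Annotated],
    window: AnalysisWindow,
    params: TrendParams,
) -> PatternFinding:
    """Red when >= count hyperglycemic tests/day occur on >= consecutive_days
    consecutive days (very-high readings count as hyperglycemic)."""
    runs = _scan_day_runs(
        annotated, window, lambda a: is_hyper_event(a.cls), params.count, params.consecutive_days
    )
    return _finding(
        "hyper_trend",
        BLOCK_HYPER,
        bool(runs),
        [a.evidence() for a in runs[0]] if runs else [],
        window,
        {"tests_per_day": params.count, "consecutive_days": params.consecutive_days},
    )


def detect_hypo_trend(
    annotated: Sequence[_Annotated],
    window: AnalysisWindow,
    params: TrendParams,
) -> PatternFinding:
    """Red when >= count hypoglycemic events/day occur on >= consecutive_days
    consecutive days (very-low readings count as hypoglycemic)."""
    runs = _scan_day_runs(
        annotated, window, lambda a: is_hypo_event(a.cls), params.count, params.consecutive_days
    )
    return _finding(
        "hypo_trend",
        BLOCK_HYPO,
        bool(runs),
        [a.evidence() for a in runs[0]] if runs else [],
        window,
        {"events_per_day": params.count, "consecutive_days": params.consecutive_days},
    )


def detect_very_high_trend(
    annotated: Sequence[_Annotated],
    window: AnalysisWindow,
    params: LevelParams,
) -> PatternFinding:
    """Red when >= tests readings exceed level (strictly) in the window."""
    hits = [a for a in annotated if a.reading.value > params.level]
    red = len(hits) >= params.tests
    return _finding(
        "very_high_trend",
        BLOCK_HYPER,
        red,
        [a.evidence() for a in hits],
        window,
        {"tests": params.tests, "level": params.level},
    )


def detect_very_low_trend(
    annotated: Sequence[_Annotated],
    window: AnalysisWindow,
    params: LevelParams,
) -> PatternFinding:
    """Red when >= tests readings fall strictly below level in the window."""
    hits = [a for a in annotated if a.reading.value < params.level]
    red = len(hits) >= params.tests
    return _finding(
        "very_low_trend",
        BLOCK_HYPO,
        red,
        [a.evidence() for a in hits],
        window,
        {"tests": params.tests, "level": params.level},
    )


def _scan_time_block(
    annotated: Sequence[_Annotated],
    window: AnalysisWindow,
    scheme: TimeBlockScheme,
    qualifies,
    events_in_block: int,
    span_days: int,
) -> Optional[tuple[str, list[_Annotated]]]:
    """Earliest (window start, block in scheme order) where >= events_in_block
    qualifying events share a block within span_days consecutive days."""
    events = [a for a in annotated if qualifies(a)]
    days = window.days()
    n_starts = max(len(days) - span_days + 1, 1)
    for start in range(n_starts):
        lo = days[start]
        hi = lo + timedelta(days=span_days - 1)
        for block in scheme.block_names:
            hits = [a for a in events if a.block == block and lo <= a.day <= hi]
            if len(hits) >= events_in_block:
                return block, hits
    return None


def detect_hypo_time_block(
    annotated: Sequence[_Annotated],
    window: AnalysisWindow,
    scheme: TimeBlockScheme,
    params: TimeBlockParams,
) -> PatternFinding:
    """Red when >= events_in_block hypoglycemic events share one time block
    within a sliding span of `days` consecutive analysis days."""
    hit = _scan_time_block(
        annotated, window, scheme, lambda a: is_hypo_event(a.cls),
        params.events_in_block, params.days,
    )
    return _finding(
        "hypo_time_block",
        BLOCK_HYPO,
        hit is not None,
        [a.evidence() for a in hit[1]] if hit else [],
        window,
        {"events_in_block": params.events_in_block, "days": params.days},
        {"block": hit[0]} if hit else {},
    )


def detect_hyper_time_block(
    annotated: Sequence[_Annotated],
    window: AnalysisWindow,
    scheme: TimeBlockScheme,
    params: TimeBlockParams,
) -> PatternFinding:
    """Mirror of the hypoglycemia time-block rule for hyperglycemic events."""
    hit = _scan_time_block(
        annotated, window, scheme, lambda a: is_hyper_event(a.cls),
        params.events_in_block, params.days,
    )
    return _finding(
        "hyper_time_block",
        BLOCK_HYPER,
        hit is not None,
        [a.evidence() for a in hit[1]] if hit else [],
        window,
        {"events_in_block": params.events_in_block, "days": params.days},
        {"block": hit[0]} if hit else {},
    )


def _qualifying_pairs(
    annotated: Sequence[_Annotated],
    first_pred,
    second_pred,
    window_hours: float,
) -> list[tuple[_Annotated, _Annotated]]:
    """Ordered pairs (a, b), a before b, b within window_hours of a, with no
    in-range reading strictly between them."""
    max_dt = timedelta(hours=window_hours)
    pairs = []
    for i, a in enumerate(annotated):
        if not first_pred(a):
            continue
        for b in annotated[i + 1 :]:
            dt = b.reading.timestamp - a.reading.timestamp
            if dt > max_dt:
                break
            if b.cls == GlycemicClass.IN_RANGE:
                break  # interruption: later partners all have in-range between
            if second_pred(b):
                pairs.append((a, b))
    return pairs


def detect_hypo_after_hyper(
    annotated: Sequence[_Annotated],
    window: AnalysisWindow,
    params: PairingParams,
) -> PatternFinding:
    """Heuristic: hypoglycemia following hyperglycemia within the pairing
    window with no in-range reading between (overcorrection of a high)."""
    pairs = _qualifying_pairs(
        annotated,
        lambda a: is_hyper_event(a.cls),
        lambda a: is_hypo_event(a.cls),
        params.pairing_window_hours,
    )
    red = len(pairs) >= params.pattern_count
    ev = [x.evidence() for pair in pairs for x in pair]
    return _finding(
        "hypo_after_hyper",
        BLOCK_HYPO,
        red,
        ev,
        window,
        {
            "pattern_count": params.pattern_count,
            "pairing_window_hours": params.pairing_window_hours,
        },
        {"heuristic": True, "n_pairs": len(pairs)},
    )


def detect_hyper_after_hypo(
    annotated: Sequence[_Annotated],
    window: AnalysisWindow,
    params: PairingParams,
) -> PatternFinding:
    """Heuristic mirror: hyperglycemia following hypoglycemia (overcorrection
    of a low)."""
    pairs = _qualifying_pairs(
        annotated,
        lambda a: is_hypo_event(a.cls),
        lambda a: is_hyper_event(a.cls),
        params.pairing_window_hours,
    )
    red = len(pairs) >= params.pattern_count
    ev = [x.evidence() for pair in pairs for x in pair]
    return _finding(
        "hyper_after_hypo",
        BLOCK_HYPER,
        red,
        ev,
        window,
        {
            "pattern_count": params.pattern_count,
            "pairing_window_hours": params.pairing_window_hours,
        },
        {"heuristic": True, "n_pairs": len(pairs)},
    )


def detect_missed_bolus_hyper(
    annotated: Sequence[_Annotated],
    window: AnalysisWindow,
    params: PairingParams,
) -> PatternFinding:
    """Heuristic: post-meal hyperglycemia whose same-meal, same-day pre-meal
    reading records bolus_given=false. Inactive when the log carries no bolus
    annotations at all (missing-data contract)."""
    if all(a.reading.bolus_given is None for a in annotated):
        return PatternFinding(
            detector="missed_bolus_hyper",
            block=BLOCK_HYPER,
            status=INACTIVE,
            evidence=(),
            window=window,
            params_used={"pattern_count": params.pattern_count},
            extra={"heuristic": True, "reason": "no_bolus_annotations"},
        )
    pre_for_post = {post: pre for pre, post in MEAL_PAIRS}
    by_day_tag: dict[tuple[date, Tag], _Annotated] = {}
    for a in annotated:
        by_day_tag.setdefault((a.day, a.reading.tag), a)
    hits = []
    for a in annotated:
        if a.reading.tag not in pre_for_post or not is_hyper_event(a.cls):
            continue
        pre = by_day_tag.get((a.day, pre_for_post[a.reading.tag]))
        if pre is not None and pre.reading.bolus_given is False:
            hits.append(a)
    red = len(hits) >= params.pattern_count
    return _finding(
        "missed_bolus_hyper",
        BLOCK_HYPER,
        red,
        [a.evidence() for a in hits],
        window,
        {"pattern_count": params.pattern_count},
        {"heuristic": True},
    )


def assess_adherence(
    annotated: Sequence[_Annotated],
    window: AnalysisWindow,
    params: AdherenceParams,
) -> tuple[float, PatternFinding]:
    """Fraction of prescribed tests performed (capped at 1); red below the
    configured threshold."""
    prescribed = params.prescribed_tests_per_day * window.n_days
    fraction = min(len(annotated) / prescribed, 1.0) if prescribed > 0 else 0.0
    red = fraction < params.red_threshold
    finding = PatternFinding(
        detector="adherence",
        block=BLOCK_ADHERENCE,
        status=RED if red else CLEAR,
        evidence=(),
        window=window,
        params_used={
            "prescribed_tests_per_day": params.prescribed_tests_per_day,
            "red_threshold": params.red_threshold,
        },
        extra={"fraction": round(fraction, 6), "performed": len(annotated)},
    )
    return fraction, finding


#: Deterministic detector order: hypoglycemia block first, then
#: hyperglycemia, then adherence (variability is reported separately).
DETECTOR_ORDER = (
    "hypo_trend",
    "hypo_time_block",
    "very_low_trend",
    "hypo_after_hyper",
    "hyper_trend",
    "hyper_time_block",
    "very_high_trend",
    "hyper_after_hypo",
    "missed_bolus_hyper",
    "adherence",
)


def run_all_patterns(
    readings: Sequence[GlucoseReading],
    window: AnalysisWindow,
    thresholds: GlycemicThresholds,
    scheme: TimeBlockScheme,
    params: PatternParams,
    day_start: time = time(0, 0),
    active: bool = True,
) -> list[PatternFinding]:
    """Run every configured detector in deterministic block order.

    When the sufficiency gate failed (``active=False``) every finding is
    returned with status ``inactive``. Disabled heuristics are omitted.
    """
    params = params.clamped()
    annotated = annotate(readings, window, thresholds, scheme, day_start)
    findings = [
        detect_hypo_trend(annotated, window, params.hypo_trend),
        detect_hypo_time_block(annotated, window, scheme, params.hypo_time_block),
        detect_very_low_trend(annotated, window, params.very_low_trend),
    ]
    if params.hypo_after_hyper.enabled:
        findings.append(detect_hypo_after_hyper(annotated, window, params.hypo_after_hyper))
    findings += [
        detect_hyper_trend(annotated, window, params.hyper_trend),
        detect_hyper_time_block(annotated, window, scheme, params.hyper_time_block),
        detect_very_high_trend(annotated, window, params.very_high_trend),
    ]
    if params.hyper_after_hypo.enabled:
        findings.append(detect_hyper_after_hypo(annotated, window, params.hyper_after_hypo))
    if params.missed_bolus.enabled:
        findings.append(detect_missed_bolus_hyper(annotated, window, params.missed_bolus))
    findings.append(assess_adherence(annotated, window, params.adherence)[1])
    if not active:
        findings = [
            replace(f, status=INACTIVE, evidence=()) for f in findings
        ]
    return findings
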