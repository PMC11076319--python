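"""Naive reference implementations of every detector rule.

Used by the synthetic generator to self-check injected ground truth and by
the test suite as the independent route in detector-equivalence checks.
Each rule is a direct enumeration over all day runs, all sliding-window
placements, or all reading pairs; per-reading classification is computed
once up front, but no scan machinery is shared with
:mod:`smbgpattern.patterns`.
"""

from __future__ import annotations

from datetime import timedelta
from typing import Optional, Sequence

from .core import (
    AnalysisWindow,
    GlucoseReading,
    GlycemicClass,
    MEAL_PAIRS,
    analysis_day,
    assign_block,
    classify_reading,
    readings_in_window,
)
from .config import AnalysisConfig


class _Prepared:
    """Window-restricted readings with per-reading day/block/class."""

    def __init__(self, readings, window: AnalysisWindow, cfg: AnalysisConfig):
        self.rs = readings_in_window(readings, window, cfg.day_start)
        self.days = [analysis_day(r.timestamp, cfg.day_start) for r in self.rs]
        self.blocks = [assign_block(r, cfg.scheme) for r in self.rs]
        self.classes = [classify_reading(r, cfg.thresholds) for r in self.rs]
        self.hypo = [c in (GlycemicClass.VERY_LOW, GlycemicClass.HYPO) for c in self.classes]
        self.hyper = [c in (GlycemicClass.HYPER, GlycemicClass.VERY_HIGH) for c in self.classes]
        self.window = window


def oracle_trend(prep: _Prepared, per_day: int, run_days: int, kind: str) -> bool:
    """True if some run of run_days consecutive days each holds >= per_day
    qualifying readings; every possible start day is tried."""
    flags = prep.hypo if kind == "hypo" else prep.hyper
    days = prep.window.days()
    for start in range(len(days) - run_days + 1):
        ok = True
        for offset in range(run_days):
            day = days[start + offset]
            n = sum(1 for d, f in zip(prep.days, flags) if f and d == day)
            if n < per_day:
                ok = False
                break
        if ok:
            return True
    return False


def oracle_level_count(prep: _Prepared, tests: int, level: float, kind: str) -> bool:
    """Count readings strictly beyond level over the whole window."""
    if kind == "very_high":
        n = sum(1 for r in prep.rs if r.value > level)
    else:
        n = sum(1 for r in prep.rs if r.value < level)
    return n >= tests


def oracle_time_block(
    prep: _Prepared, cfg: AnalysisConfig, events_in_block: int, span_days: int, kind: str
) -> bool:
    """Enumerate every (block, window placement) pair."""
    flags = prep.hypo if kind == "hypo" else prep.hyper
    days = prep.window.days()
    n_starts = max(len(days) - span_days + 1, 1)
    for block in cfg.scheme.block_names:
        for start in range(n_starts):
            lo = days[start]
            hi = lo + timedelta(days=span_days - 1)
            n = sum(
                1
                for d, b, f in zip(prep.days, prep.blocks, flags)
                if f and b == block and lo <= d <= hi
            )
            if n >= events_in_block:
                return True
    return False


def oracle_pairs(prep: _Prepared, pattern_count: int, window_hours: float, kind: str) -> bool:
    """Enumerate all ordered pairs; the in-between interruption test uses a
    prefix count of in-range readings."""
    in_range_prefix = [0]
    for c in prep.classes:
        in_range_prefix.append(in_range_prefix[-1] + (c == GlycemicClass.IN_RANGE))
    if kind == "hypo_after_hyper":
        first_ok, second_ok = prep.hyper, prep.hypo
    else:
        first_ok, second_ok = prep.hypo, prep.hyper
    max_dt = timedelta(hours=window_hours)
    n_pairs = 0
    for i in range(len(prep.rs)):
        if not first_ok[i]:
            continue
        for j in range(i + 1, len(prep.rs)):
            if prep.rs[j].timestamp - prep.rs[i].timestamp > max_dt:
                break
            interrupted = (in_range_prefix[j] - in_range_prefix[i + 1]) > 0
            if second_ok[j] and not interrupted:
                n_pairs += 1
    return n_pairs >= pattern_count


def oracle_missed_bolus(prep: _Prepared, pattern_count: int) -> Optional[bool]:
    """None when no bolus annotations exist (detector inactive)."""
    if all(r.bolus_given is None for r in prep.rs):
        return None
    n = 0
    for pre_tag, post_tag in MEAL_PAIRS:
        for r, d, hyper in zip(prep.rs, prep.days, prep.hyper):
            if r.tag != post_tag or not hyper:
                continue
            pres = [
                p
                for p, pd in zip(prep.rs, prep.days)
                if p.tag == pre_tag and pd == d
            ]
            if pres and pres[0].bolus_given is False:
                n += 1
    return n >= pattern_count


def oracle_statuses(
    readings: Sequence[GlucoseReading],
    window: AnalysisWindow,
    cfg: AnalysisConfig,
) -> dict[str, Optional[bool]]:
    """Reference red/clear verdict for every detector under the given config
    (None for an inactive missed-bolus detector)."""
    p = cfg.patterns.clamped()
    prep = _Prepared(readings, window, cfg)
    return {
        "hypo_trend": oracle_trend(
            prep, p.hypo_trend.count, p.hypo_trend.consecutive_days, "hypo"
        ),
        "hypo_time_block": oracle_time_block(
            prep, cfg, p.hypo_time_block.events_in_block, p.hypo_time_block.days, "hypo"
        ),
        "very_low_trend": oracle_level_count(
            prep, p.very_low_trend.tests, p.very_low_trend.level, "very_low"
        ),
        "hypo_after_hyper": oracle_pairs(
            prep, p.hypo_after_hyper.pattern_count,
            p.hypo_after_hyper.pairing_window_hours, "hypo_after_hyper",
        ),
        "hyper_trend": oracle_trend(
            prep, p.hyper_trend.count, p.hyper_trend.consecutive_days, "hyper"
        ),
        "hyper_time_block": oracle_time_block(
            prep, cfg, p.hyper_time_block.events_in_block, p.hyper_time_block.days, "hyper"
        ),
        "very_high_trend": oracle_level_count(
            prep, p.very_high_trend.tests, p.very_high_trend.level, "very_high"
        ),
        "hyper_after_hypo": oracle_pairs(
            prep, p.hyper_after_hypo.pattern_count,
            p.hyper_after_hypo.pairing_window_hours, "hyper_after_hypo",
        ),
        "missed_bolus_hyper": oracle_missed_bolus(prep, p.missed_bolus.pattern_count),
    }
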