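"""Orchestration of the 3-step analysis: sufficiency gate, pattern detectors,
variability gate, categorical action flags, and period comparison.

Action-flag mapping:
 - sufficiency gate failed -> investigate_low_adherence, plan_education_session,
   review_single_events (single extreme events still get examined);
 - any red hypoglycemia-block detector -> review_correction_rules +
   consider_deintensify_treatment;
 - any red hyperglycemia-block detector -> consider_intensify_treatment;
 - red missed-bolus heuristic -> review_isf_carb_ratio;
 - red adherence -> investigate_low_adherence, plan_education_session,
   reinforce_lifestyle;
 - high CV class -> intensify_smbg_before_change, and any treatment-change
   flag (consider_*_treatment) is suppressed: changing therapy under high
   variability raises hypo/hyper risk, so measurement is intensified first.

Flags are emitted in fixed priority order with hypoglycemia-derived flags
first. No dosing arithmetic and no free text beyond fixed rationale strings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import __version__
from .core import (
    AnalysisWindow,
    GlucoseReading,
    GlycemicClass,
    analysis_day,
    assign_block,
    classify_reading,
    group_by_day,
    is_hyper_event,
    is_hypo_event,
    readings_in_window,
)
from .config import AnalysisConfig
from .patterns import (
    BLOCK_HYPER,
    BLOCK_HYPO,
    PatternFinding,
    RED,
    run_all_patterns,
)
from .sufficiency import SufficiencyResult, assess_sufficiency
from .variability import (
    CV_HIGH,
    UndefinedVariabilityError,
    VariabilityReport,
    variability_report,
)

SCHEMA_VERSION = 1

# flag codes
INVESTIGATE_LOW_ADHERENCE = "investigate_low_adherence"
PLAN_EDUCATION_SESSION = "plan_education_session"
REVIEW_SINGLE_EVENTS = "review_single_events"
INTENSIFY_SMBG_BEFORE_CHANGE = "intensify_smbg_before_change"
CONSIDER_INTENSIFY_TREATMENT = "consider_intensify_treatment"
CONSIDER_DEINTENSIFY_TREATMENT = "consider_deintensify_treatment"
REVIEW_CORRECTION_RULES = "review_correction_rules"
REVIEW_ISF_CARB_RATIO = "review_isf_carb_ratio"
REINFORCE_LIFESTYLE = "reinforce_lifestyle"

TREATMENT_CHANGE_FLAGS = {CONSIDER_INTENSIFY_TREATMENT, CONSIDER_DEINTENSIFY_TREATMENT}

#: Output order; hypoglycemia-derived flags sort first.
FLAG_PRIORITY = (
    REVIEW_CORRECTION_RULES,
    CONSIDER_DEINTENSIFY_TREATMENT,
    CONSIDER_INTENSIFY_TREATMENT,
    REVIEW_ISF_CARB_RATIO,
    INTENSIFY_SMBG_BEFORE_CHANGE,
    INVESTIGATE_LOW_ADHERENCE,
    PLAN_EDUCATION_SESSION,
    REVIEW_SINGLE_EVENTS,
    REINFORCE_LIFESTYLE,
)

RATIONALES = {
    INVESTIGATE_LOW_ADHERENCE: "Test quantity or quality below minimum; investigate reasons for low adherence.",
    PLAN_EDUCATION_SESSION: "Plan an educational session on the value of structured testing.",
    REVIEW_SINGLE_EVENTS: "Examine single hypoglycemic and hyperglycemic events before the next visit.",
    INTENSIFY_SMBG_BEFORE_CHANGE: "High glycemic variability; intensify testing before changing therapy.",
    CONSIDER_INTENSIFY_TREATMENT: "Recurrent hyperglycemia pattern; consider intensifying ongoing treatment.",
    CONSIDER_DEINTENSIFY_TREATMENT: "Recurrent hypoglycemia pattern; consider de-intensifying ongoing treatment.",
    REVIEW_CORRECTION_RULES: "Recurrent hypoglycemia; review rules used to correct highs and lows.",
    REVIEW_ISF_CARB_RATIO: "Post-meal hyperglycemia with missed bolus; review insulin sensitivity factor and carb ratio.",
    REINFORCE_LIFESTYLE: "Reinforce lifestyle measures: balanced diet, regular exercise, medication as prescribed.",
}


@dataclass(frozen=True)
class ActionFlag:
    code: str
    triggered_by: tuple[str, ...]
    rationale: str

    def to_dict(self) -> dict:
        return {
            "code": self.code,
            "triggered_by": list(self.triggered_by),
            "rationale": self.rationale,
        }


@dataclass(frozen=True)
class AnalysisReport:
    window: AnalysisWindow
    sufficiency: SufficiencyResult
    patterns: list[PatternFinding]
    variability: Optional[VariabilityReport]
    actions: list[ActionFlag]
    matrix: dict[str, dict[str, int]]  # day -> block -> reading count
    config: AnalysisConfig
    input_digest: str

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "tool": {"name": "smbgpattern", "version": __version__},
            "input_digest": self.input_digest,
            "window": {
                "start": self.window.start.isoformat(),
                "end": self.window.end.isoformat(),
            },
            "sufficiency": self.sufficiency.to_dict(),
            "patterns": [f.to_dict() for f in self.patterns],
            "variability": None if self.variability is None else self.variability.to_dict(),
            "actions": [a.to_dict() for a in self.actions],
            "daily_block_matrix": {d: dict(row) for d, row in self.matrix.items()},
            "config": self.config.to_dict(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, allow_nan=False)


def input_digest(readings: Sequence[GlucoseReading]) -> str:
    """Stable digest of the reading set (order-insensitive canonical form)."""
    canon = "\n".join(
        sorted(
            f"{r.timestamp.isoformat()}|{r.value!r}|{r.tag.value}|{r.bolus_given}|{r.carbs_logged}"
            for r in readings
        )
    )
    return hashlib.sha256(canon.encode()).hexdigest()


def derive_actions(
    sufficiency: SufficiencyResult,
    patterns: Sequence[PatternFinding],
    variability: Optional[VariabilityReport],
) -> list[ActionFlag]:
    """Map gate outcomes and red findings to categorical action flags."""
    triggers: dict[str, list[str]] = {}

    def add(code: str, source: str) -> None:
        triggers.setdefault(code, [])
        if source not in triggers[code]:
            triggers[code].append(source)

    if not sufficiency.pattern_analysis_active:
        add(INVESTIGATE_LOW_ADHERENCE, "sufficiency")
        add(PLAN_EDUCATION_SESSION, "sufficiency")
        add(REVIEW_SINGLE_EVENTS, "sufficiency")
    else:
        for f in patterns:
            if f.status != RED:
                continue
            if f.detector == "missed_bolus_hyper":
                add(REVIEW_ISF_CARB_RATIO, f.detector)
            elif f.detector == "adherence":
                add(INVESTIGATE_LOW_ADHERENCE, f.detector)
                add(PLAN_EDUCATION_SESSION, f.detector)
                add(REINFORCE_LIFESTYLE, f.detector)
            elif f.block == BLOCK_HYPO:
                add(REVIEW_CORRECTION_RULES, f.detector)
                add(CONSIDER_DEINTENSIFY_TREATMENT, f.detector)
            elif f.block == BLOCK_HYPER:
                add(CONSIDER_INTENSIFY_TREATMENT, f.detector)
        if variability is not None and variability.cv_class == CV_HIGH:
            add(INTENSIFY_SMBG_BEFORE_CHANGE, "cv_gate")
            for code in TREATMENT_CHANGE_FLAGS & set(triggers):
                del triggers[code]

    return [
        ActionFlag(code=c, triggered_by=tuple(triggers[c]), rationale=RATIONALES[c])
        for c in FLAG_PRIORITY
        if c in triggers
    ]


def _daily_block_matrix(readings, window, config) -> dict[str, dict[str, int]]:
    matrix = {
        d.isoformat(): {name: 0 for name in config.scheme.block_names}
        for d in window.days()
    }
    for r in readings:
        d = analysis_day(r.timestamp, config.day_start).isoformat()
        matrix[d][assign_block(r, config.scheme)] += 1
    return matrix


def run_flowchart(
    readings: Sequence[GlucoseReading],
    window: AnalysisWindow,
    config: AnalysisConfig,
) -> AnalysisReport:
    """Run the full 3-step analysis over one window."""
    in_window = readings_in_window(readings, window, config.day_start)
    suff = assess_sufficiency(
        in_window, window, config.sufficiency, config.scheme, config.day_start
    )
    active = suff.pattern_analysis_active
    findings = run_all_patterns(
        in_window,
        window,
        config.thresholds,
        config.scheme,
        config.patterns,
        config.day_start,
        active=active,
    )
    try:
        var = variability_report(
            in_window, config.cv_cutpoints, config.day_start, config.cv_gate_basis
        )
    except UndefinedVariabilityError:
        var = None
    actions = derive_actions(suff, findings, var)
    return AnalysisReport(
        window=window,
        sufficiency=suff,
        patterns=findings,
        variability=var,
        actions=actions,
        matrix=_daily_block_matrix(in_window, window, config),
        config=config,
        input_digest=input_digest(in_window),
    )


def compare_periods(
    readings: Sequence[GlucoseReading],
    window_a: AnalysisWindow,
    window_b: AnalysisWindow,
    config: AnalysisConfig,
) -> dict:
    """Paired analysis of two disjoint windows with per-metric deltas (B - A)
    and detector status transitions."""
    if window_a.start <= window_b.end and window_b.start <= window_a.end:
        raise ValueError("comparison windows must be disjoint")
    report_a = run_flowchart(readings, window_a, config)
    report_b = run_flowchart(readings, window_b, config)
    for label, rep in (("A", report_a), ("B", report_b)):
        if rep.variability is None:
            raise UndefinedVariabilityError(
                f"window {label} holds fewer than 2 readings; deltas undefined"
            )

    va, vb = report_a.variability, report_b.variability
    deltas = {
        "mean_glucose": vb.mean_glucose - va.mean_glucose,
        "sd": vb.sd - va.sd,
        "cv_percent": vb.cv_percent - va.cv_percent,
        "lbgi": vb.lbgi - va.lbgi,
        "hbgi": vb.hbgi - va.hbgi,
    }

    def block_event_counts(rep: AnalysisReport) -> dict[str, dict[str, int]]:
        rs = readings_in_window(readings, rep.window, config.day_start)
        counts = {
            name: {"hypo": 0, "hyper": 0} for name in config.scheme.block_names
        }
        for r in rs:
            cls = classify_reading(r, config.thresholds)
            b = assign_block(r, config.scheme)
            if is_hypo_event(cls):
                counts[b]["hypo"] += 1
            if is_hyper_event(cls):
                counts[b]["hyper"] += 1
        return counts

    counts_a, counts_b = block_event_counts(report_a), block_event_counts(report_b)
    per_block = {
        name: {
            "hypo": counts_b[name]["hypo"] - counts_a[name]["hypo"],
            "hyper": counts_b[name]["hyper"] - counts_a[name]["hyper"],
        }
        for name in config.scheme.block_names
    }

    status_a = {f.detector: f.status for f in report_a.patterns}
    status_b = {f.detector: f.status for f in report_b.patterns}
    transitions = {
        det: f"{status_a[det]}->{status_b[det]}"
        for det in status_a
        if det in status_b and status_a[det] != status_b[det]
    }

    return {
        "schema_version": SCHEMA_VERSION,
        "report_a": report_a.to_dict(),
        "report_b": report_b.to_dict(),
        "deltas": {k: round(v, 6) for k, v in deltas.items()},
        "per_block_event_deltas": per_block,
        "pattern_transitions": transitions,
    }
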