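"""Synthetic structured-SMBG log generation with verifiable ground truth.

Regimen templates place tagged readings at fixed clock times (7-point
profiles: fasting, pre/post each meal, bedtime; staggered 5-point variants).
Baseline values are drawn from a lognormal day effect plus Gaussian
within-day noise around time-of-day means (post-meal offset +40 mg/dL by
default) and, by default, clamped into the in-range band so that injected
patterns are the only events present. Injections overwrite specific schedule
slots to exactly meet — or exactly miss by one unit — each detector's
default trigger; generated logs are self-checked against the brute-force
rule oracles before being returned.

All randomness flows through one seeded numpy Generator; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Optional, Sequence

import numpy as np

from .config import AnalysisConfig
from .core import (
    AnalysisWindow,
    GlucoseReading,
    POST_MEAL_TAGS,
    Tag,
)
from .oracles import oracle_statuses


class SimulationError(ValueError):
    """Infeasible injection or unreachable simulation target."""


@dataclass(frozen=True)
class SchedulePoint:
    clock: time
    tag: Tag


@dataclass(frozen=True)
class RegimenTemplate:
    """Named per-day testing schedule (1-10 points per day)."""

    name: str
    points: tuple[SchedulePoint, ...]

    def __post_init__(self) -> None:
        if not (1 <= len(self.points) <= 10):
            raise SimulationError("regimen must hold 1-10 points per day")
        clocks = [p.clock for p in self.points]
        if sorted(clocks) != clocks or len(set(clocks)) != len(clocks):
            raise SimulationError("schedule points must be strictly increasing in time")

    @classmethod
    def seven_point(cls) -> "RegimenTemplate":
        """Fasting, pre/post each meal, bedtime."""
        return cls(
            name="seven_point",
            points=(
                SchedulePoint(time(7, 0), Tag.FASTING),
                SchedulePoint(time(9, 0), Tag.POST_BREAKFAST),
                SchedulePoint(time(12, 0), Tag.PRE_LUNCH),
                SchedulePoint(time(14, 0), Tag.POST_LUNCH),
                SchedulePoint(time(18, 0), Tag.PRE_DINNER),
                SchedulePoint(time(20, 0), Tag.POST_DINNER),
                SchedulePoint(time(22, 0), Tag.BEDTIME),
            ),
        )

    @classmethod
    def five_point(cls) -> "RegimenTemplate":
        """Staggered 5-point day: fasting, around lunch and dinner, bedtime."""
        return cls(
            name="five_point",
            points=(
                SchedulePoint(time(7, 0), Tag.FASTING),
                SchedulePoint(time(12, 0), Tag.PRE_LUNCH),
                SchedulePoint(time(18, 0), Tag.PRE_DINNER),
                SchedulePoint(time(20, 0), Tag.POST_DINNER),
                SchedulePoint(time(22, 0), Tag.BEDTIME),
            ),
        )


@dataclass(frozen=True)
class Injection:
    """Shape values at one detector's default trigger (or one unit below)."""

    pattern: str
    start_day: int = 0
    at_trigger: bool = True


@dataclass(frozen=True)
class SimulationSpec:
    seed: int
    n_days: int = 28
    regimen: RegimenTemplate = field(default_factory=RegimenTemplate.seven_point)
    start: date = date(2024, 1, 1)
    base_mean: float = 110.0
    postmeal_offset: float = 40.0
    interday_cv_percent: float = 5.0
    intraday_sd: float = 8.0
    injections: tuple[Injection, ...] = ()
    missingness: float = 0.0
    clamp_in_range: bool = True

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise SimulationError("n_days must be >= 1")
        if not (0.0 <= self.missingness < 1.0):
            raise SimulationError("missingness must lie in [0, 1)")


@dataclass
class _Slot:
    day: int
    point: SchedulePoint
    value: float
    bolus_given: Optional[bool] = None
    injected: bool = False


@dataclass(frozen=True)
class SimulatedLog:
    readings: list[GlucoseReading]
    labels: dict[str, Optional[bool]]
    window: AnalysisWindow
    spec: SimulationSpec

    def red_detectors(self) -> set[str]:
        return {d for d, v in self.labels.items() if v is True}


# values used by injections: safely inside the intended class under the
# default thresholds (hypo<70 but >=54; hyper>180 but <=250; etc.)
_HYPO_VALUE = 62.0
_HYPER_VALUE = 200.0
_VERY_HIGH_AT, _VERY_HIGH_BELOW = 260.0, 250.0
_VERY_LOW_AT, _VERY_LOW_BELOW = 53.0, 54.0


def _slot_index(regimen: RegimenTemplate, tag: Tag) -> int:
    for i, p in enumerate(regimen.points):
        if p.tag == tag:
            return i
    raise SimulationError(f"regimen {regimen.name!r} has no {tag.value!r} point")


def _require_days(spec: SimulationSpec, inj: Injection, needed: int) -> None:
    if inj.start_day < 0 or inj.start_day + needed > spec.n_days:
        raise SimulationError(
            f"injection {inj.pattern!r} needs {needed} day(s) from day "
            f"{inj.start_day} but the simulation has {spec.n_days}"
        )


def _apply_injection(
    slots: list[list[_Slot]], spec: SimulationSpec, inj: Injection
) -> None:
    reg = spec.regimen
    n_pts = len(reg.points)

    def set_slot(day: int, point_idx: int, value: float, bolus=None) -> None:
        s = slots[day][point_idx]
        s.value = value
        s.injected = True
        if bolus is not None:
            s.bolus_given = bolus

    if inj.pattern == "hypo_trend":
        # 1 hypo event/day on 2 consecutive days; use two different blocks so
        # the time-block detector is not co-triggered.
        days_needed = 2 if inj.at_trigger else 1
        _require_days(spec, inj, days_needed)
        if n_pts < 2:
            raise SimulationError("hypo_trend injection needs >= 2 points/day")
        set_slot(inj.start_day, 0, _HYPO_VALUE)
        if inj.at_trigger:
            set_slot(inj.start_day + 1, n_pts - 1, _HYPO_VALUE)
    elif inj.pattern == "hyper_trend":
        # 2 hyper tests/day on 3 consecutive days
        days_needed = 3 if inj.at_trigger else 2
        _require_days(spec, inj, days_needed)
        if n_pts < 2:
            raise SimulationError("hyper_trend injection needs >= 2 points/day")
        for d in range(days_needed):
            set_slot(inj.start_day + d, 0, _HYPER_VALUE)
            set_slot(inj.start_day + d, n_pts - 1, _HYPER_VALUE)
    elif inj.pattern == "very_high_trend":
        _require_days(spec, inj, 1)
        set_slot(inj.start_day, 0, _VERY_HIGH_AT if inj.at_trigger else _VERY_HIGH_BELOW)
    elif inj.pattern == "very_low_trend":
        _require_days(spec, inj, 1)
        set_slot(inj.start_day, 0, _VERY_LOW_AT if inj.at_trigger else _VERY_LOW_BELOW)
    elif inj.pattern == "hypo_time_block":
        # 2 hypo events in the same block within 7 days (at) / 8 days (below);
        # non-consecutive days keep the hypo trend clear.
        gap = 6 if inj.at_trigger else 7
        _require_days(spec, inj, gap + 1)
        set_slot(inj.start_day, 0, _HYPO_VALUE)
        set_slot(inj.start_day + gap, 0, _HYPO_VALUE)
    elif inj.pattern == "hyper_time_block":
        gap = 6 if inj.at_trigger else 7
        _require_days(spec, inj, gap + 1)
        set_slot(inj.start_day, 0, _HYPER_VALUE)
        set_slot(inj.start_day + gap, 0, _HYPER_VALUE)
    elif inj.pattern in ("hypo_after_hyper", "hyper_after_hypo"):
        _require_days(spec, inj, 1)
        i_pre = _slot_index(reg, Tag.PRE_LUNCH)
        i_post = _slot_index(reg, Tag.POST_LUNCH)
        first, second = (
            (_HYPER_VALUE, _HYPO_VALUE)
            if inj.pattern == "hypo_after_hyper"
            else (_HYPO_VALUE, _HYPER_VALUE)
        )
        set_slot(inj.start_day, i_pre, first)
        if inj.at_trigger:
            set_slot(inj.start_day, i_post, second)
    elif inj.pattern == "missed_bolus_hyper":
        _require_days(spec, inj, 1)
        i_pre = _slot_index(reg, Tag.PRE_LUNCH)
        i_post = _slot_index(reg, Tag.POST_LUNCH)
        slots[inj.start_day][i_pre].bolus_given = not inj.at_trigger
        slots[inj.start_day][i_pre].injected = True
        set_slot(inj.start_day, i_post, _HYPER_VALUE)
    else:
        raise SimulationError(f"unknown injection pattern {inj.pattern!r}")


def simulate_log(
    spec: SimulationSpec, config: Optional[AnalysisConfig] = None
) -> SimulatedLog:
    """Generate a log and its oracle-verified detector labels.

    The returned labels are the brute-force oracle verdicts for every
    detector on the final log; each injection is additionally self-checked
    (at-trigger must fire, below-trigger must stay clear) and a mismatch
    raises :class:`SimulationError`.
    """
    cfg = config if config is not None else AnalysisConfig.default()
    if any(i.pattern == "missed_bolus_hyper" for i in spec.injections):
        # the detector is only active with annotations present and enabled
        from .patterns import PairingParams

        cfg = replace(cfg, patterns=replace(cfg.patterns, missed_bolus=PairingParams(enabled=True)))
    rng = np.random.default_rng(spec.seed)

    sigma_inter = spec.interday_cv_percent / 100.0
    has_bolus_context = any(i.pattern == "missed_bolus_hyper" for i in spec.injections)

    slots: list[list[_Slot]] = []
    for d in range(spec.n_days):
        day_mult = float(np.exp(rng.normal(0.0, sigma_inter))) if sigma_inter > 0 else 1.0
        day_slots = []
        for p in spec.regimen.points:
            mean = spec.base_mean + (spec.postmeal_offset if p.tag in POST_MEAL_TAGS else 0.0)
            value = mean * day_mult
            if spec.intraday_sd > 0:
                value += float(rng.normal(0.0, spec.intraday_sd))
            if spec.clamp_in_range:
                lo = cfg.thresholds.hypo_limit + 10.0
                hi = cfg.thresholds.hyper_limit_for(p.tag) - 5.0
                value = min(max(value, lo), hi)
            value = float(min(max(value, 20.0), 600.0))
            bolus = True if (has_bolus_context and p.tag not in POST_MEAL_TAGS) else None
            day_slots.append(_Slot(day=d, point=p, value=round(value, 1), bolus_given=bolus))
        slots.append(day_slots)

    for inj in spec.injections:
        _apply_injection(slots, spec, inj)

    readings: list[GlucoseReading] = []
    for day_slots in slots:
        for s in day_slots:
            if not s.injected and spec.missingness > 0 and rng.random() < spec.missingness:
                continue
            ts = datetime.combine(spec.start + timedelta(days=s.day), s.point.clock)
            readings.append(
                GlucoseReading(
                    timestamp=ts,
                    value=s.value,
                    tag=s.point.tag,
                    bolus_given=s.bolus_given,
                )
            )

    window = AnalysisWindow(spec.start, spec.start + timedelta(days=spec.n_days - 1))
    labels = oracle_statuses(readings, window, cfg)
    for inj in spec.injections:
        actual = labels[inj.pattern]
        if bool(actual) != inj.at_trigger:
            raise SimulationError(
                f"self-check failed: injection {inj.pattern!r} "
                f"(at_trigger={inj.at_trigger}) but oracle says {actual!r}"
            )
    return SimulatedLog(readings=readings, labels=labels, window=window, spec=spec)


def sweep_cv(
    spec: SimulationSpec,
    targets: Sequence[float],
    tolerance: float = 1.0,
    max_retries: int = 12,
) -> list[tuple[float, SimulatedLog, float]]:
    """Generate one log per CV target with realized overall CV within
    ``tolerance`` percentage points; raises when a target is unreachable
    (e.g., any positive target under zero noise)."""
    out = []
    # a spec with no randomness at all pins the realized CV; respect it
    frozen_noise = spec.interday_cv_percent == 0 and spec.intraday_sd == 0
    for k, target in enumerate(targets):
        if target < 0:
            raise SimulationError("CV target must be non-negative")
        # interday CV percent is approximately the realized CV
        sigma_pct = 0.0 if frozen_noise else target
        best = None
        for attempt in range(max_retries):
            # fixed seed per target: realized CV is then a deterministic,
            # monotone function of sigma and the update converges
            trial = replace(
                spec,
                seed=spec.seed + 1000 * k,
                interday_cv_percent=sigma_pct,
                clamp_in_range=False,
                injections=(),
            )
            log = simulate_log(trial)
            values = np.array([r.value for r in log.readings], dtype=float)
            if values.size < 2:
                raise SimulationError("need >= 2 readings to realize a CV target")
            realized = 100.0 * float(values.std(ddof=1)) / float(values.mean())
            if abs(realized - target) <= tolerance:
                best = (target, log, realized)
                break
            if frozen_noise:
                break  # nothing to adjust: the realized CV cannot move
            if realized > 0:
                sigma_pct = max(sigma_pct * (target / realized), 0.0)
            elif target > 0:
                break  # degenerate constant log: positive targets unreachable
        if best is None:
            raise SimulationError(
                f"could not realize CV target {target}% within ±{tolerance} pp "
                f"after {max_retries} attempts"
            )
        out.append(best)
    return out
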