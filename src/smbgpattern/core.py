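"""Domain types shared by every analysis stage.

Glucose readings, tag vocabulary, glycemic classification thresholds,
time-block schemes partitioning the 24-h day, and analysis-day arithmetic.
All glucose values are mg/dL internally; mmol/L inputs are converted at
ingest (see :mod:`smbgpattern.io`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Mapping, Optional, Sequence

MMOL_TO_MGDL = 18.016


class DataError(ValueError):
    """Raised for physically impossible or structurally invalid input data."""


class Tag(str, enum.Enum):
    """Measurement context recorded with a reading."""

    FASTING = "fasting"
    PRE_BREAKFAST = "pre_breakfast"
    POST_BREAKFAST = "post_breakfast"
    PRE_LUNCH = "pre_lunch"
    POST_LUNCH = "post_lunch"
    PRE_DINNER = "pre_dinner"
    POST_DINNER = "post_dinner"
    BEDTIME = "bedtime"
    NIGHT = "night"
    PRE_EXERCISE = "pre_exercise"
    OTHER = "other"


#: Tags for which the post-meal hyperglycemia limit applies.
POST_MEAL_TAGS = frozenset({Tag.POST_BREAKFAST, Tag.POST_LUNCH, Tag.POST_DINNER})

#: (pre-meal tag, post-meal tag) pairs for the same meal.
MEAL_PAIRS = (
    (Tag.PRE_BREAKFAST, Tag.POST_BREAKFAST),
    (Tag.PRE_LUNCH, Tag.POST_LUNCH),
    (Tag.PRE_DINNER, Tag.POST_DINNER),
)


class GlycemicClass(enum.IntEnum):
    """Ordered glycemic classification; ordering follows the glucose scale."""

    VERY_LOW = 0
    HYPO = 1
    IN_RANGE = 2
    HYPER = 3
    VERY_HIGH = 4


@dataclass(frozen=True)
class GlucoseReading:
    """One timestamped SMBG measurement.

    Parameters
    ----------
    timestamp : datetime
        Local date-time of the measurement (minute resolution).
    value : float
        Glucose concentration in mg/dL; must lie in (0, 1000).
    tag : Tag
        Measurement context.
    bolus_given : bool, optional
        Whether an insulin bolus was recorded with this reading.
    carbs_logged : bool, optional
        Whether carbohydrate intake was logged with this reading.
    """

    timestamp: datetime
    value: float
    tag: Tag = Tag.OTHER
    bolus_given: Optional[bool] = None
    carbs_logged: Optional[bool] = None

    def __post_init__(self) -> None:
        if not isinstance(self.timestamp, datetime):
            raise DataError(f"timestamp must be a datetime, got {self.timestamp!r}")
        if not (0 < self.value < 1000):
            raise DataError(
                f"glucose value {self.value} mg/dL outside plausible range (0, 1000)"
            )
        if not isinstance(self.tag, Tag):
            object.__setattr__(self, "tag", Tag(self.tag))


@dataclass(frozen=True)
class GlycemicThresholds:
    """Classification limits in mg/dL.

    Strict-inequality semantics: a reading is very low when value < 54,
    hypoglycemic when value < hypo_limit, hyperglycemic when value exceeds
    the tag-dependent limit, very high when value > 250.
    """

    very_low_limit: float = 54.0
    hypo_limit: float = 70.0
    hyper_premeal_limit: float = 130.0
    hyper_postmeal_limit: float = 180.0
    very_high_limit: float = 250.0

    def __post_init__(self) -> None:
        if not (
            self.very_low_limit
            < self.hypo_limit
            < self.hyper_premeal_limit
            <= self.hyper_postmeal_limit
            < self.very_high_limit
        ):
            raise DataError(
                "thresholds must satisfy very_low < hypo < hyper_premeal "
                "<= hyper_postmeal < very_high, got "
                f"{self.very_low_limit}/{self.hypo_limit}/{self.hyper_premeal_limit}"
                f"/{self.hyper_postmeal_limit}/{self.very_high_limit}"
            )

    def hyper_limit_for(self, tag: Tag) -> float:
        return (
            self.hyper_postmeal_limit if tag in POST_MEAL_TAGS else self.hyper_premeal_limit
        )


def classify_value(value: float, tag: Tag, thresholds: GlycemicThresholds) -> GlycemicClass:
    """Classify a glucose value given its tag; exactly one class applies."""
    if value < thresholds.very_low_limit:
        return GlycemicClass.VERY_LOW
    if value < thresholds.hypo_limit:
        return GlycemicClass.HYPO
    if value > thresholds.very_high_limit:
        return GlycemicClass.VERY_HIGH
    if value > thresholds.hyper_limit_for(tag):
        return GlycemicClass.HYPER
    return GlycemicClass.IN_RANGE


def classify_reading(reading: GlucoseReading, thresholds: GlycemicThresholds) -> GlycemicClass:
    return classify_value(reading.value, reading.tag, thresholds)


def is_hypo_event(cls: GlycemicClass) -> bool:
    """Very-low readings also count as hypoglycemic events (class containment)."""
    return cls <= GlycemicClass.HYPO


def is_hyper_event(cls: GlycemicClass) -> bool:
    """Very-high readings also count as hyperglycemic events."""
    return cls >= GlycemicClass.HYPER


def _minutes(t: time) -> int:
    return t.hour * 60 + t.minute


@dataclass(frozen=True)
class TimeBlock:
    """Half-open block [start, end) of the clock day, in minutes since 00:00."""

    name: str
    start_min: int
    end_min: int


@dataclass(frozen=True)
class TimeBlockScheme:
    """Ordered partition of the 24-h clock day into named blocks.

    Blocks must be contiguous, start at 00:00 and end at 24:00, so every
    clock time maps to exactly one block (half-open convention: a reading
    exactly on a boundary belongs to the block starting there).
    """

    blocks: tuple[TimeBlock, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise DataError("scheme must contain at least one block")
        if self.blocks[0].start_min != 0 or self.blocks[-1].end_min != 1440:
            raise DataError("blocks must cover 00:00-24:00")
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise DataError("block names must be unique")
        for prev, cur in zip(self.blocks, self.blocks[1:]):
            if prev.end_min != cur.start_min:
                raise DataError(
                    f"blocks {prev.name!r} and {cur.name!r} leave a gap or overlap"
                )
        for b in self.blocks:
            if not (0 <= b.start_min < b.end_min <= 1440):
                raise DataError(f"block {b.name!r} has invalid bounds")

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.blocks)

    @classmethod
    def default(cls) -> "TimeBlockScheme":
        return cls(
            blocks=(
                TimeBlock("night", 0, 6 * 60),
                TimeBlock("breakfast", 6 * 60, 10 * 60 + 30),
                TimeBlock("midday", 10 * 60 + 30, 15 * 60),
                TimeBlock("dinner", 15 * 60, 21 * 60),
                TimeBlock("bedtime", 21 * 60, 24 * 60),
            )
        )

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, time, time]]) -> "TimeBlockScheme":
        blocks = []
        for name, start, end in pairs:
            end_min = 1440 if end == time(0, 0) else _minutes(end)
            blocks.append(TimeBlock(name, _minutes(start), end_min))
        return cls(tuple(blocks))


def assign_block(reading: GlucoseReading, scheme: TimeBlockScheme) -> str:
    """Total, deterministic mapping of a reading to its time block name."""
    m = _minutes(reading.timestamp.time())
    for b in scheme.blocks:
        if b.start_min <= m < b.end_min:
            return b.name
    raise AssertionError("unreachable: scheme covers the full day")  # pragma: no cover


@dataclass(frozen=True)
class AnalysisWindow:
    """Inclusive range of analysis days [start, end]."""

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise DataError(f"window end {self.end} precedes start {self.start}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def days(self) -> list[date]:
        return [self.start + timedelta(days=i) for i in range(self.n_days)]

    def contains_day(self, d: date) -> bool:
        return self.start <= d <= self.end


def analysis_day(ts: datetime, day_start: time = time(0, 0)) -> date:
    """Analysis day of a timestamp: a day runs [day_start, next day_start)."""
    return (ts - timedelta(minutes=_minutes(day_start))).date()


def group_by_day(
    readings: Iterable[GlucoseReading], day_start: time = time(0, 0)
) -> dict[date, list[GlucoseReading]]:
    """Group readings by analysis day; each reading lands in exactly one day."""
    out: dict[date, list[GlucoseReading]] = {}
    for r in sorted(readings, key=lambda r: r.timestamp):
        out.setdefault(analysis_day(r.timestamp, day_start), []).append(r)
    return dict(sorted(out.items()))


def readings_in_window(
    readings: Iterable[GlucoseReading],
    window: AnalysisWindow,
    day_start: time = time(0, 0),
) -> list[GlucoseReading]:
    """Readings whose analysis day falls inside the window, timestamp-sorted."""
    return sorted(
        (r for r in readings if window.contains_day(analysis_day(r.timestamp, day_start))),
        key=lambda r: r.timestamp,
    )


def count_by_block(
    readings: Iterable[GlucoseReading], scheme: TimeBlockScheme
) -> dict[str, int]:
    counts = {name: 0 for name in scheme.block_names}
    for r in readings:
        counts[assign_block(r, scheme)] += 1
    return counts
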