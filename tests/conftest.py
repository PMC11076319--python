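from __future__ import annotations

from datetime import date, datetime, time, timedelta

import numpy as np
import pytest

from smbgpattern.config import AnalysisConfig
from smbgpattern.core import AnalysisWindow, GlucoseReading, Tag

TAGS = [t for t in Tag]


def R(ts: str, value: float, tag: str = "other", bolus=None, carbs=None) -> GlucoseReading:
    """Shorthand reading constructor from an ISO timestamp string."""
    return GlucoseReading(
        timestamp=datetime.fromisoformat(ts),
        value=value,
        tag=Tag(tag),
        bolus_given=bolus,
        carbs_logged=carbs,
    )


def random_log(
    rng: np.random.Generator,
    n: int,
    window: AnalysisWindow,
    with_bolus: bool = False,
) -> list[GlucoseReading]:
    """Random readings with unique minute-resolution timestamps inside the
    window; values span every glycemic class."""
    n_days = window.n_days
    total_minutes = n_days * 24 * 60
    n = min(n, total_minutes)
    offsets = rng.choice(total_minutes, size=n, replace=False)
    start_dt = datetime.combine(window.start, time(0, 0))
    readings = []
    for off in sorted(int(o) for o in offsets):
        ts = start_dt + timedelta(minutes=off)
        # mixture covering very_low/hypo/in_range/hyper/very_high
        bucket = rng.random()
        if bucket < 0.10:
            value = rng.uniform(40, 54)
        elif bucket < 0.25:
            value = rng.uniform(54, 70)
        elif bucket < 0.65:
            value = rng.uniform(70, 130)
        elif bucket < 0.90:
            value = rng.uniform(130, 250)
        else:
            value = rng.uniform(250, 450)
        tag = TAGS[int(rng.integers(len(TAGS)))]
        bolus = None
        if with_bolus and rng.random() < 0.5:
            bolus = bool(rng.random() < 0.5)
        readings.append(
            GlucoseReading(timestamp=ts, value=round(float(value), 1), tag=tag, bolus_given=bolus)
        )
    return readings


@pytest.fixture
def default_config() -> AnalysisConfig:
    return AnalysisConfig.default()


@pytest.fixture
def window_14d() -> AnalysisWindow:
    return AnalysisWindow(date(2024, 1, 1), date(2024, 1, 14))


@pytest.fixture
def window_28d() -> AnalysisWindow:
    return AnalysisWindow(date(2024, 1, 1), date(2024, 1, 28))
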