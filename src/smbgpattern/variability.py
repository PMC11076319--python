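"""Glycemic-variability metrics (SD, CV, LBGI, HBGI) and the CV gate.

The low/high blood glucose indices use the log-scale risk symmetrization
f(BG) = 1.509 * ((ln BG)^1.084 - 5.381) for BG in mg/dL, per-reading risk
r(BG) = 10 * f(BG)^2, with LBGI the mean risk over negative-f contributions
and HBGI over positive-f contributions, so LBGI + HBGI equals the mean total
risk. CV classes: low (< 33%), acceptable (33-36%), high (> 36%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import time
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import GlucoseReading, group_by_day

CV_LOW = "low"
CV_ACCEPTABLE = "acceptable"
CV_HIGH = "high"

RISK_A = 1.509
RISK_B = 1.084
RISK_C = 5.381

#: Glucose (mg/dL) at which the risk function crosses zero.
RISK_NEUTRAL_GLUCOSE = math.exp(RISK_C ** (1.0 / RISK_B))


class UndefinedVariabilityError(ValueError):
    """Raised when variability is requested for fewer than 2 readings."""


@dataclass(frozen=True)
class CvCutpoints:
    low_upper: float = 33.0  # cv < low_upper  -> low
    acceptable_upper: float = 36.0  # cv <= acceptable_upper -> acceptable

    def __post_init__(self) -> None:
        if not (0 < self.low_upper <= self.acceptable_upper):
            raise ValueError("cutpoints must satisfy 0 < low_upper <= acceptable_upper")


def risk_transform(values: np.ndarray) -> np.ndarray:
    """f(BG) on an array of mg/dL values."""
    return RISK_A * (np.log(values) ** RISK_B - RISK_C)


def compute_sd_cv(values: Sequence[float]) -> tuple[float, float, float]:
    """Mean, sample SD (n-1 denominator), and CV in percent."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise UndefinedVariabilityError(
            f"variability undefined for {arr.size} reading(s); need >= 2"
        )
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return mean, sd, 100.0 * sd / mean


def compute_lbgi_hbgi(values: Sequence[float]) -> tuple[float, float]:
    """LBGI and HBGI over all readings; both non-negative and summing to the
    mean total risk."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise UndefinedVariabilityError("LBGI/HBGI need at least one reading")
    if np.any(arr <= 0):
        raise ValueError("glucose values must be positive")
    f = risk_transform(arr)
    r = 10.0 * f**2
    lbgi = float(np.mean(np.where(f < 0, r, 0.0)))
    hbgi = float(np.mean(np.where(f > 0, r, 0.0)))
    return lbgi, hbgi


def classify_cv(cv_percent: float, cutpoints: CvCutpoints = CvCutpoints()) -> str:
    if cv_percent < cutpoints.low_upper:
        return CV_LOW
    if cv_percent <= cutpoints.acceptable_upper:
        return CV_ACCEPTABLE
    return CV_HIGH


@dataclass(frozen=True)
class VariabilityReport:
    mean_glucose: float
    sd: float
    cv_percent: float
    lbgi: float
    hbgi: float
    cv_class: str
    n_readings: int
    daily_mean_cv_percent: Optional[float]  # CV of mean daily glucose; None if < 2 days
    gate_basis: str  # which CV drives cv_class: "overall" or "daily_means"

    def to_dict(self) -> dict:
        return {
            "mean_glucose": round(self.mean_glucose, 6),
            "sd": round(self.sd, 6),
            "cv_percent": round(self.cv_percent, 6),
            "lbgi": round(self.lbgi, 6),
            "hbgi": round(self.hbgi, 6),
            "cv_class": self.cv_class,
            "n_readings": self.n_readings,
            "daily_mean_cv_percent": (
                None
                if self.daily_mean_cv_percent is None
                else round(self.daily_mean_cv_percent, 6)
            ),
            "gate_basis": self.gate_basis,
        }


def variability_report(
    readings: Iterable[GlucoseReading],
    cutpoints: CvCutpoints = CvCutpoints(),
    day_start: time = time(0, 0),
    gate_basis: str = "overall",
) -> VariabilityReport:
    """Full variability panel over a reading set (needs >= 2 readings).

    The categorical class is driven by the overall CV by default; set
    ``gate_basis="daily_means"`` to gate on the CV of mean daily glucose
    (falls back to overall when fewer than 2 days are present).
    """
    readings = list(readings)
    values = [r.value for r in readings]
    mean, sd, cv = compute_sd_cv(values)
    lbgi, hbgi = compute_lbgi_hbgi(values)

    daily_means = [
        float(np.mean([r.value for r in day_readings]))
        for day_readings in group_by_day(readings, day_start).values()
    ]
    daily_cv = compute_sd_cv(daily_means)[2] if len(daily_means) >= 2 else None

    if gate_basis == "daily_means" and daily_cv is not None:
        gate_cv = daily_cv
    else:
        gate_cv = cv
    return VariabilityReport(
        mean_glucose=mean,
        sd=sd,
        cv_percent=cv,
        lbgi=lbgi,
        hbgi=hbgi,
        cv_class=classify_cv(gate_cv, cutpoints),
        n_readings=len(values),
        daily_mean_cv_percent=daily_cv,
        gate_basis=gate_basis,
    )
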