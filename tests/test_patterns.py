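from __future__ import annotations

from dataclasses import replace
from datetime import date, time

import numpy as np
import pytest

from smbgpattern.config import AnalysisConfig
from smbgpattern.core import AnalysisWindow, GlycemicThresholds, TimeBlockScheme
from smbgpattern.oracles import oracle_statuses
from smbgpattern.patterns import (
    AdherenceParams,
    LevelParams,
    PairingParams,
    PatternParams,
    TimeBlockParams,
    TrendParams,
    annotate,
    assess_adherence,
    detect_hyper_after_hypo,
    detect_hyper_trend,
    detect_hypo_after_hyper,
    detect_hypo_time_block,
    detect_hypo_trend,
    detect_missed_bolus_hyper,
    detect_very_high_trend,
    detect_very_low_trend,
    run_all_patterns,
)

from conftest import R, random_log

T = GlycemicThresholds()
SCHEME = TimeBlockScheme.default()
W = AnalysisWindow(date(2024, 1, 1), date(2024, 1, 14))


def ann(readings, window=W):
    return annotate(readings, window, T, SCHEME, time(0, 0))


def hyper_pair(day: int, n: int = 2):
    """n hyperglycemic readings on 2024-01-<day>."""
    return [R(f"2024-01-{day:02d}T{8 + 2 * i:02d}:00", 200) for i in range(n)]


def hypo_on(day: int, hour: int = 8, value: float = 62):
    return R(f"2024-01-{day:02d}T{hour:02d}:00", value)


class TestHyperTrend:
    P = TrendParams(count=2, consecutive_days=3)

    def test_default_trigger_red(self):
        rs = hyper_pair(3) + hyper_pair(4) + hyper_pair(5)
        f = detect_hyper_trend(ann(rs), W, self.P)
        assert f.status == "red"
        assert len(f.evidence) == 6

    def test_two_days_only_clear(self):
        rs = hyper_pair(3) + hyper_pair(4)
        assert detect_hyper_trend(ann(rs), W, self.P).status == "clear"

    def test_single_heavy_day_clear(self):
        rs = hyper_pair(3, n=5)
        assert detect_hyper_trend(ann(rs), W, self.P).status == "clear"

    def test_gap_day_breaks_run(self):
        rs = hyper_pair(3) + hyper_pair(5) + hyper_pair(6)
        assert detect_hyper_trend(ann(rs), W, self.P).status == "clear"

    def test_very_high_counts_as_hyper(self):
        rs = []
        for d in (3, 4, 5):
            rs += [hypo_on(d, 8, 300), hypo_on(d, 12, 300)]
        assert detect_hyper_trend(ann(rs), W, self.P).status == "red"

    def test_earliest_run_reported(self):
        rs = hyper_pair(2) + hyper_pair(3) + hyper_pair(4) + hyper_pair(9) + hyper_pair(10) + hyper_pair(11)
        f = detect_hyper_trend(ann(rs), W, self.P)
        assert f.status == "red"
        assert all(e.day <= "2024-01-04" for e in f.evidence)


class TestHypoTrend:
    P = TrendParams(count=1, consecutive_days=2)

    def test_default_trigger_red(self):
        f = detect_hypo_trend(ann([hypo_on(3), hypo_on(4)]), W, self.P)
        assert f.status == "red"

    def test_nonconsecutive_clear(self):
        assert detect_hypo_trend(ann([hypo_on(3), hypo_on(5)]), W, self.P).status == "clear"

    def test_three_hypos_one_day_clear(self):
        rs = [hypo_on(3, h) for h in (7, 12, 20)]
        assert detect_hypo_trend(ann(rs), W, self.P).status == "clear"

    def test_very_low_counts_as_hypo(self):
        # class containment: a very-low reading is also a hypoglycemic event
        f = detect_hypo_trend(ann([hypo_on(3, 8, 50), hypo_on(4, 8, 62)]), W, self.P)
        assert f.status == "red"


class TestVeryHighTrend:
    def test_one_reading_above_250_red(self):
        f = detect_very_high_trend(ann([R("2024-01-05T12:00", 260)]), W, LevelParams(1, 250))
        assert f.status == "red"

    def test_all_at_or_below_250_clear(self):
        rs = [R("2024-01-05T12:00", 250), R("2024-01-06T12:00", 240)]
        assert detect_very_high_trend(ann(rs), W, LevelParams(1, 250)).status == "clear"

    def test_raised_level_misses_260(self):
        f = detect_very_high_trend(ann([R("2024-01-05T12:00", 260)]), W, LevelParams(1, 300))
        assert f.status == "clear"


class TestVeryLowTrend:
    def test_one_reading_below_54_red(self):
        f = detect_very_low_trend(ann([R("2024-01-05T03:00", 50)]), W, LevelParams(1, 54))
        assert f.status == "red"

    def test_exactly_54_clear(self):
        f = detect_very_low_trend(ann([R("2024-01-05T03:00", 54)]), W, LevelParams(1, 54))
        assert f.status == "clear"

    def test_raised_level_and_count(self):
        rs = [R("2024-01-05T03:00", 70), R("2024-01-08T03:00", 70)]
        f = detect_very_low_trend(ann(rs), W, LevelParams(3, 80))
        assert f.status == "clear"  # two qualifying readings < required three


class TestHypoTimeBlock:
    P = TimeBlockParams(events_in_block=2, days=7)

    def test_same_block_5_days_apart_red(self):
        rs = [hypo_on(3, 2), hypo_on(8, 3)]  # both in the night block
        f = detect_hypo_time_block(ann(rs), W, SCHEME, self.P)
        assert f.status == "red"
        assert f.extra["block"] == "night"

    def test_different_blocks_same_day_clear(self):
        rs = [hypo_on(3, 2), hypo_on(3, 12)]
        assert detect_hypo_time_block(ann(rs), W, SCHEME, self.P).status == "clear"

    def test_same_block_8_days_apart_clear(self):
        rs = [hypo_on(3, 2), hypo_on(11, 3)]
        assert detect_hypo_time_block(ann(rs), W, SCHEME, self.P).status == "clear"

    def test_window_boundary_7_days_inclusive(self):
        rs = [hypo_on(3, 2), hypo_on(9, 3)]  # days 3..9 span exactly 7 days
        assert detect_hypo_time_block(ann(rs), W, SCHEME, self.P).status == "red"


class TestPairDetectors:
    P = PairingParams(enabled=True, pattern_count=1, pairing_window_hours=5)

    def test_hypo_after_hyper_pair(self):
        rs = [R("2024-01-05T12:00", 280), R("2024-01-05T15:00", 60)]
        f = detect_hypo_after_hyper(ann(rs), W, self.P)
        assert f.status == "red"
        assert f.extra["n_pairs"] == 1

    def test_ordering_matters(self):
        rs = [R("2024-01-05T12:00", 60), R("2024-01-05T15:00", 280)]
        assert detect_hypo_after_hyper(ann(rs), W, self.P).status == "clear"

    def test_in_range_reading_interrupts(self):
        rs = [
            R("2024-01-05T12:00", 280),
            R("2024-01-05T13:30", 110),
            R("2024-01-05T15:00", 60),
        ]
        assert detect_hypo_after_hyper(ann(rs), W, self.P).status == "clear"

    def test_outside_window_hours_clear(self):
        rs = [R("2024-01-05T08:00", 280), R("2024-01-05T14:30", 60)]
        assert detect_hypo_after_hyper(ann(rs), W, self.P).status == "clear"

    def test_hyper_after_hypo_mirror(self):
        rs = [R("2024-01-05T12:00", 60), R("2024-01-05T15:00", 280)]
        assert detect_hyper_after_hypo(ann(rs), W, self.P).status == "red"
        rs_swapped = [R("2024-01-05T12:00", 280), R("2024-01-05T15:00", 60)]
        assert detect_hyper_after_hypo(ann(rs_swapped), W, self.P).status == "clear"


class TestMissedBolus:
    P = PairingParams(enabled=True, pattern_count=1)

    def test_missed_bolus_counts(self):
        rs = [
            R("2024-01-05T12:00", 110, "pre_lunch", bolus=False),
            R("2024-01-05T14:00", 240, "post_lunch"),
        ]
        assert detect_missed_bolus_hyper(ann(rs), W, self.P).status == "red"

    def test_bolus_given_does_not_count(self):
        rs = [
            R("2024-01-05T12:00", 110, "pre_lunch", bolus=True),
            R("2024-01-05T14:00", 240, "post_lunch"),
        ]
        assert detect_missed_bolus_hyper(ann(rs), W, self.P).status == "clear"

    def test_no_annotations_inactive(self):
        rs = [
            R("2024-01-05T12:00", 110, "pre_lunch"),
            R("2024-01-05T14:00", 240, "post_lunch"),
        ]
        assert detect_missed_bolus_hyper(ann(rs), W, self.P).status == "inactive"


class TestAdherence:
    def test_full_adherence(self):
        rs = [R(f"2024-01-{d:02d}T{6 + i:02d}:00", 100) for d in range(1, 15) for i in range(4)]
        frac, f = assess_adherence(ann(rs), W, AdherenceParams(4, 0.7))
        assert frac == 1.0
        assert f.status == "clear"

    def test_half_adherence(self):
        rs = [R(f"2024-01-{d:02d}T{6 + i:02d}:00", 100) for d in range(1, 15) for i in range(2)]
        frac, f = assess_adherence(ann(rs), W, AdherenceParams(4, 0.7))
        assert frac == pytest.approx(0.5)
        assert f.status == "red"

    def test_zero_tests(self):
        frac, f = assess_adherence(ann([]), W, AdherenceParams(4, 0.7))
        assert frac == 0.0
        assert f.status == "red"


class TestParamClamping:
    def test_out_of_range_values_clamp(self):
        p = PatternParams(
            hyper_trend=TrendParams(count=9, consecutive_days=0),
            very_high_trend=LevelParams(tests=50, level=500),
            very_low_trend=LevelParams(tests=0, level=10),
            hypo_time_block=TimeBlockParams(events_in_block=1, days=99),
        ).clamped()
        assert p.hyper_trend == TrendParams(5, 1)
        assert p.very_high_trend == LevelParams(10, 300)
        assert p.very_low_trend == LevelParams(1, 50)
        assert p.hypo_time_block == TimeBlockParams(2, 10)

    def test_defaults_are_fixed_points(self):
        assert PatternParams().clamped() == PatternParams()


class TestRunAll:
    def test_one_finding_per_detector_deterministic_order(self, default_config):
        cfg = default_config
        rs = hyper_pair(3) + [hypo_on(5)]
        findings = run_all_patterns(rs, W, cfg.thresholds, cfg.scheme, cfg.patterns)
        names = [f.detector for f in findings]
        assert names == [
            "hypo_trend", "hypo_time_block", "very_low_trend",
            "hyper_trend", "hyper_time_block", "very_high_trend", "adherence",
        ]

    def test_heuristics_included_when_enabled(self, default_config):
        cfg = default_config
        params = replace(
            cfg.patterns,
            hypo_after_hyper=PairingParams(enabled=True),
            hyper_after_hypo=PairingParams(enabled=True),
            missed_bolus=PairingParams(enabled=True),
        )
        findings = run_all_patterns([], W, cfg.thresholds, cfg.scheme, params)
        names = {f.detector for f in findings}
        assert {"hypo_after_hyper", "hyper_after_hypo", "missed_bolus_hyper"} <= names

    def test_inactive_when_gate_failed(self, default_config):
        cfg = default_config
        rs = hyper_pair(3) + hyper_pair(4) + hyper_pair(5)
        findings = run_all_patterns(
            rs, W, cfg.thresholds, cfg.scheme, cfg.patterns, active=False
        )
        assert all(f.status == "inactive" for f in findings)
        assert all(f.evidence == () for f in findings)

    def test_red_findings_carry_evidence(self, default_config):
        cfg = default_config
        rs = hyper_pair(3) + hyper_pair(4) + hyper_pair(5)
        findings = run_all_patterns(rs, W, cfg.thresholds, cfg.scheme, cfg.patterns)
        for f in findings:
            if f.detector == "adherence":
                continue  # count-based, no per-reading evidence
            if f.status == "red":
                assert f.evidence


def enabled_config() -> AnalysisConfig:
    cfg = AnalysisConfig.default()
    return replace(
        cfg,
        patterns=replace(
            cfg.patterns,
            hypo_after_hyper=PairingParams(enabled=True),
            hyper_after_hypo=PairingParams(enabled=True),
            missed_bolus=PairingParams(enabled=True),
        ),
    )


class TestOracleEquivalence:
    def test_detectors_match_bruteforce_on_random_logs(self):
        cfg = enabled_config()
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(0, 201))
            rs = random_log(rng, n, W, with_bolus=bool(rng.random() < 0.5))
            expected = oracle_statuses(rs, W, cfg)
            findings = run_all_patterns(rs, W, cfg.thresholds, cfg.scheme, cfg.patterns)
            got = {f.detector: f for f in findings}
            for det, exp in expected.items():
                status = got[det].status
                if exp is None:
                    assert status == "inactive", det
                else:
                    assert (status == "red") == exp, det


class TestParameterMonotonicity:
    def test_raising_counts_never_turns_clear_red(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            rs = random_log(rng, int(rng.integers(20, 150)), W)
            a = ann(rs)
            for days in range(1, 6):
                lo = detect_hyper_trend(a, W, TrendParams(2, days))
                hi = detect_hyper_trend(a, W, TrendParams(2, days + 1))
                if hi.status == "red":
                    assert lo.status == "red"
            for count in range(1, 5):
                lo = detect_very_low_trend(a, W, LevelParams(count, 54))
                hi = detect_very_low_trend(a, W, LevelParams(count + 1, 54))
                if hi.status == "red":
                    assert lo.status == "red"
            for events in range(2, 6):
                lo = detect_hypo_time_block(a, W, SCHEME, TimeBlockParams(events, 7))
                hi = detect_hypo_time_block(a, W, SCHEME, TimeBlockParams(events + 1, 7))
                if hi.status == "red":
                    assert lo.status == "red"
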