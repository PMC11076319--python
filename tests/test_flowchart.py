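from __future__ import annotations

import json
from dataclasses import replace
from datetime import date, datetime, time, timedelta

import numpy as np
import pytest

from smbgpattern.config import AnalysisConfig
from smbgpattern.core import AnalysisWindow, GlucoseReading, Tag
from smbgpattern.flowchart import (
    CONSIDER_DEINTENSIFY_TREATMENT,
    CONSIDER_INTENSIFY_TREATMENT,
    FLAG_PRIORITY,
    INTENSIFY_SMBG_BEFORE_CHANGE,
    INVESTIGATE_LOW_ADHERENCE,
    PLAN_EDUCATION_SESSION,
    REVIEW_CORRECTION_RULES,
    REVIEW_ISF_CARB_RATIO,
    REVIEW_SINGLE_EVENTS,
    TREATMENT_CHANGE_FLAGS,
    compare_periods,
    run_flowchart,
)
from smbgpattern.patterns import PairingParams
from smbgpattern.synthetic import Injection, SimulationSpec, simulate_log
from smbgpattern.variability import CvCutpoints, UndefinedVariabilityError

from conftest import random_log


def active_log(seed=1, injections=(), **kw) -> tuple:
    spec = SimulationSpec(seed=seed, n_days=28, injections=tuple(injections), **kw)
    log = simulate_log(spec)
    return log.readings, log.window


class TestStep1Branch:
    def test_insufficient_data_actions(self, default_config, window_28d):
        # 10 readings over 4 weeks: everything inactive, step-1 actions fire
        rs = [
            GlucoseReading(datetime(2024, 1, 1 + 2 * i, 8, 0), 100.0, Tag.OTHER)
            for i in range(10)
        ]
        rep = run_flowchart(rs, window_28d, default_config)
        assert rep.sufficiency.pattern_analysis_active is False
        assert all(f.status == "inactive" for f in rep.patterns)
        codes = {a.code for a in rep.actions}
        assert {INVESTIGATE_LOW_ADHERENCE, PLAN_EDUCATION_SESSION, REVIEW_SINGLE_EVENTS} <= codes
        assert not codes & TREATMENT_CHANGE_FLAGS


class TestStep3Mapping:
    def test_red_hypo_low_cv_deintensify(self, default_config):
        rs, w = active_log(seed=3, injections=[Injection("hypo_trend", 10)])
        rep = run_flowchart(rs, w, default_config)
        assert rep.variability.cv_class != "high"
        codes = {a.code for a in rep.actions}
        assert CONSIDER_DEINTENSIFY_TREATMENT in codes
        assert REVIEW_CORRECTION_RULES in codes

    def test_red_hyper_low_cv_intensify(self, default_config):
        rs, w = active_log(seed=4, injections=[Injection("hyper_trend", 10)])
        rep = run_flowchart(rs, w, default_config)
        assert rep.variability.cv_class != "high"
        assert CONSIDER_INTENSIFY_TREATMENT in {a.code for a in rep.actions}

    def test_red_hyper_high_cv_suppressed(self, default_config):
        # unclamped noisy baseline pushes CV above 36%
        rs, w = active_log(
            seed=5,
            injections=[Injection("hyper_trend", 10)],
            clamp_in_range=False,
            interday_cv_percent=45.0,
        )
        rep = run_flowchart(rs, w, default_config)
        assert rep.variability.cv_class == "high"
        codes = {a.code for a in rep.actions}
        assert INTENSIFY_SMBG_BEFORE_CHANGE in codes
        assert not codes & TREATMENT_CHANGE_FLAGS

    def test_missed_bolus_maps_to_isf_flag(self):
        cfg = AnalysisConfig.default()
        cfg = replace(
            cfg, patterns=replace(cfg.patterns, missed_bolus=PairingParams(enabled=True))
        )
        rs, w = active_log(seed=6, injections=[Injection("missed_bolus_hyper", 10)])
        rep = run_flowchart(rs, w, cfg)
        assert REVIEW_ISF_CARB_RATIO in {a.code for a in rep.actions}

    def test_flag_soundness_and_priority_order(self, default_config):
        rs, w = active_log(
            seed=7,
            injections=[Injection("hypo_trend", 5), Injection("hyper_trend", 15)],
        )
        rep = run_flowchart(rs, w, default_config)
        finding_ids = {f.detector for f in rep.patterns} | {"sufficiency", "cv_gate"}
        for a in rep.actions:
            assert a.triggered_by
            assert set(a.triggered_by) <= finding_ids
        order = [FLAG_PRIORITY.index(a.code) for a in rep.actions]
        assert order == sorted(order)


class TestDeterminism:
    def test_byte_identical_reports(self, default_config):
        rs, w = active_log(seed=8, injections=[Injection("very_low_trend", 3)])
        j1 = run_flowchart(rs, w, default_config).to_json()
        j2 = run_flowchart(list(reversed(rs)), w, default_config).to_json()
        assert j1 == j2


class TestComparePeriods:
    W_A = AnalysisWindow(date(2024, 1, 1), date(2024, 1, 14))
    W_B = AnalysisWindow(date(2024, 1, 15), date(2024, 1, 28))

    def _two_period_log(self, inject_b=False):
        rs_a = simulate_log(SimulationSpec(seed=11, n_days=14)).readings
        inj = (Injection("hypo_trend", 3),) if inject_b else ()
        spec_b = SimulationSpec(seed=11, n_days=14, start=date(2024, 1, 15), injections=inj)
        return rs_a + simulate_log(spec_b).readings

    def test_identical_data_zero_deltas(self, default_config):
        rs = self._two_period_log()
        out = compare_periods(rs, self.W_A, self.W_B, default_config)
        for v in out["deltas"].values():
            assert v == pytest.approx(0.0, abs=1e-6)
        assert out["pattern_transitions"] == {}

    def test_injected_pattern_transition(self, default_config):
        rs = self._two_period_log(inject_b=True)
        out = compare_periods(rs, self.W_A, self.W_B, default_config)
        assert out["pattern_transitions"]["hypo_trend"] == "clear->red"

    def test_overlapping_windows_error(self, default_config):
        w_b = AnalysisWindow(date(2024, 1, 10), date(2024, 1, 20))
        with pytest.raises(ValueError, match="disjoint"):
            compare_periods([], self.W_A, w_b, default_config)

    def test_empty_window_b_error(self, default_config):
        rs = simulate_log(SimulationSpec(seed=12, n_days=14)).readings
        with pytest.raises(UndefinedVariabilityError, match="window B"):
            compare_periods(rs, self.W_A, self.W_B, default_config)


class TestSuppressionProperty:
    def test_never_both_gate_and_treatment_flags(self):
        rng = np.random.default_rng(100)
        for i in range(40):
            w = AnalysisWindow(date(2024, 1, 1), date(2024, 1, int(rng.integers(7, 29))))
            rs = random_log(rng, int(rng.integers(0, 180)), w)
            cfg = AnalysisConfig.default()
            cfg = replace(
                cfg,
                cv_cutpoints=CvCutpoints(
                    low_upper=float(rng.uniform(10, 33)),
                    acceptable_upper=float(rng.uniform(33, 60)),
                ),
            )
            rep = run_flowchart(rs, w, cfg)
            codes = {a.code for a in rep.actions}
            if INTENSIFY_SMBG_BEFORE_CHANGE in codes:
                assert not codes & TREATMENT_CHANGE_FLAGS
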