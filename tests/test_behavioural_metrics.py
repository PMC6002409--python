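"""Condition summaries, integration-method SSRT, and exclusion filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiostop.behavioural_metrics import (ConditionSummary, apply_exclusions,
                                            condition_summaries,
                                            ssrt_integration, summarize_session)
from cardiostop.task_engine import TrialRecord, TrialSpec

from conftest import build_exclusion_fixture


def _stop(idx, phase, ssd, responded):
    spec = TrialSpec(index=idx, trial_type=f"stop-{phase}", block=1)
    return TrialRecord(spec=spec, ssd_used=ssd,
                       go_rt=500.0 if responded else None,
                       responded=responded, stop_success=not responded)


def _go(idx, trial_type, rt):
    spec = TrialSpec(index=idx, trial_type=trial_type, block=1)
    return TrialRecord(spec=spec, ssd_used=None, go_rt=rt,
                       responded=rt is not None, stop_success=None)


class TestConditionSummaries:
    def test_p_respond_counts(self):
        recs = [_stop(i, "systole", 200.0, responded=(i % 2 == 0))
                for i in range(4)]
        s = condition_summaries(recs, "p")
        assert s.p_respond_systole == 0.5
        assert math.isnan(s.p_respond_diastole)

    def test_mean_ssd(self):
        recs = [_stop(i, "diastole", ssd, True)
                for i, ssd in enumerate([200.0, 250.0, 200.0, 150.0])]
        assert condition_summaries(recs).mean_ssd_diastole == 200.0

    def test_go_only_session_no_crash(self):
        recs = [_go(i, "go-systole", 450.0) for i in range(5)]
        s = condition_summaries(recs, "p")
        assert s.go_rt_systole == 450.0
        assert math.isnan(s.mean_ssd_systole)
        assert "no stop-systole trials" in s.notes

    def test_go_rt_excludes_control_trials(self):
        recs = [_go(1, "go-systole", 400.0), _go(2, "go-control-s", 800.0)]
        assert condition_summaries(recs).go_rt_systole == 400.0


class TestSSRTIntegration:
    def test_hand_ranked_toy_set(self):
        # rank = ceil(5 * 0.4) = 2 -> RT 450; SSRT = 450 - 200
        assert ssrt_integration([400, 450, 500, 550, 600], 0, 0.4, 200.0) == 250.0

    def test_p_respond_one_boundary(self):
        assert ssrt_integration([400, 500], 0, 1.0, 100.0) == 400.0

    def test_omissions_enter_at_maximum(self):
        # pooled {500, 600, 700, 1000}; rank = ceil(4 * 0.75) = 3 -> 700
        assert ssrt_integration([500, 600, 700], 1, 0.75, 150.0) == 550.0

    def test_p_respond_zero_undefined(self):
        assert math.isnan(ssrt_integration([400, 500], 0, 0.0, 100.0))

    def test_empty_go_rts_rejected(self):
        with pytest.raises(ValueError):
            ssrt_integration([], 0, 0.5, 100.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        """Independently recoded sort-index-subtract oracle."""
        rts = data.draw(st.lists(st.floats(100, 999), min_size=1, max_size=40))
        omissions = data.draw(st.integers(0, 5))
        p = data.draw(st.floats(0.01, 1.0))
        ssd = data.draw(st.floats(0, 500))

        pooled = sorted(list(rts) + [1000.0] * omissions)
        n = len(pooled)
        k = math.ceil(n * p)
        k = 1 if k < 1 else (n if k > n else k)
        expected = pooled[k - 1] - ssd

        assert ssrt_integration(rts, omissions, p, ssd) == pytest.approx(expected)


class TestSummarizeSession:
    def _session(self):
        recs = [_go(i, "go-systole", 400.0 + 10 * i) for i in range(5)]
        recs += [_go(10 + i, "go-control-s", 600.0) for i in range(2)]
        recs += [_stop(20 + i, "systole", 200.0, responded=(i < 2))
                 for i in range(4)]
        return recs

    def test_ssrt_uses_pooled_go_distribution(self):
        s = summarize_session(self._session(), "p", ssrt_go_pool="all")
        # pooled go RTs {400,410,420,430,440,600,600}, p=0.5, rank ceil(3.5)=4
        assert s.ssrt_systole == 430.0 - 200.0

    def test_per_phase_pool_option(self):
        s = summarize_session(self._session(), "p", ssrt_go_pool="per-phase")
        assert s.ssrt_systole == 430.0 - 200.0  # same trials here
        with pytest.raises(ValueError):
            summarize_session(self._session(), "p", ssrt_go_pool="bogus")


class TestApplyExclusions:
    def test_identical_participants_retained(self):
        base = dict(go_rt_systole=470.0, go_rt_diastole=474.0,
                    p_respond_systole=0.5, p_respond_diastole=0.5,
                    mean_ssd_systole=240.0, mean_ssd_diastole=230.0)
        summaries = [ConditionSummary(participant_id=f"p{i}", **base)
                     for i in range(10)]
        res = apply_exclusions(summaries)
        assert len(res.retained) == 10 and not res.excluded

    def test_single_waiter_excluded(self):
        rng = np.random.default_rng(0)
        summaries = []
        for i in range(19):
            summaries.append(ConditionSummary(
                participant_id=f"p{i}",
                go_rt_systole=float(rng.normal(470, 15)),
                go_rt_diastole=474.0,
                p_respond_systole=0.5, p_respond_diastole=0.5,
                mean_ssd_systole=240.0, mean_ssd_diastole=230.0))
        summaries.append(ConditionSummary(
            participant_id="waiter", go_rt_systole=470.0 + 5 * 15,
            go_rt_diastole=474.0, p_respond_systole=0.5,
            p_respond_diastole=0.5, mean_ssd_systole=240.0,
            mean_ssd_diastole=230.0))
        res = apply_exclusions(summaries)
        assert set(res.excluded) == {"waiter"}
        assert res.excluded["waiter"].startswith("waiting")

    def test_nonconverger_excluded_in_pass_two(self):
        rng = np.random.default_rng(1)
        summaries = []
        for i in range(19):
            summaries.append(ConditionSummary(
                participant_id=f"p{i}", go_rt_systole=470.0, go_rt_diastole=474.0,
                p_respond_systole=float(rng.normal(0.5, 0.03)),
                p_respond_diastole=0.5,
                mean_ssd_systole=240.0, mean_ssd_diastole=230.0))
        summaries.append(ConditionSummary(
            participant_id="nonc", go_rt_systole=470.0, go_rt_diastole=474.0,
            p_respond_systole=0.10, p_respond_diastole=0.5,
            mean_ssd_systole=240.0, mean_ssd_diastole=230.0))
        res = apply_exclusions(summaries)
        assert set(res.excluded) == {"nonc"}
        assert res.excluded["nonc"].startswith("non-convergence")

    def test_pass_two_statistics_exclude_pass_one(self):
        """Waiters with extreme inhibition success must not inflate the
        pass-2 spread; the non-convergers are still caught."""
        summaries = build_exclusion_fixture()
        res = apply_exclusions(summaries)
        assert res.flow == {"entrants": 60, "after_pass1": 52,
                            "after_pass2": 46, "retained": 46}
        assert all(pid.startswith(("waitRT", "waitSSD"))
                   for pid, r in res.excluded.items() if r.startswith("waiting"))
        assert all(pid.startswith("nonc")
                   for pid, r in res.excluded.items()
                   if r.startswith("non-convergence"))

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            apply_exclusions([ConditionSummary(participant_id="a"),
                              ConditionSummary(participant_id="b")])
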