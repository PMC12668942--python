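"""Trace scoring: traceability, latency, per-marker statistics, inference."""

import numpy as np
import pytest

from cogtrace import (
    EventType,
    FaultKind,
    WARNING_EVENTS,
    anticipation_latency,
    bootstrap_ci,
    compare_conditions,
    marker_stats,
    traceability_score,
)
from cogtrace.emitter import SymbolicMarker, SymbolicTrace
from cogtrace.features import ContractError
from cogtrace.metrics import (
    InsufficientDataError,
    holm_correction,
    is_interpretable,
    marker_correct,
)
from cogtrace.simulate import CognitiveState, GroundTruth, StateInterval


def marker(etype, t, detail=None):
    return SymbolicMarker("label", "x", t, etype, detail or {})


def truth_with_drift(onset=10.0, drift_end=14.0, error=13.0, duration=60.0):
    return GroundTruth(
        fault_kind=FaultKind.GRADUAL_DRIFT,
        fault_onset=onset,
        error_onset=error,
        state_timeline=[
            StateInterval(0.0, onset, CognitiveState.STABLE),
            StateInterval(onset, drift_end, CognitiveState.DRIFT),
            StateInterval(drift_end, duration, CognitiveState.STABLE),
        ],
        true_intent="left",
    )


class TestTraceability:
    def test_hand_counted_nine_of_ten(self):
        truth = truth_with_drift()
        markers = [marker(EventType.SIGMA1, 2.0)]
        markers += [marker(EventType.DRIFT, 10.5 + 0.3 * i) for i in range(8)]
        markers += [marker(EventType.DRIFT, 40.0)]  # far outside the drift span
        trace = SymbolicTrace("t", sorted(markers, key=lambda m: m.timestamp))
        assert traceability_score(trace, truth, tolerance=1.0) == pytest.approx(0.9)

    def test_all_consistent_scores_one(self):
        truth = truth_with_drift()
        trace = SymbolicTrace("t", [marker(EventType.DRIFT, 11.0)])
        assert traceability_score(trace, truth) == 1.0

    def test_empty_trace_scores_one_by_convention(self):
        assert traceability_score(SymbolicTrace("t", []), truth_with_drift()) == 1.0

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ContractError):
            traceability_score(SymbolicTrace("t", []), truth_with_drift(), -1.0)

    @pytest.mark.parametrize(
        "etype,t,expected",
        [
            (EventType.SIGMA1, 2.0, True),          # always interpretable
            (EventType.SIGMA1, 50.0, True),
            (EventType.DRIFT, 11.0, True),          # inside drift span
            (EventType.DRIFT, 14.8, True),          # within tolerance of edge
            (EventType.DRIFT, 30.0, False),
            (EventType.REJECT_H1, 11.0, True),      # post-fault interval
            (EventType.REJECT_H1, 5.0, False),      # pre-fault
            (EventType.ACCEPT_H1, 5.0, True),       # stable interval
        ],
    )
    def test_consistency_map(self, etype, t, expected):
        assert is_interpretable(marker(etype, t), truth_with_drift(), 1.0) is expected

    def test_reject_needs_a_fault(self):
        clean = GroundTruth(
            FaultKind.NONE, None, None,
            [StateInterval(0, 60, CognitiveState.STABLE)], "left",
        )
        assert not is_interpretable(marker(EventType.REJECT_H1, 5.0), clean)


class TestAnticipationLatency:
    def test_simple_subtraction(self):
        truth = truth_with_drift(error=5.3)
        trace = SymbolicTrace("t", [marker(EventType.DRIFT, 3.0)])
        assert anticipation_latency(trace, truth) == pytest.approx(2.3)

    def test_absent_without_error_onset(self):
        truth = truth_with_drift()
        truth.error_onset = None
        trace = SymbolicTrace("t", [marker(EventType.DRIFT, 3.0)])
        assert anticipation_latency(trace, truth) is None

    def test_absent_when_warnings_trail_error(self):
        truth = truth_with_drift(error=5.0)
        trace = SymbolicTrace("t", [marker(EventType.CONFLICT, 8.0)])
        assert anticipation_latency(trace, truth) is None

    def test_non_negative_across_study(self, small_study):
        for r in small_study.records:
            lat = anticipation_latency(r.trace, r.truth)
            assert lat is None or lat > 0


class TestMarkerStats:
    def test_sigma_intent_match_defines_correctness(self):
        truth = truth_with_drift()
        good = marker(EventType.SIGMA1, 2.0, {"intent": "left"})
        bad = marker(EventType.SIGMA1, 2.0, {"intent": "right"})
        assert marker_correct(good, truth)
        assert not marker_correct(bad, truth)

    def test_recount_matches_brute_force(self, small_study):
        """marker_stats equals an independent per-marker recount."""
        records = small_study.records[:20]
        traces = [r.trace for r in records]
        truths = [r.truth for r in records]
        stats = marker_stats(traces, truths, tolerance=1.0)

        for etype in EventType:
            n_markers = n_correct = n_fp = n_active = 0
            leads = []
            for trace, truth in zip(traces, truths):
                ms = [m for m in trace.markers if m.event_type == etype]
                n_markers += len(ms)
                n_active += bool(ms)
                for m in ms:
                    interp = is_interpretable(m, truth, 1.0)
                    if etype is EventType.SIGMA1:
                        correct = m.detail.get("intent") == truth.true_intent
                    elif etype in WARNING_EVENTS:
                        correct = interp and truth.error_onset is not None and (
                            m.timestamp < truth.error_onset
                        )
                    else:
                        correct = interp
                    n_correct += correct
                    if etype in WARNING_EVENTS:
                        if truth.fault_onset is None or not interp:
                            n_fp += 1
                        if correct:
                            leads.append(truth.error_onset - m.timestamp)
                    elif not interp:
                        n_fp += 1
            st = stats[etype]
            assert (st.n_markers, st.n_correct, st.n_false_positive) == (
                n_markers, n_correct, n_fp,
            )
            assert st.n_episodes_active == n_active
            assert sorted(st.lead_times) == sorted(leads)

    def test_rates_bounded(self, small_study):
        stats = marker_stats(
            [r.trace for r in small_study.records],
            [r.truth for r in small_study.records],
        )
        for st in stats.values():
            assert 0 <= st.activation_frequency <= 1
            assert 0 <= st.correct_prediction_rate <= 1
            assert 0 <= st.false_positive_rate <= 1

    def test_sigma_emitted_everywhere(self, small_study):
        stats = marker_stats(
            [r.trace for r in small_study.records],
            [r.truth for r in small_study.records],
        )
        assert stats[EventType.SIGMA1].activation_frequency == 1.0
        assert stats[EventType.SIGMA1].false_positive_rate == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            marker_stats([SymbolicTrace("a", [])], [])


class TestBootstrap:
    def test_constant_sample_zero_width(self):
        lo, hi = bootstrap_ci(np.full(30, 2.5), seed=0)
        assert lo == hi == 2.5

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(1).normal(size=50)
        assert bootstrap_ci(x, seed=7) == bootstrap_ci(x, seed=7)
        assert bootstrap_ci(x, seed=7) != bootstrap_ci(x, seed=8)

    def test_empty_sample_rejected(self):
        with pytest.raises(ContractError):
            bootstrap_ci([], seed=0)
        with pytest.raises(ContractError):
            bootstrap_ci([1.0, 2.0], level=1.5, seed=0)

    def test_nominal_coverage_of_95_percent_interval(self):
        """Monte-Carlo coverage of the percentile interval for a Normal mean."""
        rng = np.random.default_rng(42)
        covered = 0
        reps = 600
        for i in range(reps):
            x = rng.normal(0.0, 1.0, size=40)
            lo, hi = bootstrap_ci(x, np.mean, 0.95, n_resamples=600, seed=i)
            covered += lo <= 0.0 <= hi
        assert 0.90 <= covered / reps <= 0.985

    def test_interval_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        lo1, hi1 = bootstrap_ci(rng.normal(size=40), seed=0)
        lo2, hi2 = bootstrap_ci(rng.normal(size=2000), seed=0)
        assert (hi2 - lo2) < (hi1 - lo1)


class TestCompareConditions:
    def test_identical_paired_samples_zero_effect(self):
        x = np.arange(10.0)
        report = compare_conditions(x, x, paired=True)
        assert report.effect_size == 0.0
        assert report.p_value == 1.0

    def test_shifted_normal_pairs_unit_cohens_d(self):
        rng = np.random.default_rng(11)
        b = rng.normal(size=200)
        a = b + rng.normal(1.0, 1.0, size=200)
        report = compare_conditions(a, b, paired=True)
        assert report.test == "paired_t"
        assert report.effect_size == pytest.approx(1.0, abs=0.25)

    def test_skewed_samples_take_wilcoxon_branch(self):
        rng = np.random.default_rng(12)
        a = rng.exponential(1.0, size=60)
        b = a + rng.exponential(0.5, size=60)
        report = compare_conditions(a, b, paired=True)
        assert report.test == "wilcoxon"
        assert report.effect_size_name == "rank_biserial"
        assert -1 <= report.effect_size <= 1

    def test_unpaired_branches(self):
        rng = np.random.default_rng(13)
        report = compare_conditions(
            rng.normal(size=40), rng.normal(size=45), paired=False
        )
        assert report.test in ("independent_t", "mann_whitney")

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            compare_conditions([1.0, 2.0], [1.0, 2.0])


def test_holm_correction_is_conservative_and_monotone():
    raw = np.array([0.001, 0.02, 0.04, 0.5])
    adj = holm_correction(raw)
    assert np.all(adj >= raw)
    assert np.all(np.diff(adj) >= 0)
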