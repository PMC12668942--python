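"""Detection state machine: pseudocode precedence, lifecycle, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogtrace import (
    DiscriminatorParams,
    EventType,
    WARNING_EVENTS,
    detect_events,
    events_from_features,
    scenario,
    simulate_episode,
)
from cogtrace.config import EpisodeConfig, FaultKind, FaultSpec
from cogtrace.discriminator import CalibrationError
from cogtrace.features import ContractError

from conftest import make_features


def drift_conflict_oracle(features, threshold_drift, threshold_conflict):
    """Literal re-implementation of the published if/elif branching."""
    events = []
    for f in features:
        if f.divergence > threshold_drift:
            events.append("DriftEvent")
        elif f.conflict_ratio > threshold_conflict:
            events.append("ConflictEscalate")
    return events


feature_rows = st.lists(
    st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1, max_size=25
)


class TestPseudocodeEquivalence:
    @settings(max_examples=80, deadline=None)
    @given(feature_rows)
    def test_drift_conflict_emissions_equal_oracle(self, rows):
        params = DiscriminatorParams()
        features = make_features(rows)
        events = events_from_features(features, params)
        got = [
            e.type.value
            for e in events
            if e.type in (EventType.DRIFT, EventType.CONFLICT)
        ]
        assert got == drift_conflict_oracle(
            features, params.threshold_drift, params.threshold_conflict
        )

    @pytest.mark.parametrize(
        "div,cr,expected",
        [
            (0.40, 0.0, [EventType.DRIFT]),
            (0.20, 0.60, [EventType.CONFLICT]),
            (0.40, 0.60, [EventType.DRIFT]),  # strict elif precedence
            (0.20, 0.20, []),
        ],
    )
    def test_threshold_examples(self, div, cr, expected):
        features = make_features([(div, cr)], evidence={"left": 1.0, "right": 0.0})
        events = events_from_features(features, DiscriminatorParams())
        got = [e.type for e in events if e.type in (EventType.DRIFT, EventType.CONFLICT)]
        assert got == expected

    @settings(max_examples=40, deadline=None)
    @given(feature_rows, st.floats(0, 1), st.floats(0, 1))
    def test_raising_drift_threshold_never_adds_drift_events(self, rows, t1, t2):
        lo, hi = sorted([t1, t2])
        features = make_features(rows)
        n = {
            th: sum(
                e.type is EventType.DRIFT
                for e in events_from_features(
                    features, DiscriminatorParams(threshold_drift=th)
                )
            )
            for th in (lo, hi)
        }
        assert n[hi] <= n[lo]


class TestHypothesisLifecycle:
    def test_sigma1_at_first_confident_window(self):
        rows = [
            (0, 0, 0.4, {"left": 0.5, "right": 0.5}),   # conf 0.5: no commit
            (0, 0, 0.4, {"left": 0.9, "right": 0.1}),   # conf 0.9: commit
            (0, 0, 0.4, {"left": 0.9, "right": 0.1}),
        ]
        events = events_from_features(make_features(rows), DiscriminatorParams())
        sig = [e for e in events if e.type is EventType.SIGMA1]
        assert len(sig) == 1
        assert sig[0].timestamp == pytest.approx(4.0)
        assert sig[0].detail["intent"] == "left"

    def test_reject_on_entropy_spike_only_after_commit(self):
        rows = [
            (0, 0, 0.9, {"left": 0.5, "right": 0.5}),   # spike pre-commit: ignored
            (0, 0, 0.4, {"left": 0.9, "right": 0.1}),   # commit
            (0, 0, 0.7, {"left": 0.9, "right": 0.1}),   # spike: reject
            (0, 0, 0.7, {"left": 0.9, "right": 0.1}),   # rejected once only
        ]
        events = events_from_features(make_features(rows), DiscriminatorParams())
        rejects = [e for e in events if e.type is EventType.REJECT_H1]
        assert len(rejects) == 1
        assert rejects[0].timestamp == pytest.approx(6.0)

    def test_reject_on_leader_change(self):
        rows = [
            (0, 0, 0.4, {"left": 0.9, "right": 0.1}),
            (0, 0, 0.4, {"left": 0.1, "right": 0.9}),
        ]
        events = events_from_features(make_features(rows), DiscriminatorParams())
        assert any(e.type is EventType.REJECT_H1 for e in events)

    def test_accept_after_stable_streak_without_warnings(self):
        params = DiscriminatorParams(accept_windows=3)
        quiet = (0, 0, 0.4, {"left": 0.9, "right": 0.1})
        events = events_from_features(make_features([quiet] * 5), params)
        accepts = [e for e in events if e.type is EventType.ACCEPT_H1]
        assert len(accepts) == 1
        assert accepts[0].timestamp == pytest.approx(2.0 + 2 * 2.0)

    def test_warning_suppresses_accept(self):
        params = DiscriminatorParams(accept_windows=3)
        quiet = (0, 0, 0.4, {"left": 0.9, "right": 0.1})
        warn = (0.9, 0, 0.4, {"left": 0.9, "right": 0.1})
        events = events_from_features(make_features([quiet, warn] + [quiet] * 5), params)
        assert not any(e.type is EventType.ACCEPT_H1 for e in events)

    @settings(max_examples=40, deadline=None)
    @given(feature_rows)
    def test_stream_invariants(self, rows):
        events = events_from_features(make_features(rows), DiscriminatorParams())
        ts = [e.timestamp for e in events]
        assert ts == sorted(ts)
        assert sum(e.type is EventType.SIGMA1 for e in events) <= 1
        if any(e.type in (EventType.REJECT_H1, EventType.ACCEPT_H1) for e in events):
            first_sigma = next(
                e.timestamp for e in events if e.type is EventType.SIGMA1
            )
            for e in events:
                if e.type in (EventType.REJECT_H1, EventType.ACCEPT_H1):
                    assert e.timestamp >= first_sigma


class TestSignalPath:
    def test_short_signal_raises_calibration_error(self):
        with pytest.raises(CalibrationError):
            detect_events(np.zeros((2, 1000)), DiscriminatorParams())

    def test_empty_signal_rejected(self):
        with pytest.raises((ContractError, CalibrationError)):
            detect_events(np.zeros((1, 0)))

    def test_param_validation(self):
        with pytest.raises(ContractError):
            DiscriminatorParams(window_size=1)
        with pytest.raises(ContractError):
            DiscriminatorParams(step=0)
        with pytest.raises(ContractError):
            DiscriminatorParams(threshold_drift=1.5)
        with pytest.raises(ContractError):
            DiscriminatorParams(commit_confidence=0.0)

    def test_events_per_window_on_real_episode(self, motor_episode):
        events = detect_events(motor_episode.signal, sampling_rate=256)
        ts = [e.timestamp for e in events]
        assert ts == sorted(ts)
        # every window contributes at least its NoEvent placeholder
        assert len(events) >= 30
        assert any(e.type is EventType.SIGMA1 for e in events)

    def test_baseline_only_episode_has_no_warnings(self):
        ep = simulate_episode(scenario("motor_control", with_fault=False, seed=30))
        events = detect_events(ep.signal, sampling_rate=256)
        assert not any(e.type in WARNING_EVENTS for e in events)


class TestCalibrationGates:
    def test_false_positive_rate_on_fault_free_episodes(self):
        """Warning-class events occur in at most 5% of 200 clean episodes."""
        tasks = ["motor_control", "inhibition", "overload"]
        flagged = 0
        for i in range(200):
            ep = simulate_episode(
                scenario(tasks[i % 3], with_fault=False, seed=1000 + i)
            )
            events = detect_events(ep.signal, sampling_rate=ep.config.sampling_rate)
            flagged += any(e.type in WARNING_EVENTS for e in events)
        assert flagged <= 10

    def test_drift_detected_between_fault_and_error(self):
        """>=90% of default gradual-drift episodes warn before error onset."""
        hits = 0
        n = 50
        for seed in range(n):
            cfg = EpisodeConfig(fault=FaultSpec(kind=FaultKind.GRADUAL_DRIFT), seed=seed)
            ep = simulate_episode(cfg)
            events = detect_events(ep.signal, sampling_rate=256)
            horizon = ep.truth.error_onset or np.inf
            hits += any(
                e.type is EventType.DRIFT
                and ep.truth.fault_onset < e.timestamp < horizon
                for e in events
            )
        assert hits / n >= 0.9
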