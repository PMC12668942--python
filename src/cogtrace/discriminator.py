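"""Sliding-window event detection with a hypothesis lifecycle.

Per analysis window, in order: (1) before any commitment, a Sigma1 event is
emitted at the first window whose matched-filter confidence reaches the
commit threshold; (2) after commitment, RejectH1 fires once when spectral
entropy spikes above its cutoff or the leading hypothesis changes;
(3) divergence above ``threshold_drift`` emits DriftEvent, otherwise a
conflict ratio above ``threshold_conflict`` emits ConflictEscalate (strict
if/elif precedence); (4) AcceptH1 fires once if the committed hypothesis has
led for ``accept_windows`` consecutive windows with no warning so far.
Windows with no emission contribute NoEvent.  Event timestamps are the end
time of the window that produced them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .features import (
    DEFAULT_TEMPLATES,
    ContractError,
    FeatureVector,
    extract_features,
    sliding_windows,
    window_psd,
)


class EventType(str, enum.Enum):
    SIGMA1 = "Sigma1"
    DRIFT = "DriftEvent"
    CONFLICT = "ConflictEscalate"
    REJECT_H1 = "RejectH1"
    ACCEPT_H1 = "AcceptH1"
    NO_EVENT = "NoEvent"


#: event types that warn of an impending fault
WARNING_EVENTS = frozenset({EventType.DRIFT, EventType.CONFLICT, EventType.REJECT_H1})


class CalibrationError(ValueError):
    """Signal too short to establish the baseline spectral reference."""


@dataclass(frozen=True)
class DiscriminatorParams:
    """Detection thresholds and windowing of the Discriminator."""

    window_size: int = 512
    step: int = 512
    threshold_drift: float = 0.35
    threshold_conflict: float = 0.5
    commit_confidence: float = 0.75
    reject_entropy_spike: float = 0.6
    alpha_band: tuple[float, float] = (8.0, 12.0)
    baseline_windows: int = 3
    accept_windows: int = 7
    #: disabled detector branches (used by ablation studies)
    disabled: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ContractError(f"window_size must be >= 2, got {self.window_size}")
        if not 1 <= self.step <= self.window_size:
            raise ContractError(
                f"step must be in [1, window_size], got {self.step}"
            )
        for name in ("threshold_drift", "threshold_conflict", "reject_entropy_spike"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ContractError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.commit_confidence <= 1:
            raise ContractError(
                f"commit_confidence must be in (0, 1], got {self.commit_confidence}"
            )
        if self.baseline_windows < 1:
            raise ContractError(f"baseline_windows must be >= 1, got {self.baseline_windows}")


@dataclass(frozen=True)
class CognitiveEvent:
    type: EventType
    timestamp: float
    evidence: FeatureVector | None = field(default=None, compare=False)
    #: auxiliary detail, e.g. the committed intent class for Sigma1
    detail: dict = field(default_factory=dict, compare=False)


def events_from_features(
    features: list[FeatureVector], params: DiscriminatorParams, timestamps=None
) -> list[CognitiveEvent]:
    """Run the detection state machine over a precomputed feature sequence.

    This is the full branching logic of :func:`detect_events`, separated from
    signal processing so it can be exercised on arbitrary feature streams.
    ``timestamps`` gives the emission time per window (defaults to the
    feature's ``t_center``).
    """
    if timestamps is None:
        timestamps = [f.t_center for f in features]
    drift_on = "discriminator_drift" not in params.disabled
    conflict_on = "discriminator_conflict" not in params.disabled

    events: list[CognitiveEvent] = []
    committed: str | None = None
    rejected = False
    accepted = False
    warned = False
    lead_streak = 0

    for feat, ts in zip(features, timestamps):
        emitted = False
        leader = feat.leading_hypothesis
        if committed is None:
            if feat.confidence >= params.commit_confidence and leader:
                committed = leader
                events.append(
                    CognitiveEvent(EventType.SIGMA1, ts, feat, {"intent": committed})
                )
                emitted = True
                lead_streak = 1
        else:
            if not rejected and (
                feat.spectral_entropy > params.reject_entropy_spike
                or (leader is not None and leader != committed)
            ):
                rejected = True
                warned = True
                events.append(CognitiveEvent(EventType.REJECT_H1, ts, feat))
                emitted = True
            lead_streak = lead_streak + 1 if leader == committed else 0

        # drift/conflict follow the strict if/elif precedence on every window
        if drift_on and feat.divergence > params.threshold_drift:
            events.append(CognitiveEvent(EventType.DRIFT, ts, feat))
            warned = True
            emitted = True
        elif conflict_on and feat.conflict_ratio > params.threshold_conflict:
            events.append(CognitiveEvent(EventType.CONFLICT, ts, feat))
            warned = True
            emitted = True

        if (
            committed is not None
            and not accepted
            and not rejected
            and not warned
            and lead_streak >= params.accept_windows
        ):
            accepted = True
            events.append(CognitiveEvent(EventType.ACCEPT_H1, ts, feat))
            emitted = True
        if not emitted:
            events.append(CognitiveEvent(EventType.NO_EVENT, ts, feat))
    return events


def detect_events(
    signal: np.ndarray,
    params: DiscriminatorParams | None = None,
    *,
    sampling_rate: float = 256.0,
    templates=DEFAULT_TEMPLATES,
) -> list[CognitiveEvent]:
    """Detect cognitive events from a multichannel signal.

    The baseline spectral reference is the mean normalised PSD of the first
    ``baseline_windows`` windows (assumed pre-fault).
    """
    params = params or DiscriminatorParams()
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if signal.size == 0:
        raise ContractError("signal is empty")
    if signal.shape[1] < params.baseline_windows * params.window_size:
        raise CalibrationError(
            f"signal has {signal.shape[1]} samples; "
            f"{params.baseline_windows} x {params.window_size} needed for the baseline reference"
        )
    windows = list(
        sliding_windows(signal, params.window_size, params.step, sampling_rate)
    )
    # per-bin median across the calibration windows: robust to a fault onset
    # landing inside the last of them (early-onset tail of the scenarios)
    ref = np.median(
        [window_psd(w.data, sampling_rate)[1] for w in windows[: params.baseline_windows]],
        axis=0,
    )
    ref = ref / ref.sum()

    features = [
        extract_features(
            w, ref, alpha_band=params.alpha_band, templates=templates
        )
        for w in windows
    ]
    return events_from_features(features, params, timestamps=[w.t_end for w in windows])
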