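"""Trace evaluation: traceability, anticipation latency, per-marker
statistics, bootstrap intervals, and condition comparisons.

A marker is *semantically interpretable* when its timestamp falls (within a
tolerance) inside a ground-truth state interval consistent with its type:
DriftEvent with ``drift``, ConflictEscalate with ``conflict``/``overload``,
RejectH1 with ``reversal`` or any post-fault interval, AcceptH1 with
``stable``; Sigma1 is always temporally interpretable.  The Traceability
Score is the fraction of interpretable markers among all emissions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .discriminator import WARNING_EVENTS, EventType
from .emitter import SymbolicMarker, SymbolicTrace
from .features import ContractError
from .simulate import CognitiveState, GroundTruth

_CONSISTENT_STATES: dict[EventType, frozenset[CognitiveState]] = {
    EventType.DRIFT: frozenset({CognitiveState.DRIFT}),
    EventType.CONFLICT: frozenset({CognitiveState.CONFLICT, CognitiveState.OVERLOAD}),
    EventType.ACCEPT_H1: frozenset({CognitiveState.STABLE}),
    EventType.NO_EVENT: frozenset({CognitiveState.STABLE}),
}


def is_interpretable(
    marker: SymbolicMarker, truth: GroundTruth, tolerance: float = 1.0
) -> bool:
    """Type-consistent temporal overlap between a marker and the timeline."""
    if tolerance < 0:
        raise ContractError(f"tolerance must be >= 0, got {tolerance}")
    if marker.event_type is EventType.SIGMA1:
        return True
    t = marker.timestamp
    if marker.event_type is EventType.REJECT_H1:
        if truth.fault_onset is None:
            return False
        for iv in truth.state_timeline:
            post_fault = iv.t_start >= truth.fault_onset - 1e-9
            if (iv.state is CognitiveState.REVERSAL or post_fault) and (
                iv.t_start - tolerance <= t <= iv.t_end + tolerance
            ):
                return True
        return False
    allowed = _CONSISTENT_STATES.get(marker.event_type)
    if allowed is None:
        return False
    return any(
        iv.state in allowed and iv.t_start - tolerance <= t <= iv.t_end + tolerance
        for iv in truth.state_timeline
    )


def traceability_score(
    trace: SymbolicTrace, truth: GroundTruth, tolerance: float = 1.0
) -> float:
    """Interpretable markers / total markers; 1.0 for an empty trace."""
    if tolerance < 0:
        raise ContractError(f"tolerance must be >= 0, got {tolerance}")
    if not trace.markers:
        return 1.0
    n_ok = sum(is_interpretable(m, truth, tolerance) for m in trace.markers)
    return n_ok / len(trace.markers)


def anticipation_latency(trace: SymbolicTrace, truth: GroundTruth) -> float | None:
    """Error onset minus the first warning-class marker preceding it.

    ``None`` when there is no error onset or no qualifying marker.
    """
    if truth.error_onset is None:
        return None
    warnings = [
        m.timestamp
        for m in trace.markers
        if m.event_type in WARNING_EVENTS and m.timestamp < truth.error_onset
    ]
    if not warnings:
        return None
    return truth.error_onset - min(warnings)


@dataclass
class MarkerStats:
    """Per-marker-type activation, precision, and lead-time statistics."""

    n_episodes: int = 0
    n_episodes_active: int = 0
    n_markers: int = 0
    n_correct: int = 0
    n_false_positive: int = 0
    lead_times: list[float] = field(default_factory=list)

    @property
    def activation_frequency(self) -> float:
        return self.n_episodes_active / self.n_episodes if self.n_episodes else 0.0

    @property
    def correct_prediction_rate(self) -> float:
        return self.n_correct / self.n_markers if self.n_markers else 0.0

    @property
    def false_positive_rate(self) -> float:
        return self.n_false_positive / self.n_markers if self.n_markers else 0.0

    @property
    def mean_lead_time(self) -> float:
        return float(np.mean(self.lead_times)) if self.lead_times else float("nan")

    @property
    def sd_lead_time(self) -> float:
        return float(np.std(self.lead_times, ddof=1)) if len(self.lead_times) > 1 else float("nan")


def marker_correct(
    marker: SymbolicMarker, truth: GroundTruth, tolerance: float = 1.0
) -> bool:
    """Whether a marker counts as a correct prediction.

    Warning-class markers must be interpretable *and* precede error onset;
    Sigma1 must name the ground-truth intent class; others must be
    interpretable.
    """
    if marker.event_type is EventType.SIGMA1:
        committed = marker.detail.get("intent")
        return committed is not None and committed == truth.true_intent
    if not is_interpretable(marker, truth, tolerance):
        return False
    if marker.event_type in WARNING_EVENTS:
        return truth.error_onset is not None and marker.timestamp < truth.error_onset
    return True


def marker_stats(
    traces: list[SymbolicTrace],
    truths: list[GroundTruth],
    tolerance: float = 1.0,
) -> dict[EventType, MarkerStats]:
    """Aggregate per-marker-type statistics over index-aligned episodes.

    A warning-class marker is a false positive when it occurs in a fault-free
    episode or outside any type-consistent interval; for non-warning markers
    only the out-of-interval clause applies (Sigma1 is therefore structurally
    at 0% false positives).
    """
    if len(traces) != len(truths):
        raise ContractError(
            f"traces ({len(traces)}) and truths ({len(truths)}) must be index-aligned"
        )
    out: dict[EventType, MarkerStats] = {
        et: MarkerStats(n_episodes=len(traces)) for et in EventType
    }
    for trace, truth in zip(traces, truths):
        seen: set[EventType] = set()
        fault_free = truth.fault_onset is None
        for m in trace.markers:
            st = out[m.event_type]
            st.n_markers += 1
            seen.add(m.event_type)
            interpretable = is_interpretable(m, truth, tolerance)
            correct = marker_correct(m, truth, tolerance)
            if correct:
                st.n_correct += 1
            if m.event_type in WARNING_EVENTS:
                if fault_free or not interpretable:
                    st.n_false_positive += 1
                if correct:
                    st.lead_times.append(truth.error_onset - m.timestamp)
            elif not interpretable:
                st.n_false_positive += 1
        for et in seen:
            out[et].n_episodes_active += 1
    return out


@dataclass
class TraceMetrics:
    t_trace: float
    anticipation_latency_mean: float
    anticipation_latency_sd: float
    per_marker: dict[EventType, MarkerStats]
    n_episodes: int = 0
    n_latencies: int = 0


def evaluate_traces(
    traces: list[SymbolicTrace],
    truths: list[GroundTruth],
    tolerance: float = 1.0,
) -> TraceMetrics:
    """Score a collection of traces against their ground truths."""
    scores = [traceability_score(tr, gt, tolerance) for tr, gt in zip(traces, truths)]
    lats = [
        lat
        for tr, gt in zip(traces, truths)
        if (lat := anticipation_latency(tr, gt)) is not None
    ]
    return TraceMetrics(
        t_trace=float(np.mean(scores)) if scores else 1.0,
        anticipation_latency_mean=float(np.mean(lats)) if lats else float("nan"),
        anticipation_latency_sd=float(np.std(lats, ddof=1)) if len(lats) > 1 else float("nan"),
        per_marker=marker_stats(traces, truths, tolerance),
        n_episodes=len(traces),
        n_latencies=len(lats),
    )


def bootstrap_ci(
    values,
    statistic=np.mean,
    level: float = 0.95,
    n_resamples: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval; deterministic given ``seed``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ContractError("sample is empty")
    if not 0 < level < 1:
        raise ContractError(f"level must be in (0, 1), got {level}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    resamples = values[idx]
    try:
        boot = np.asarray(statistic(resamples, axis=1), dtype=float)
    except TypeError:
        boot = np.array([statistic(row) for row in resamples], dtype=float)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(boot, [alpha, 1 - alpha])
    return float(lo), float(hi)


@dataclass(frozen=True)
class ComparisonReport:
    test: str
    statistic: float
    p_value: float
    effect_size: float
    effect_size_name: str
    shapiro_p: tuple[float, float]


class InsufficientDataError(ValueError):
    pass


def compare_conditions(
    samples_a, samples_b, paired: bool = True, alpha: float = 0.05
) -> ComparisonReport:
    """Shapiro-Wilk gated comparison of two conditions.

    Both samples normal at ``alpha`` -> (paired) t-test with Cohen's d;
    otherwise Wilcoxon signed-rank (paired) or Mann-Whitney U with a
    rank-biserial effect size.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("need at least 3 observations per condition")
    if paired and a.size != b.size:
        raise ContractError("paired samples must be equal length")

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 1.0  # a constant sample carries no normality evidence
        return float(sstats.shapiro(x).pvalue)

    pa, pb = _shapiro_p(a), _shapiro_p(b)
    normal = pa > alpha and pb > alpha

    if paired:
        diff = a - b
        if np.all(diff == 0):
            return ComparisonReport("paired_t", 0.0, 1.0, 0.0, "cohen_d", (pa, pb))
        if normal:
            res = sstats.ttest_rel(a, b)
            d = float(np.mean(diff) / np.std(diff, ddof=1))
            return ComparisonReport(
                "paired_t", float(res.statistic), float(res.pvalue), d, "cohen_d", (pa, pb)
            )
        res = sstats.wilcoxon(a, b)
        nz = diff[diff != 0]
        ranks = sstats.rankdata(np.abs(nz))
        w_pos = ranks[nz > 0].sum()
        w_neg = ranks[nz < 0].sum()
        r = float((w_pos - w_neg) / (w_pos + w_neg))
        return ComparisonReport(
            "wilcoxon", float(res.statistic), float(res.pvalue), r, "rank_biserial", (pa, pb)
        )
    if normal:
        res = sstats.ttest_ind(a, b)
        pooled = np.sqrt(
            ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1))
            / (a.size + b.size - 2)
        )
        d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
        return ComparisonReport(
            "independent_t", float(res.statistic), float(res.pvalue), d, "cohen_d", (pa, pb)
        )
    res = sstats.mannwhitneyu(a, b)
    r = float(2 * res.statistic / (a.size * b.size) - 1)
    return ComparisonReport(
        "mann_whitney", float(res.statistic), float(res.pvalue), r, "rank_biserial", (pa, pb)
    )


def holm_correction(p_values) -> np.ndarray:
    """Holm-Bonferroni adjusted p-values for a family of comparisons."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]
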