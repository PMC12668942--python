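"""Simulation-study orchestration: batch generation, detection, emission,
evaluation, ablations, and the per-marker summary table.

A study simulates ``n_episodes_per_task`` episodes for each task paradigm
(fault-bearing with probability ``fault_rate``), runs the discriminator and
emitter (honouring ablation flags), and aggregates trace metrics overall,
per task, and per marker type over the task pools in which each marker is
meaningful (Sigma1 over all tasks, DriftEvent over motor/overload, RejectH1
and ConflictEscalate over inhibition/overload).  Everything is reproducible
from ``root_seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ConfigurationError, EpisodeConfig, TaskType, scenario
from .discriminator import DiscriminatorParams, EventType, detect_events
from .emitter import SymbolicTrace, emit
from .features import ContractError
from .metrics import (
    MarkerStats,
    TraceMetrics,
    anticipation_latency,
    evaluate_traces,
    marker_stats,
)
from .simulate import GroundTruth, simulate_episode

ALL_TASKS = (TaskType.MOTOR_CONTROL, TaskType.INHIBITION, TaskType.OVERLOAD)

#: task pools over which each marker's row of the summary table is computed
MARKER_TASK_POOLS: dict[EventType, tuple[TaskType, ...]] = {
    EventType.SIGMA1: ALL_TASKS,
    EventType.REJECT_H1: (TaskType.INHIBITION, TaskType.OVERLOAD),
    EventType.DRIFT: (TaskType.MOTOR_CONTROL, TaskType.OVERLOAD),
    EventType.CONFLICT: (TaskType.INHIBITION, TaskType.OVERLOAD),
}

_ABLATABLE = {"discriminator_drift", "discriminator_conflict", "emitter"}


@dataclass(frozen=True)
class StudyConfig:
    n_episodes_per_task: int = 300
    tasks: tuple[TaskType, ...] = ALL_TASKS
    fault_rate: float = 0.8
    discriminator: DiscriminatorParams = field(default_factory=DiscriminatorParams)
    ablation: frozenset = field(default_factory=frozenset)
    tolerance: float = 1.0
    root_seed: int = 0
    #: per-episode configuration overrides (noise_sd, behavior_lag_*, ...)
    episode_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tasks", tuple(TaskType(t) for t in self.tasks))
        object.__setattr__(self, "ablation", frozenset(self.ablation))
        if self.n_episodes_per_task < 1:
            raise ConfigurationError(
                f"n_episodes_per_task must be >= 1, got {self.n_episodes_per_task}"
            )
        if not self.tasks:
            raise ConfigurationError("task set must not be empty")
        if not 0 <= self.fault_rate <= 1:
            raise ConfigurationError(f"fault_rate must be in [0, 1], got {self.fault_rate}")
        unknown = self.ablation - _ABLATABLE
        if unknown:
            raise ConfigurationError(f"unknown ablation flags: {sorted(unknown)}")


@dataclass
class EpisodeRecord:
    task: TaskType
    index: int
    faulted: bool
    config: EpisodeConfig
    truth: GroundTruth
    trace: SymbolicTrace


@dataclass
class StudyReport:
    config: StudyConfig
    records: list[EpisodeRecord]
    overall: TraceMetrics
    per_task: dict[TaskType, TraceMetrics]
    marker_table: pd.DataFrame

    def pool_records(self, tasks) -> list[EpisodeRecord]:
        tasks = set(tasks)
        return [r for r in self.records if r.task in tasks]

    def statistics(self) -> dict[str, float]:
        """Flat summary statistics of the study (used by calibration)."""
        return study_statistics(self)

    def to_json(self, indent: int | None = None) -> str:
        """Canonical JSON rendering of the aggregate report."""
        payload = {
            "config": _config_payload(self.config),
            "n_episodes": len(self.records),
            "overall": _metrics_payload(self.overall),
            "per_task": {
                t.value: _metrics_payload(m) for t, m in self.per_task.items()
            },
            "marker_table": self.marker_table.to_dict(orient="records"),
            "statistics": self.statistics(),
        }
        return json.dumps(payload, indent=indent, sort_keys=True, allow_nan=True)


def _config_payload(config: StudyConfig) -> dict:
    d = asdict(config)
    d["tasks"] = [t.value for t in config.tasks]
    d["ablation"] = sorted(config.ablation)
    d["discriminator"]["disabled"] = sorted(config.discriminator.disabled)
    return d


def _metrics_payload(m: TraceMetrics) -> dict:
    return {
        "t_trace": m.t_trace,
        "anticipation_latency_mean": m.anticipation_latency_mean,
        "anticipation_latency_sd": m.anticipation_latency_sd,
        "n_episodes": m.n_episodes,
        "n_latencies": m.n_latencies,
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full simulation study described by ``config``."""
    root = np.random.SeedSequence(config.root_seed)
    task_seeds = root.spawn(len(config.tasks))
    det_params = replace(
        config.discriminator,
        disabled=frozenset(config.discriminator.disabled)
        | (config.ablation & {"discriminator_drift", "discriminator_conflict"}),
    )
    emitter_on = "emitter" not in config.ablation

    records: list[EpisodeRecord] = []
    for task, task_ss in zip(config.tasks, task_seeds):
        task_rng = np.random.default_rng(task_ss)
        ep_seeds = task_rng.integers(0, 2**31 - 1, size=config.n_episodes_per_task)
        fault_draws = task_rng.random(config.n_episodes_per_task) < config.fault_rate
        for i, (seed, faulted) in enumerate(zip(ep_seeds, fault_draws)):
            ep_config = scenario(
                task,
                with_fault=bool(faulted),
                seed=int(seed),
                **config.episode_overrides,
            )
            episode = simulate_episode(ep_config)
            events = detect_events(
                episode.signal, det_params, sampling_rate=ep_config.sampling_rate
            )
            episode_id = f"{task.value}-{i:04d}"
            if emitter_on:
                trace = emit(
                    events,
                    episode_id=episode_id,
                    config_fingerprint=ep_config.fingerprint(),
                )
            else:
                trace = SymbolicTrace(episode_id=episode_id, markers=[])
            records.append(
                EpisodeRecord(task, i, bool(faulted), ep_config, episode.truth, trace)
            )

    traces = [r.trace for r in records]
    truths = [r.truth for r in records]
    overall = evaluate_traces(traces, truths, config.tolerance)
    per_task = {
        task: evaluate_traces(
            [r.trace for r in records if r.task == task],
            [r.truth for r in records if r.task == task],
            config.tolerance,
        )
        for task in config.tasks
    }
    table = _marker_table(records, config)
    return StudyReport(config, records, overall, per_task, table)


def _pool_stats(
    records: list[EpisodeRecord], tasks, tolerance: float
) -> dict[EventType, MarkerStats]:
    pool = [r for r in records if r.task in set(tasks)]
    return marker_stats([r.trace for r in pool], [r.truth for r in pool], tolerance)


def _marker_table(records: list[EpisodeRecord], config: StudyConfig) -> pd.DataFrame:
    rows = []
    for et, pool in MARKER_TASK_POOLS.items():
        tasks = [t for t in pool if t in config.tasks]
        if not tasks:
            continue
        stats = _pool_stats(records, tasks, config.tolerance)[et]
        rows.append(
            {
                "marker": et.value,
                "task_pool": "+".join(t.value for t in tasks),
                "n_episodes": stats.n_episodes,
                "activation_frequency_pct": 100 * stats.activation_frequency,
                "correct_prediction_rate_pct": 100 * stats.correct_prediction_rate,
                "false_positive_rate_pct": 100 * stats.false_positive_rate,
                "mean_lead_time_s": stats.mean_lead_time,
                "sd_lead_time_s": stats.sd_lead_time,
                "n_markers": stats.n_markers,
            }
        )
    return pd.DataFrame(rows)


def study_statistics(report: StudyReport) -> dict[str, float]:
    """Flat named statistics extracted from a study report."""
    table = report.marker_table.set_index("marker")
    stats: dict[str, float] = {
        "t_trace": report.overall.t_trace,
        "anticipation_mean": report.overall.anticipation_latency_mean,
        "anticipation_sd": report.overall.anticipation_latency_sd,
    }
    for task, m in report.per_task.items():
        stats[f"t_trace_{task.value}"] = m.t_trace
    key_map = {
        EventType.SIGMA1: "sigma1",
        EventType.DRIFT: "drift",
        EventType.REJECT_H1: "reject",
        EventType.CONFLICT: "conflict",
    }
    for et, prefix in key_map.items():
        if et.value not in table.index:
            continue
        row = table.loc[et.value]
        stats[f"{prefix}_activation"] = float(row["activation_frequency_pct"])
        stats[f"{prefix}_correct"] = float(row["correct_prediction_rate_pct"])
        stats[f"{prefix}_fp"] = float(row["false_positive_rate_pct"])
        stats[f"{prefix}_lead"] = float(row["mean_lead_time_s"])
    return stats


# --------------------------------------------------------------------------
# calibration

FREE_PARAMS = {
    "noise_sd": (0.02, 0.20),
    "behavior_lag_mean": (1.5, 5.0),
    "behavior_lag_sd": (0.05, 1.0),
    "commit_confidence": (0.55, 0.95),
    "tolerance": (0.1, 2.0),
}


@dataclass
class CalibrationResult:
    params: dict[str, float]
    achieved: dict[str, float]
    objective: float
    evaluations: int
    history: list[dict] = field(default_factory=list)


def _apply_params(base: StudyConfig, params: dict[str, float]) -> StudyConfig:
    overrides = dict(base.episode_overrides)
    disc = base.discriminator
    tolerance = base.tolerance
    for name, value in params.items():
        if name in ("noise_sd", "behavior_lag_mean", "behavior_lag_sd"):
            overrides[name] = value
        elif name == "commit_confidence":
            disc = replace(disc, commit_confidence=value)
        elif name == "tolerance":
            tolerance = value
    return replace(base, episode_overrides=overrides, discriminator=disc, tolerance=tolerance)


def _objective(achieved: dict[str, float], targets: dict[str, float]) -> float:
    total = 0.0
    for name, target in targets.items():
        got = achieved.get(name, float("nan"))
        if np.isnan(got):
            total += 4.0  # heavy penalty for an undefined statistic
            continue
        scale = abs(target) if target != 0 else 1.0
        total += ((got - target) / scale) ** 2
    return total


def calibrate(
    targets: dict[str, float],
    free_params,
    budget: int = 20,
    *,
    base_config: StudyConfig | None = None,
    seed: int = 0,
) -> CalibrationResult:
    """Random-search calibration of the simulator/detector free parameters.

    Minimises the summed squared relative error between the study statistics
    (see :func:`study_statistics`) and ``targets``.  With ``budget=0`` the
    initial parameters are evaluated and returned unchanged.
    """
    if not targets:
        raise ContractError("target table must not be empty")
    free_params = list(free_params)
    unknown = set(free_params) - set(FREE_PARAMS)
    if unknown:
        raise ContractError(f"unknown free parameters: {sorted(unknown)}")
    base = base_config or StudyConfig(n_episodes_per_task=40)
    rng = np.random.default_rng(seed)

    initial = {}
    for name in free_params:
        if name in base.episode_overrides:
            initial[name] = base.episode_overrides[name]
        elif name == "commit_confidence":
            initial[name] = base.discriminator.commit_confidence
        elif name == "tolerance":
            initial[name] = base.tolerance
        else:
            initial[name] = getattr(EpisodeConfig(), name)

    history: list[dict] = []
    best_params, best_achieved, best_obj = initial, None, float("inf")
    # the first candidate evaluates the base configuration untouched; random
    # draws over the documented parameter ranges follow
    candidates: list[dict | None] = [None] + [
        {
            name: float(rng.uniform(*FREE_PARAMS[name]))
            for name in free_params
        }
        for _ in range(budget)
    ]
    for cand in candidates:
        config = base if cand is None else _apply_params(base, cand)
        params = initial if cand is None else cand
        achieved = study_statistics(run_study(config))
        obj = _objective(achieved, targets)
        history.append({"params": params, "objective": obj})
        if obj < best_obj:
            best_params, best_achieved, best_obj = params, achieved, obj
        if budget == 0:
            break
    if best_achieved is None:
        best_achieved = study_statistics(run_study(_apply_params(base, initial)))
    return CalibrationResult(
        params=best_params,
        achieved=best_achieved,
        objective=best_obj if best_obj < float("inf") else _objective(best_achieved, targets),
        evaluations=len(history),
        history=history,
    )
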