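"""Episode and fault configuration.

An :class:`EpisodeConfig` fully determines a simulated episode (including its
random seed), mirroring the scenario YAML schema one-to-one.  Fault regimes are
parameterised by :class:`FaultSpec`; only the fields relevant to the selected
``kind`` are consulted, the rest are ignored.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import asdict, dataclass, field, replace


class TaskType(str, enum.Enum):
    """Cognitive task paradigm driving the scenario defaults."""

    MOTOR_CONTROL = "motor_control"   # oddball/P300-like motor planning
    INHIBITION = "inhibition"         # Go/No-Go late decision reversal
    OVERLOAD = "overload"             # RSVP-induced schema collapse


class FaultKind(str, enum.Enum):
    GRADUAL_DRIFT = "gradual_drift"
    DECISION_REVERSAL = "decision_reversal"
    SCHEMA_COLLAPSE = "schema_collapse"
    NONE = "none"


class ConfigurationError(ValueError):
    """Raised when a configuration value is out of range or inconsistent."""


@dataclass(frozen=True)
class FaultSpec:
    """Parameters of an injected fault regime.

    ``drift_amplitude``, ``onset_mu``/``onset_sigma`` belong to the gradual
    intent-drift regime; ``entropy_cutoff`` and ``decision_delay`` to the
    late decision reversal; ``input_rate``, ``precision_decay_tau`` and
    ``ambiguity_threshold`` to overload-induced schema collapse.
    ``drift_start``/``drift_end`` give the generic perturbation window; task
    scenarios may override the perturbation duration via ``drift_duration``.
    """

    kind: FaultKind = FaultKind.NONE
    drift_amplitude: float = 0.12
    onset_mu: float = 5.5
    onset_sigma: float = 1.0
    entropy_cutoff: float = 0.6
    decision_delay: tuple[float, float] = (0.300, 0.500)
    input_rate: float = 5.0
    precision_decay_tau: float = 2.2
    ambiguity_threshold: float = 0.7
    drift_start: float = 20.0
    drift_end: float = 40.0
    drift_duration: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", FaultKind(self.kind))
        object.__setattr__(self, "decision_delay", tuple(self.decision_delay))
        if self.onset_sigma < 0:
            raise ConfigurationError(f"onset_sigma must be >= 0, got {self.onset_sigma}")
        if not self.drift_start < self.drift_end:
            raise ConfigurationError(
                f"drift_start ({self.drift_start}) must be < drift_end ({self.drift_end})"
            )
        lo, hi = self.decision_delay
        if not 0 <= lo <= hi:
            raise ConfigurationError(f"decision_delay bounds must satisfy 0 <= lo <= hi, got {self.decision_delay}")
        if self.drift_amplitude < 0:
            raise ConfigurationError(f"drift_amplitude must be >= 0, got {self.drift_amplitude}")
        if self.precision_decay_tau <= 0:
            raise ConfigurationError(f"precision_decay_tau must be > 0, got {self.precision_decay_tau}")
        if not 0 <= self.ambiguity_threshold <= 1:
            raise ConfigurationError(f"ambiguity_threshold must be in [0, 1], got {self.ambiguity_threshold}")
        if self.drift_duration is not None and self.drift_duration <= 0:
            raise ConfigurationError(f"drift_duration must be > 0, got {self.drift_duration}")

    @property
    def perturbation_duration(self) -> float:
        """Length of the perturbation phase in seconds."""
        if self.drift_duration is not None:
            return self.drift_duration
        return self.drift_end - self.drift_start


@dataclass(frozen=True)
class EpisodeConfig:
    """Full scenario description; the seed makes episodes reproducible.

    ``behavior_lag_mean``/``behavior_lag_sd`` (seconds) set the Gaussian lag
    between fault onset and behavioral error onset; together with ``noise_sd``
    they are the calibrated free parameters of the simulator (see
    ``docs/methods.md`` for the frozen values and their provenance).
    """

    task_type: TaskType = TaskType.MOTOR_CONTROL
    duration: float = 60.0
    sampling_rate: float = 256.0
    n_channels: int = 4
    fault: FaultSpec = field(default_factory=FaultSpec)
    noise_sd: float = 0.014
    behavior_lag_mean: float = 4.5
    behavior_lag_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "task_type", TaskType(self.task_type))
        if self.duration <= 0:
            raise ConfigurationError(f"duration must be > 0, got {self.duration}")
        if self.sampling_rate <= 0:
            raise ConfigurationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.n_channels < 1:
            raise ConfigurationError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.behavior_lag_sd < 0:
            raise ConfigurationError(f"behavior_lag_sd must be >= 0, got {self.behavior_lag_sd}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def with_fault(self, fault: FaultSpec) -> "EpisodeConfig":
        return replace(self, fault=fault)

    def fingerprint(self) -> str:
        """Stable hash of the configuration (used in manifests and traces)."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


#: calibrated per-task behavioral lag (mean, sd) in seconds: the gap between
#: fault onset and error onset that reproduces the reported anticipation
#: structure under each task's detection dynamics (frozen after calibration)
SCENARIO_LAGS: dict[TaskType, tuple[float, float]] = {
    TaskType.MOTOR_CONTROL: (4.8, 0.3),
    TaskType.INHIBITION: (7.25, 0.3),
    TaskType.OVERLOAD: (3.6, 0.3),
}


def scenario(
    task_type: TaskType | str,
    *,
    with_fault: bool = True,
    seed: int = 0,
    **overrides,
) -> EpisodeConfig:
    """Build the canonical scenario configuration for a task paradigm.

    Each task couples to its fault regime: motor control to gradual intent
    drift, inhibition (Go/No-Go) to late decision reversal, and overload
    (RSVP) to schema collapse.  ``with_fault=False`` returns the matched
    fault-free control scenario.
    """
    task_type = TaskType(task_type)
    if not with_fault:
        fault = FaultSpec(kind=FaultKind.NONE)
    elif task_type is TaskType.MOTOR_CONTROL:
        # Transient drift burst spanning a few analysis windows.
        fault = FaultSpec(kind=FaultKind.GRADUAL_DRIFT, drift_duration=5.0)
    elif task_type is TaskType.INHIBITION:
        # late-stage reversal: entropy builds only after a sustained run
        fault = FaultSpec(kind=FaultKind.DECISION_REVERSAL, onset_mu=8.0)
    else:
        # RSVP overload accumulates before precision collapses
        fault = FaultSpec(kind=FaultKind.SCHEMA_COLLAPSE, onset_mu=8.0)
    lag_mean, lag_sd = SCENARIO_LAGS[task_type]
    defaults = {"behavior_lag_mean": lag_mean, "behavior_lag_sd": lag_sd}
    defaults.update(overrides)
    return EpisodeConfig(task_type=task_type, fault=fault, seed=seed, **defaults)
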