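"""Readers/writers for signals, episodes, configs, and run manifests.

Signals round-trip through NPZ (``signal``, ``sampling_rate``, optional
``behavior``) or long-format CSV (``time,channel,value`` with a
``# sampling_rate=...`` comment line).  Ground truth is a JSON sidecar.
Scenario/study configuration files are YAML or JSON mappings whose keys
mirror the configuration dataclasses exactly; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ConfigurationError, EpisodeConfig, FaultKind, FaultSpec, TaskType
from .discriminator import DiscriminatorParams
from .experiments import StudyConfig
from .simulate import CognitiveState, Episode, GroundTruth, StateInterval


class FormatError(ValueError):
    """A file does not match its declared format."""


# --------------------------------------------------------------------------
# signals


def write_signal(path, signal: np.ndarray, sampling_rate: float, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix == ".csv" else "npz")
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if fmt == "npz":
        np.savez(path, signal=signal, sampling_rate=float(sampling_rate))
    elif fmt == "csv":
        n_ch, n = signal.shape
        t = np.arange(n) / sampling_rate
        frame = pd.DataFrame(
            {
                "time": np.tile(t, n_ch),
                "channel": np.repeat(np.arange(n_ch), n),
                "value": signal.reshape(-1),
            }
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# sampling_rate={float(sampling_rate)}\n")
            frame.to_csv(fh, index=False)
    else:
        raise FormatError(f"unknown signal format {fmt!r}")


def read_signal(path, fmt: str | None = None) -> tuple[np.ndarray, float]:
    """Load a channels x samples matrix and its sampling rate."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = fmt or ("csv" if path.suffix == ".csv" else "npz")
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as data:
            if "signal" not in data:
                raise FormatError("NPZ file lacks a 'signal' array")
            if "sampling_rate" not in data:
                raise FormatError("NPZ file lacks sampling-rate metadata")
            signal = np.asarray(data["signal"], dtype=float)
            if signal.ndim != 2:
                raise FormatError(
                    f"signal must be a 2-D channels x samples array, got ndim={signal.ndim}"
                )
            return signal, float(data["sampling_rate"])
    if fmt == "csv":
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().strip()
            rate = None
            if first.startswith("#"):
                if "sampling_rate=" not in first:
                    raise FormatError("CSV comment line lacks sampling_rate metadata")
                rate = float(first.split("sampling_rate=")[1])
                header = fh.readline().strip()
            else:
                header = first
            if header.split(",")[:3] != ["time", "channel", "value"]:
                raise FormatError("CSV header must be 'time,channel,value'")
            frame = pd.read_csv(fh, names=["time", "channel", "value"])
        if rate is None:
            raise FormatError("CSV file lacks sampling-rate metadata")
        counts = frame.groupby("channel").size()
        if counts.nunique() != 1:
            raise FormatError("ragged channels: unequal samples per channel")
        n_ch, n = len(counts), int(counts.iloc[0])
        signal = np.empty((n_ch, n))
        for i, (_, grp) in enumerate(frame.groupby("channel")):
            signal[i] = grp.sort_values("time")["value"].to_numpy()
        return signal, rate
    raise FormatError(f"unknown signal format {fmt!r}")


# --------------------------------------------------------------------------
# episodes and ground truth


def truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "fault_kind": truth.fault_kind.value,
        "fault_onset": truth.fault_onset,
        "error_onset": truth.error_onset,
        "true_intent": truth.true_intent,
        "state_timeline": [
            {"t_start": iv.t_start, "t_end": iv.t_end, "state": iv.state.value}
            for iv in truth.state_timeline
        ],
        "meta": {k: v for k, v in truth.meta.items() if _json_safe(v)},
    }


def truth_from_dict(d: dict) -> GroundTruth:
    return GroundTruth(
        fault_kind=FaultKind(d["fault_kind"]),
        fault_onset=d.get("fault_onset"),
        error_onset=d.get("error_onset"),
        state_timeline=[
            StateInterval(iv["t_start"], iv["t_end"], CognitiveState(iv["state"]))
            for iv in d["state_timeline"]
        ],
        true_intent=d["true_intent"],
        meta=d.get("meta", {}),
    )


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def save_episode(episode: Episode, directory, stem: str = "episode") -> dict:
    """Write an episode as NPZ signal + JSON ground-truth/config sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    npz = directory / f"{stem}.npz"
    np.savez(
        npz,
        signal=episode.signal,
        behavior=episode.behavior,
        sampling_rate=float(episode.config.sampling_rate),
    )
    sidecar = directory / f"{stem}.truth.json"
    payload = {
        "truth": truth_to_dict(episode.truth),
        "config": config_to_dict(episode.config),
    }
    sidecar.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return {"signal": str(npz), "truth": str(sidecar)}


def load_episode(directory, stem: str = "episode") -> Episode:
    directory = Path(directory)
    with np.load(directory / f"{stem}.npz", allow_pickle=False) as data:
        signal = np.asarray(data["signal"], dtype=float)
        behavior = np.asarray(data["behavior"], dtype=float)
    payload = json.loads((directory / f"{stem}.truth.json").read_text(encoding="utf-8"))
    config = validate_config(payload["config"])
    truth = truth_from_dict(payload["truth"])
    return Episode(signal=signal, behavior=behavior, truth=truth, config=config)


# --------------------------------------------------------------------------
# configuration


def config_to_dict(config: EpisodeConfig) -> dict:
    d = dataclasses.asdict(config)
    d["task_type"] = config.task_type.value
    d["fault"]["kind"] = config.fault.kind.value
    d["fault"]["decision_delay"] = list(config.fault.decision_delay)
    return d


_EPISODE_KEYS = {f.name for f in dataclasses.fields(EpisodeConfig)}
_FAULT_KEYS = {f.name for f in dataclasses.fields(FaultSpec)}
_STUDY_KEYS = {f.name for f in dataclasses.fields(StudyConfig)}
_DISC_KEYS = {f.name for f in dataclasses.fields(DiscriminatorParams)}


def validate_config(raw: dict) -> EpisodeConfig | StudyConfig:
    """Build a typed configuration from a parsed YAML/JSON mapping.

    Defaults are applied for missing keys; unknown keys raise a
    :class:`ConfigurationError` naming the key.  A mapping containing any
    study-level key (``n_episodes_per_task``, ``tasks``, ...) yields a
    :class:`StudyConfig`, otherwise an :class:`EpisodeConfig`.
    """
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"configuration must be a mapping, got {type(raw).__name__}")
    study_only = _STUDY_KEYS - _EPISODE_KEYS
    if raw.keys() & study_only:
        return _build_study_config(raw)
    return _build_episode_config(raw)


def _check_keys(raw: dict, allowed: set[str], context: str) -> None:
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigurationError(f"unknown {context} key(s): {sorted(unknown)}")


def _build_episode_config(raw: dict) -> EpisodeConfig:
    _check_keys(raw, _EPISODE_KEYS, "episode configuration")
    kwargs = dict(raw)
    if "fault" in kwargs and isinstance(kwargs["fault"], dict):
        fault_raw = kwargs["fault"]
        _check_keys(fault_raw, _FAULT_KEYS, "fault")
        kwargs["fault"] = FaultSpec(**fault_raw)
    try:
        return EpisodeConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigurationError):
            raise
        raise ConfigurationError(str(exc)) from exc


def _build_study_config(raw: dict) -> StudyConfig:
    _check_keys(raw, _STUDY_KEYS, "study configuration")
    kwargs = dict(raw)
    if "discriminator" in kwargs and isinstance(kwargs["discriminator"], dict):
        disc_raw = kwargs["discriminator"]
        _check_keys(disc_raw, _DISC_KEYS, "discriminator")
        if "alpha_band" in disc_raw:
            disc_raw = {**disc_raw, "alpha_band": tuple(disc_raw["alpha_band"])}
        kwargs["discriminator"] = DiscriminatorParams(**disc_raw)
    if "episode_overrides" in kwargs:
        _check_keys(
            kwargs["episode_overrides"],
            {"noise_sd", "behavior_lag_mean", "behavior_lag_sd", "duration",
             "sampling_rate", "n_channels"},
            "episode_overrides",
        )
    try:
        return StudyConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigurationError):
            raise
        raise ConfigurationError(str(exc)) from exc


def load_config(path) -> EpisodeConfig | StudyConfig:
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    return validate_config(raw)


# --------------------------------------------------------------------------
# run manifest


ARTIFACT_VERSION = "0.1.0"


@dataclasses.dataclass
class RunManifest:
    """Inventory of a run directory: file checksums, seeds, fingerprints."""

    artifact_version: str
    config_fingerprint: str
    seeds: list[int]
    files: dict[str, str]  # relative path -> sha256

    @classmethod
    def from_directory(
        cls, directory, config_fingerprint: str = "", seeds: list[int] | None = None
    ) -> "RunManifest":
        directory = Path(directory)
        files = {}
        for p in sorted(directory.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                files[str(p.relative_to(directory))] = _sha256(p)
        return cls(ARTIFACT_VERSION, config_fingerprint, list(seeds or []), files)

    def write(self, directory) -> Path:
        path = Path(directory) / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def read(cls, directory) -> "RunManifest":
        payload = json.loads((Path(directory) / "manifest.json").read_text())
        return cls(**payload)

    def verify(self, directory) -> bool:
        directory = Path(directory)
        return all(
            (directory / rel).is_file() and _sha256(directory / rel) == digest
            for rel, digest in self.files.items()
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
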