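import numpy as np
import pytest

from cogtrace import StudyConfig, run_study, scenario, simulate_episode


@pytest.fixture(scope="session")
def motor_episode():
    """One fault-bearing motor-control episode with default calibration."""
    return simulate_episode(scenario("motor_control", seed=3))


@pytest.fixture(scope="session")
def small_study():
    """A small but complete study (3 tasks x 24 episodes)."""
    return run_study(StudyConfig(n_episodes_per_task=24, root_seed=5))


def mini_config(**kwargs):
    """A cheap episode configuration for distribution-level tests."""
    from cogtrace import EpisodeConfig

    defaults = dict(duration=20.0, sampling_rate=64.0, n_channels=1)
    defaults.update(kwargs)
    return EpisodeConfig(**defaults)


def make_features(rows, t0=2.0, dt=2.0, **common):
    """Build a synthetic FeatureVector sequence from (divergence,
    conflict_ratio[, entropy, evidence]) rows."""
    from cogtrace.features import FeatureVector

    out = []
    default_evidence = common.pop("evidence", None)
    for i, row in enumerate(rows):
        div, cr = row[0], row[1]
        entropy = row[2] if len(row) > 2 else 0.4
        if len(row) > 3:
            evidence = row[3]
        else:
            evidence = default_evidence or {"left": 1.0, "right": cr}
        out.append(
            FeatureVector(
                divergence=div,
                conflict_ratio=cr,
                spectral_entropy=entropy,
                synchrony=0.8,
                alpha_power=0.4,
                t_center=t0 + i * dt,
                evidence=evidence,
                **common,
            )
        )
    return out
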