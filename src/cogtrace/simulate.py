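"""Synthetic EEG-like episode generation with parameterised fault injection.

An episode is a multichannel band-limited signal (pink background noise, a
dominant alpha oscillation, and a narrowband motor-beta carrier encoding the
agent's intent class), a behavioral performance-error series, and a ground
truth timeline.  Three fault regimes can be injected on top of a clean
baseline:

``gradual_drift``
    A Gaussian-edged low-frequency (2 Hz) deviation of fixed amplitude whose
    onset is drawn from a truncated normal distribution.
``decision_reversal``
    A disorder phase (broadband noise ramp) raises rolling spectral entropy;
    once it crosses the entropy cutoff the encoded intent flips after a
    uniformly drawn decision delay.
``schema_collapse``
    A 5 Hz input-locked component whose gain follows an exponentially
    decaying precision; the intent carrier attenuates and diffuse noise grows
    with the ambiguity index (1 - precision), which defines entry into the
    ``overload`` state.

Behavioral error onset lags fault onset by a Gaussian-distributed interval;
everything is a pure function of the episode configuration (seed included).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .config import ConfigurationError, EpisodeConfig, FaultKind, FaultSpec
from .features import (
    ContractError,
    normalized_entropy,
    sliding_windows,
    window_psd,
)

# --- signal model constants (arbitrary units; see docs/methods.md) ----------
ALPHA_FREQ = 10.0        #: dominant resting oscillation (Hz)
ALPHA_AMP = 0.06         #: alpha amplitude per channel
PHASE_JITTER = 0.4       #: per-channel alpha phase jitter (rad)
INTENT_AMP = 0.03        #: intent carrier amplitude
INTENT_CARRIERS = {"left": 18.0, "right": 24.0}   #: class -> carrier freq (Hz)
MISCODE_P = 0.08         #: probability of atypical (swapped) intent encoding
DRIFT_FREQ = 2.0         #: gradual-drift carrier frequency (Hz)
NOISE_CV = 0.15          #: per-episode lognormal spread of the noise level
NOISE_CLIP = (0.7, 1.4)  #: bounds of the per-episode noise multiplier
ALPHA_CV = 0.50          #: per-episode lognormal spread of alpha amplitude
ALPHA_CLIP = (0.7, 3.0)  #: bounds of the per-episode alpha multiplier
DISORDER_AMP = 0.04      #: broadband disorder amplitude (decision reversal)
DISORDER_RISE_S = 1.5    #: disorder envelope mid-rise time after onset (s)
COMPETE_PEAK = 0.55      #: competing-intent carrier gain reached before the flip
INPUT_LOCKED_AMP = 0.15  #: 5 Hz input-locked response amplitude at full precision
INTENT_FLOOR = 0.85      #: residual intent gain under full schema collapse
OVERLOAD_NOISE_AMP = 0.005  #: diffuse noise amplitude at full ambiguity
OVERLOAD_COMPETE = 2.8   #: gain ceiling of the transiently intruding schema
LOCKED_DECAY_EXP = 0.55  #: locked-response gain ~ precision**exponent
EDGE_S = 0.3             #: Gaussian edge scale of perturbation envelopes (s)
CONFLICT_LEAD_S = 1.0    #: conflict state begins this long before the entropy crossing
RECOVERY_S = 1.1         #: signal recovery tail after the drift state ends (s)
ERD_DEPTH = 0.4          #: fractional alpha desynchronization during drift

#: behavioral error threshold and debounce used throughout the package
ERROR_THRESHOLD = 1.0
DEBOUNCE_S = 0.25
BEHAVIOR_NOISE = 0.12
#: rolling-window length (samples) for the generator's entropy trigger
ENTROPY_WINDOW = 512


class CognitiveState(str, enum.Enum):
    STABLE = "stable"
    DRIFT = "drift"
    CONFLICT = "conflict"
    REVERSAL = "reversal"
    OVERLOAD = "overload"


@dataclass(frozen=True)
class StateInterval:
    t_start: float
    t_end: float
    state: CognitiveState


@dataclass
class GroundTruth:
    """Per-episode ground truth: fault timing and the cognitive state timeline."""

    fault_kind: FaultKind
    fault_onset: float | None
    error_onset: float | None
    state_timeline: list[StateInterval]
    true_intent: str
    meta: dict = field(default_factory=dict)

    def validate(self, duration: float) -> None:
        tl = self.state_timeline
        if not tl:
            raise ValueError("state_timeline is empty")
        if abs(tl[0].t_start) > 1e-9 or abs(tl[-1].t_end - duration) > 1e-9:
            raise ValueError("state_timeline must cover [0, duration]")
        for a, b in zip(tl, tl[1:]):
            if abs(a.t_end - b.t_start) > 1e-9:
                raise ValueError("state_timeline intervals must be contiguous")
        if self.fault_kind is FaultKind.NONE and (
            self.fault_onset is not None or self.error_onset is not None
        ):
            raise ValueError("fault-free truth must not carry onsets")
        if (
            self.fault_onset is not None
            and self.error_onset is not None
            and self.error_onset < self.fault_onset
        ):
            raise ValueError("error_onset must be >= fault_onset")

    def state_at(self, t: float) -> CognitiveState:
        for iv in self.state_timeline:
            if iv.t_start <= t <= iv.t_end:
                return iv.state
        return self.state_timeline[-1].state


@dataclass
class Episode:
    """A simulated run: signal (channels x samples), behavior, ground truth."""

    signal: np.ndarray
    behavior: np.ndarray
    truth: GroundTruth
    config: EpisodeConfig
    #: named additive components, kept for fault injection and introspection
    components: dict = field(default_factory=dict, repr=False)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.signal.shape[1]) / self.config.sampling_rate


# --------------------------------------------------------------------------
# building blocks


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int) -> np.ndarray:
    """1/f-amplitude noise, unit standard deviation per channel."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _edge(t: np.ndarray, center: float, scale: float = EDGE_S) -> np.ndarray:
    """Gaussian-CDF rising edge used for smooth perturbation envelopes."""
    return norm.cdf(t, loc=center, scale=scale)


def _behavior_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    raw = rng.standard_normal(n + 64)
    smooth = np.convolve(raw, np.ones(64) / 64.0, mode="valid")[:n]
    return np.abs(smooth) * BEHAVIOR_NOISE * 8.0  # smoothing shrinks the sd


def error_onset(
    behavior: np.ndarray, threshold: float, sampling_rate: float
) -> float | None:
    """First time behavior exceeds ``threshold`` and stays above it >= 250 ms.

    Returns ``None`` when no debounced crossing exists.
    """
    behavior = np.asarray(behavior, dtype=float)
    if behavior.size == 0:
        raise ContractError("behavior vector is empty")
    if threshold <= 0:
        raise ContractError(f"threshold must be > 0, got {threshold}")
    hold = max(int(round(DEBOUNCE_S * sampling_rate)), 1)
    above = behavior > threshold
    if hold == 1:
        idx = np.flatnonzero(above)
        return float(idx[0] / sampling_rate) if idx.size else None
    run = np.convolve(above.astype(int), np.ones(hold, dtype=int), mode="valid")
    idx = np.flatnonzero(run == hold)
    if idx.size == 0:
        return None
    return float(idx[0] / sampling_rate)


# --------------------------------------------------------------------------
# baseline generation


def generate_baseline(config: EpisodeConfig) -> Episode:
    """Simulate a stationary fault-free episode.

    The signal is pink background noise plus a dominant alpha-band (8-12 Hz)
    oscillation and a narrowband intent carrier; behavior stays below the
    error threshold throughout, and the state timeline is one ``stable``
    interval.
    """
    if config.fault.kind is not FaultKind.NONE:
        raise ContractError("generate_baseline requires a fault-free configuration")
    return _build_baseline(config)


def _build_baseline(config: EpisodeConfig) -> Episode:
    fs, n, n_ch = config.sampling_rate, config.n_samples, config.n_channels
    t = np.arange(n) / fs
    root = np.random.SeedSequence(config.seed)
    # fixed spawn order so channel count never perturbs later draws
    ss_noise, ss_alpha, ss_intent, ss_fault, ss_lag, ss_behavior = root.spawn(6)
    noise_rng = np.random.default_rng(ss_noise)
    alpha_rng = np.random.default_rng(ss_alpha)
    intent_rng = np.random.default_rng(ss_intent)
    behavior_rng = np.random.default_rng(ss_behavior)

    # session-to-session variability: each episode draws its own noise level
    noise_scale = float(
        np.clip(noise_rng.lognormal(0.0, NOISE_CV), *NOISE_CLIP)
    )
    noise = _pink_noise(noise_rng, n_ch, n) * config.noise_sd * noise_scale

    # resting alpha power varies widely between sessions; each episode
    # draws its own level (this is what makes marginal faults missable)
    alpha_scale = float(np.clip(alpha_rng.lognormal(0.0, ALPHA_CV), *ALPHA_CLIP))
    common_phase = alpha_rng.uniform(0, 2 * np.pi)
    jitter = alpha_rng.normal(0, PHASE_JITTER, size=n_ch)
    alpha = ALPHA_AMP * alpha_scale * np.sin(
        2 * np.pi * ALPHA_FREQ * t[None, :] + common_phase + jitter[:, None]
    )

    classes = sorted(INTENT_CARRIERS)
    true_intent = classes[intent_rng.integers(len(classes))]
    miscoded = intent_rng.random() < MISCODE_P
    encoded = (
        [c for c in classes if c != true_intent][0] if miscoded else true_intent
    )
    intent_phase = intent_rng.uniform(0, 2 * np.pi)
    carrier = INTENT_AMP * np.sin(
        2 * np.pi * INTENT_CARRIERS[encoded] * t + intent_phase
    )
    intent = np.tile(carrier, (n_ch, 1))

    signal = noise + alpha + intent
    behavior = _behavior_baseline(behavior_rng, n)

    truth = GroundTruth(
        fault_kind=FaultKind.NONE,
        fault_onset=None,
        error_onset=None,
        state_timeline=[StateInterval(0.0, config.duration, CognitiveState.STABLE)],
        true_intent=true_intent,
        meta={"encoded_intent": encoded, "miscoded": miscoded},
    )
    truth.validate(config.duration)
    components = {
        "t": t,
        "alpha": alpha,
        "alpha_scale": alpha_scale,
        "intent_phase": intent_phase,
        "encoded": encoded,
        "fault_seed": ss_fault,
        "lag_seed": ss_lag,
        "noise_seed": ss_noise,
    }
    return Episode(signal=signal, behavior=behavior, truth=truth, config=config, components=components)


# --------------------------------------------------------------------------
# fault injection


def inject_fault(base: Episode, fault: FaultSpec, rng_state=None) -> Episode:
    """Inject a fault regime into a clean baseline episode.

    ``rng_state`` seeds the fault-specific draws (onset, decision delay,
    behavioral lag, extra noise); when omitted, the sub-streams reserved by
    the baseline's seed are used so that :func:`simulate_episode` stays a pure
    function of its configuration.
    """
    if base.truth.fault_kind is not FaultKind.NONE:
        raise ContractError("inject_fault requires a fault-free base episode")
    if fault.kind is FaultKind.NONE:
        raise ContractError("fault.kind must not be 'none'")
    if rng_state is None:
        ss = base.components["fault_seed"]
    elif isinstance(rng_state, np.random.SeedSequence):
        ss = rng_state
    else:
        ss = np.random.SeedSequence(rng_state)
    ss_onset, ss_mech, ss_lag, ss_extra = ss.spawn(4)
    onset_rng = np.random.default_rng(ss_onset)
    mech_rng = np.random.default_rng(ss_mech)
    lag_rng = np.random.default_rng(ss_lag)
    extra_rng = np.random.default_rng(ss_extra)

    config = base.config.with_fault(fault)
    duration, fs = config.duration, config.sampling_rate
    t = base.components["t"]
    meta = dict(base.truth.meta)

    raw_onset = onset_rng.normal(fault.onset_mu, fault.onset_sigma)
    onset = float(np.clip(raw_onset, 0.0, duration))
    if raw_onset != onset:
        meta["onset_clamped"] = True

    signal = base.signal.copy()
    states: list[StateInterval]

    if fault.kind is FaultKind.GRADUAL_DRIFT:
        signal, states = _apply_drift(base, signal, t, onset, fault, mech_rng, duration)
    elif fault.kind is FaultKind.DECISION_REVERSAL:
        signal, states, meta_r = _apply_reversal(
            base, signal, t, onset, fault, mech_rng, extra_rng, duration
        )
        meta.update(meta_r)
    else:
        signal, states = _apply_collapse(
            base, signal, t, onset, fault, mech_rng, extra_rng, duration
        )

    # behavioral degradation lags the fault; zero-amplitude drift is a no-op
    no_effect = fault.kind is FaultKind.GRADUAL_DRIFT and fault.drift_amplitude == 0
    behavior = base.behavior.copy()
    err_onset = None
    if not no_effect:
        lag = max(lag_rng.normal(config.behavior_lag_mean, config.behavior_lag_sd), 0.1)
        te = onset + lag
        if te < duration - DEBOUNCE_S:
            mask = t >= te
            behavior = behavior + mask * (
                1.05 + 0.8 * (1 - np.exp(-(np.maximum(t - te, 0)) / 1.5))
            )
            err_onset = error_onset(behavior, ERROR_THRESHOLD, fs)
        else:
            meta["error_beyond_duration"] = True

    truth = GroundTruth(
        fault_kind=fault.kind,
        fault_onset=onset,
        error_onset=err_onset,
        state_timeline=states,
        true_intent=base.truth.true_intent,
        meta=meta,
    )
    truth.validate(duration)
    components = dict(base.components)
    return Episode(signal=signal, behavior=behavior, truth=truth, config=config, components=components)


def _timeline(duration: float, *marks: tuple[float, CognitiveState]) -> list[StateInterval]:
    """Build a contiguous state timeline from (start, state) change points."""
    points = [(0.0, CognitiveState.STABLE)] + [
        (max(0.0, min(s, duration)), st) for s, st in marks
    ]
    out: list[StateInterval] = []
    for (s, st), (e, _) in zip(points, points[1:] + [(duration, None)]):
        if e > s:
            out.append(StateInterval(s, e, st))
    if not out:
        out = [StateInterval(0.0, duration, CognitiveState.STABLE)]
    # force exact coverage after clipping
    out[0] = StateInterval(0.0, out[0].t_end, out[0].state)
    out[-1] = StateInterval(out[-1].t_start, duration, out[-1].state)
    return out


def _apply_drift(base, signal, t, onset, fault, mech_rng, duration):
    alpha = base.components["alpha"]
    # the drift state lasts `length`; the signal deviation fades over a
    # recovery transition that outlives the state itself
    length = fault.perturbation_duration
    env = fault.drift_amplitude * (
        _edge(t, onset + 2 * EDGE_S) - _edge(t, onset + length + RECOVERY_S, 0.8)
    )
    env = np.clip(env, 0.0, None)
    phase = mech_rng.uniform(0, 2 * np.pi)
    drift = env * np.sin(2 * np.pi * DRIFT_FREQ * t + phase)
    # attentional drift desynchronises the resting alpha rhythm (ERD)
    erd = ERD_DEPTH * env / max(fault.drift_amplitude, 1e-12)
    signal = signal + drift[None, :] - alpha * erd[None, :]
    states = _timeline(
        duration,
        (onset, CognitiveState.DRIFT),
        (min(onset + length, duration), CognitiveState.STABLE),
    )
    return signal, states


def _apply_reversal(base, signal, t, onset, fault, mech_rng, extra_rng, duration):
    fs = base.config.sampling_rate
    n_ch = signal.shape[0]
    # disorder scales with the episode's ongoing rhythm amplitude so the
    # entropy trigger geometry is preserved across alpha levels
    disorder = (
        extra_rng.standard_normal(signal.shape)
        * DISORDER_AMP
        * base.components["alpha_scale"]
    )

    rise = _edge(t, onset + DISORDER_RISE_S, 0.8)
    encoded = base.components["encoded"]
    other = [c for c in INTENT_CARRIERS if c != encoded][0]
    phase = base.components["intent_phase"]
    old = INTENT_AMP * np.sin(2 * np.pi * INTENT_CARRIERS[encoded] * t + phase)
    new = INTENT_AMP * np.sin(2 * np.pi * INTENT_CARRIERS[other] * t + phase)
    # the competing schema grows with the disorder itself, peaking as the
    # entropy trigger approaches
    compete_gain = COMPETE_PEAK * rise

    # rolling spectral entropy on the provisional (pre-flip) signal: disorder
    # plus the ramping competitor, i.e. exactly what a monitor would observe
    provisional = signal + disorder * rise[None, :] + (new * compete_gain)[None, :]
    t_cross = None
    for w in sliding_windows(provisional, ENTROPY_WINDOW, sampling_rate=fs):
        if w.t_end <= onset:
            continue
        _, p = window_psd(w.data, fs)
        if normalized_entropy(p) > fault.entropy_cutoff:
            t_cross = w.t_end
            break

    meta: dict = {"entropy_cross": t_cross}
    if t_cross is None:
        states = _timeline(duration, (onset, CognitiveState.CONFLICT))
        return (
            signal + disorder * rise[None, :] + (new * compete_gain)[None, :],
            states,
            meta,
        )

    delay = mech_rng.uniform(*fault.decision_delay)
    t_flip = min(t_cross + delay, duration)
    meta["flip"] = t_flip
    meta["decision_delay"] = delay

    # during the conflict phase the competing schema's carrier ramps up
    # toward (but not past) the committed one; at t_flip the intent flips
    # and the losing carrier is extinguished
    flip_mask = t >= t_flip
    new_gain = np.where(flip_mask, 1.0, compete_gain)
    old_gain = np.where(flip_mask, 0.0, 1.0)
    swap = new * new_gain + old * (old_gain - 1.0)
    meta["post_flip_intent"] = other

    # disorder resolves shortly after the reversal is enacted
    env = rise * (1 - _edge(t, t_flip + 0.8, 0.4))
    signal = signal + disorder * env[None, :] + np.tile(swap, (n_ch, 1))
    states = _timeline(
        duration,
        # schema competition becomes the dominant cognitive state at the
        # entropy crossing; the disorder build-up before it is still
        # nominally stable
        (max(onset, t_cross - CONFLICT_LEAD_S), CognitiveState.CONFLICT),
        (t_flip, CognitiveState.REVERSAL),
    )
    return signal, states, meta


def _apply_collapse(base, signal, t, onset, fault, mech_rng, extra_rng, duration):
    tau = fault.precision_decay_tau
    delta = np.maximum(t - onset, 0.0)
    precision = np.exp(-delta / tau)
    ambiguity = (1.0 - precision) * (t >= onset)

    # input-locked 5 Hz response; power decays with precision (gain ~ sqrt)
    locked = (
        INPUT_LOCKED_AMP
        * np.power(precision, LOCKED_DECAY_EXP)
        * (t >= onset)
        * np.sin(2 * np.pi * fault.input_rate * (t - onset))
    )
    # the intent carrier loses gain as precision decays
    encoded = base.components["encoded"]
    other = [c for c in INTENT_CARRIERS if c != encoded][0]
    phase = base.components["intent_phase"]
    carrier = INTENT_AMP * np.sin(2 * np.pi * INTENT_CARRIERS[encoded] * t + phase)
    gain = INTENT_FLOOR + (1 - INTENT_FLOOR) * precision
    attenuation = carrier * (gain - 1.0)  # additive correction (negative)

    # an alternative schema intrudes transiently while the collapse unfolds
    # (grows with ambiguity, fades as the stream disengages); per-episode
    # susceptibility sets how strongly it competes with the committed intent
    susceptibility = mech_rng.uniform()
    intruder = (
        INTENT_AMP
        * OVERLOAD_COMPETE
        * susceptibility
        * ambiguity
        * np.exp(-delta / (2 * tau))
        * np.sin(2 * np.pi * INTENT_CARRIERS[other] * t + phase)
    )

    diffuse = extra_rng.standard_normal(signal.shape) * OVERLOAD_NOISE_AMP * ambiguity[None, :]

    signal = signal + locked[None, :] + attenuation[None, :] + intruder[None, :] + diffuse
    if fault.ambiguity_threshold < 1.0:
        t_amb = onset + tau * float(np.log(1.0 / (1.0 - fault.ambiguity_threshold)))
    else:
        t_amb = duration
    states = _timeline(
        duration,
        (onset, CognitiveState.DRIFT),
        (min(t_amb, duration), CognitiveState.OVERLOAD),
    )
    return signal, states


# --------------------------------------------------------------------------
# entry point


def simulate_episode(config: EpisodeConfig) -> Episode:
    """Generate a baseline and, when configured, inject the fault.

    Pure function of ``config``: identical configurations (seed included)
    produce bit-identical episodes.
    """
    base = _build_baseline(config.with_fault(FaultSpec(kind=FaultKind.NONE)))
    # keep the caller's config (with its fault spec) on the returned episode
    if config.fault.kind is FaultKind.NONE:
        return Episode(
            signal=base.signal,
            behavior=base.behavior,
            truth=base.truth,
            config=config,
            components=base.components,
        )
    return inject_fault(base, config.fault)
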