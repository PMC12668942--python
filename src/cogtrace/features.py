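"""Sliding-window spectral feature extraction.

Each analysis window of the multichannel signal is summarised by a
:class:`FeatureVector`: Jensen-Shannon divergence of its power spectral
density against a baseline reference, normalised spectral entropy, alpha-band
power fraction, alpha-band phase-locking across channels, and the conflict
ratio between competing intent hypotheses (matched-filter evidence).
All features are dimensionless and bounded in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.spatial.distance import jensenshannon

#: frequency band over which spectral features are computed (Hz)
FEATURE_BAND = (1.0, 45.0)
#: Welch segment length within a 512-sample window; 1 Hz resolution at 256 Hz
PSD_NPERSEG = 256

CANONICAL_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}


class ContractError(ValueError):
    """A precondition of an operation was violated."""


@dataclass(frozen=True)
class IntentTemplate:
    """An intent-class template for the matched-filter bank.

    Either a spectral band (power concentrated in ``band`` Hz) or an explicit
    time-domain ``waveform`` (channels x samples) may be given.  Band
    templates are phase-invariant and are what the study pipeline uses; the
    motor-beta defaults separate two imagined-movement classes.
    """

    name: str
    band: tuple[float, float] | None = None
    waveform: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if (self.band is None) == (self.waveform is None):
            raise ContractError("exactly one of band or waveform must be given")


#: default two-class intent bank (low/high motor-beta carriers)
DEFAULT_TEMPLATES = (
    IntentTemplate("left", band=(16.0, 20.0)),
    IntentTemplate("right", band=(22.0, 26.0)),
)


@dataclass(frozen=True)
class FeatureVector:
    divergence: float
    conflict_ratio: float
    spectral_entropy: float
    synchrony: float
    alpha_power: float
    t_center: float
    #: matched-filter evidence per intent template (not a trigger by itself)
    evidence: dict[str, float] = field(default_factory=dict, compare=False)

    @property
    def leading_hypothesis(self) -> str | None:
        if not self.evidence:
            return None
        return max(self.evidence, key=self.evidence.get)

    @property
    def confidence(self) -> float:
        """max evidence / total evidence; 0 when there is no evidence at all."""
        total = sum(self.evidence.values())
        if total <= 0:
            return 0.0
        return max(self.evidence.values()) / total


@dataclass(frozen=True)
class Window:
    """A signal window with its sample offset and timing."""

    data: np.ndarray  # channels x window_size
    start: int
    sampling_rate: float

    @property
    def t_center(self) -> float:
        return (self.start + self.data.shape[1] / 2) / self.sampling_rate

    @property
    def t_end(self) -> float:
        return (self.start + self.data.shape[1]) / self.sampling_rate


def sliding_windows(
    signal: np.ndarray, window_size: int, step: int | None = None, sampling_rate: float = 256.0
):
    """Yield consecutive windows; a trailing fragment shorter than
    ``window_size`` is discarded.

    ``signal`` is channels x samples; ``step`` defaults to ``window_size``
    (non-overlapping).
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if window_size < 2:
        raise ContractError(f"window_size must be >= 2, got {window_size}")
    step = window_size if step is None else step
    if step < 1:
        raise ContractError(f"step must be >= 1, got {step}")
    n = signal.shape[1]
    for start in range(0, n - window_size + 1, step):
        yield Window(signal[:, start : start + window_size], start, sampling_rate)


def window_psd(window: np.ndarray, sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Channel-averaged Welch PSD of a window, band-limited and normalised.

    Returns ``(freqs, p)`` with ``p`` summing to 1 over :data:`FEATURE_BAND`.
    An all-zero window yields the uniform distribution.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    nperseg = min(PSD_NPERSEG, window.shape[1])
    freqs, psd = sps.welch(window, fs=sampling_rate, nperseg=nperseg, axis=-1)
    p = psd.mean(axis=0)
    lo, hi = FEATURE_BAND
    mask = (freqs >= lo) & (freqs <= hi)
    freqs, p = freqs[mask], p[mask]
    total = p.sum()
    if total <= 0:
        p = np.full_like(p, 1.0 / len(p))
    else:
        p = p / total
    return freqs, p


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (base 2), bounded in [0, 1]."""
    d = jensenshannon(np.asarray(p, float), np.asarray(q, float), base=2)
    if np.isnan(d):  # both distributions all-zero
        return 0.0
    return float(min(d * d, 1.0))


def band_power(freqs: np.ndarray, p: np.ndarray, band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(p[mask].sum())


def phase_locking_value(
    window: np.ndarray, sampling_rate: float, band: tuple[float, float] = (8.0, 12.0)
) -> float:
    """Mean pairwise phase-locking value across channels in ``band``.

    Returns 1.0 for single-channel input (perfect self-synchrony by
    convention).
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    n_ch = window.shape[0]
    if n_ch < 2:
        return 1.0
    nyq = sampling_rate / 2
    lo = max(band[0] / nyq, 1e-6)
    hi = min(band[1] / nyq, 0.999)
    b, a = sps.butter(3, [lo, hi], btype="band")
    filtered = sps.filtfilt(b, a, window, axis=-1)
    phases = np.angle(sps.hilbert(filtered, axis=-1))
    plvs = []
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            plvs.append(np.abs(np.mean(np.exp(1j * (phases[i] - phases[j])))))
    return float(np.mean(plvs))


def hypothesis_evidence(
    window: np.ndarray,
    templates=DEFAULT_TEMPLATES,
    sampling_rate: float = 256.0,
    psd: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict[str, float]:
    """Non-negative matched-filter evidence for each intent template.

    Band templates score the window's channel-averaged band power on the
    normalised PSD; waveform templates score the rectified normalised
    correlation with the window.  ``psd`` may pass a precomputed
    ``(freqs, p)`` pair to avoid re-estimation.
    """
    templates = list(templates)
    if len(templates) < 2:
        raise ContractError("at least 2 intent templates are required")
    window = np.atleast_2d(np.asarray(window, dtype=float))
    scores: dict[str, float] = {}
    freqs_p: tuple[np.ndarray, np.ndarray] | None = psd
    for tpl in templates:
        if tpl.band is not None:
            if freqs_p is None:
                freqs_p = window_psd(window, sampling_rate)
            scores[tpl.name] = band_power(*freqs_p, tpl.band)
        else:
            w = np.atleast_2d(np.asarray(tpl.waveform, dtype=float))
            if w.shape != window.shape:
                raise ContractError(
                    f"template {tpl.name!r} shape {w.shape} != window shape {window.shape}"
                )
            denom = np.linalg.norm(w) * np.linalg.norm(window)
            corr = 0.0 if denom == 0 else float(np.vdot(w, window) / denom)
            scores[tpl.name] = max(corr, 0.0)
    return scores


def conflict_ratio(scores: dict[str, float]) -> float:
    """Second-largest over largest evidence score, in [0, 1].

    1.0 means full ambiguity between the two leading hypotheses; 0.0 a single
    unopposed hypothesis (or no evidence at all).
    """
    vals = sorted(scores.values(), reverse=True)
    if len(vals) < 2 or vals[0] <= 0:
        return 0.0
    return float(min(vals[1] / vals[0], 1.0))


def extract_features(
    window: np.ndarray | Window,
    baseline_reference: np.ndarray,
    *,
    sampling_rate: float = 256.0,
    alpha_band: tuple[float, float] = (8.0, 12.0),
    templates=DEFAULT_TEMPLATES,
    t_center: float | None = None,
) -> FeatureVector:
    """Compute the window's feature vector against a baseline PSD reference.

    ``baseline_reference`` must be a normalised spectral distribution on the
    grid produced by :func:`window_psd` (it sums to 1).
    """
    if isinstance(window, Window):
        if t_center is None:
            t_center = window.t_center
        sampling_rate = window.sampling_rate
        window = window.data
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[1] < 2:
        raise ContractError("window must have >= 2 samples per channel")
    baseline_reference = np.asarray(baseline_reference, dtype=float)
    if not np.isclose(baseline_reference.sum(), 1.0, atol=1e-6):
        raise ContractError("baseline_reference must be normalised (sum to 1)")

    freqs, p = window_psd(window, sampling_rate)
    if len(p) != len(baseline_reference):
        raise ContractError(
            f"baseline_reference has {len(baseline_reference)} bins, window PSD has {len(p)}"
        )
    evidence = hypothesis_evidence(window, templates, sampling_rate, psd=(freqs, p))
    return FeatureVector(
        divergence=js_divergence(p, baseline_reference),
        conflict_ratio=conflict_ratio(evidence),
        spectral_entropy=normalized_entropy(p),
        synchrony=phase_locking_value(window, sampling_rate, alpha_band),
        alpha_power=band_power(freqs, p, alpha_band),
        t_center=0.0 if t_center is None else float(t_center),
        evidence=evidence,
    )


def normalized_entropy(p: np.ndarray) -> float:
    """Shannon entropy of a distribution divided by log of its bin count."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n <= 1:
        return 0.0
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum() / np.log(n))
    return min(max(h, 0.0), 1.0)
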