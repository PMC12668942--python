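# Methods

This note documents the generative model, the detection pipeline, the
scoring conventions, the calibrated parameters, and the known limitations of
the package. Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted beyond what the code measures.

## Signal model

An episode is a 4-channel, 60 s, 256 Hz time series in arbitrary units,
built additively from:

- **pink background noise** — 1/f-amplitude noise, per-channel standard
  deviation `noise_sd` (default 0.014). Each episode additionally draws a
  lognormal noise multiplier (CV 0.15, clipped to [0.7, 1.4]) modelling
  session-to-session recording quality.
- **alpha rhythm** — 10 Hz sinusoid, base amplitude 0.06, a common phase
  with 0.4 rad per-channel jitter (giving alpha-band phase locking ≈ 0.9).
  Resting alpha power varies strongly between sessions, so each episode
  draws a lognormal alpha multiplier (CV 0.5, clipped to [0.7, 3.0]). This
  variability is deliberate: it is the main reason marginal faults are
  sometimes missed (a high-alpha background dilutes the spectral share of a
  fixed-amplitude perturbation), which is what produces sub-100% marker
  activation frequencies.
- **intent carrier** — a narrowband motor-beta tone encoding the agent's
  intent class ("left" → 18 Hz, "right" → 24 Hz; amplitude 0.03). With
  probability 0.08 an episode encodes the *opposite* class throughout — an
  analogue of atypical sensorimotor spectral organisation — which is what
  bounds the σ1 correct-prediction rate near 92%.
- **behavior channel** — rectified smoothed noise (≈ 0.12 SD) far below the
  error threshold (1.0); after a fault, error onset occurs at
  fault onset + lag, lag ~ Normal(per-task mean, 0.3 s), as a sustained
  excursion above threshold. `error_onset()` recovers it with a 250 ms
  debounce, and the stored ground truth is exactly the debounced measurement.

All randomness derives from one root seed per episode via fixed-order
sub-streams (noise, alpha, intent, fault, lag, behavior), so episodes are
bit-reproducible and adding channels does not perturb onset draws.

## Fault regimes

- **Gradual intent drift** (motor-control task): a 2 Hz deviation of fixed
  amplitude 0.12 with Gaussian-CDF edges, onset ~ Normal(5.5, 1.0) s clipped
  to the episode, plateau 5 s in the task scenario (the generic
  configuration keeps the 20 s drift window). The drift state ends with the
  plateau, but the signal deviation decays over a further ≈ 1.1 s recovery
  tail, and the ongoing alpha rhythm desynchronises by up to 40% during the
  burst (event-related desynchronisation). Detections inside the recovery
  tail fall outside the annotated drift state — a deliberate source of
  imperfect traceability.
- **Late decision reversal** (inhibition task, onset ~ Normal(8.0, 1.0) s):
  broadband disorder (amplitude 0.04 × the episode's alpha level) ramps up
  over ≈ 3 s while the competing intent's carrier grows with it (peak gain
  0.55 of the committed carrier). The generator computes rolling spectral
  entropy on this pre-flip signal with the same estimator the detector uses;
  at the first window crossing the 0.6 cutoff, the intent flips after a
  uniform 300–500 ms decision delay, the losing carrier is extinguished, and
  the disorder resolves. Ground-truth states: stable → conflict (from 1 s
  before the crossing) → reversal.
- **Schema collapse** (RSVP overload task, onset ~ Normal(8.0, 1.0) s):
  precision decays as exp(−Δt/2.2 s). A 5 Hz input-locked response enters
  with gain precision^0.55 and amplitude 0.15; the intent carrier attenuates
  toward a 0.85 floor; diffuse noise and a transiently intruding alternative
  schema (gain ∝ susceptibility × ambiguity × exp(−Δt/4.4 s), susceptibility
  ~ U(0,1) per episode) grow with ambiguity. The `overload` state begins
  when ambiguity crosses 0.7 (≈ 2.65 s after onset).

## Detection

Non-overlapping 512-sample windows (2 s at 256 Hz). Per-window features use
a Welch PSD (256-sample segments, 1 Hz resolution) band-limited to 1–45 Hz
and normalised:

- **divergence** — Jensen–Shannon divergence (base 2, squared distance, in
  [0, 1]) against a baseline reference: the per-bin *median* of the first 3
  windows' spectra. The median makes the reference robust to a fault onset
  landing inside the third calibration window (the early tail of the onset
  distribution).
- **spectral entropy** — Shannon entropy of the normalised spectrum over
  log(bin count).
- **conflict ratio** — second-largest over largest matched-filter evidence;
  the default bank scores band power in the two intent-carrier bands.
- **alpha power, synchrony** — band-power fraction and mean pairwise
  phase-locking in 8–12 Hz; reported but not used as triggers.

The per-window state machine: σ1 at the first window whose evidence
confidence reaches 0.75; after commitment, one Reject(H1) when entropy
exceeds 0.6 or the leading hypothesis changes; divergence > 0.35 emits
DriftEvent, *else* conflict ratio > 0.5 emits ConflictEscalate (strict
if/elif precedence, checked on every window); Accept(H1) once after 7
consecutive committed-leader windows with no prior warning. Events are
timestamped at the end of the window that produced them — detection cannot
precede its data, and all detection times are therefore quantised to the
2 s window grid.

Accept(H1)'s trigger is a reconstruction (its vocabulary row exists but no
trigger is specified anywhere): 7 windows rather than 5 so that confirmation
cannot pre-empt warnings from the latest fault onsets (≈ 8 + 2σ s).

## Scoring conventions

A marker is *interpretable* when its timestamp lies within `tolerance`
(default 1.0 s) of a type-consistent state interval: DriftEvent ↔ drift;
ConflictEscalate ↔ conflict or overload; Reject(H1) ↔ reversal or any
post-fault interval; Accept(H1) ↔ stable; σ1 ↔ always. T_trace is the
interpretable fraction of all emitted markers (1.0 for an empty trace, by
convention). σ1 *correctness* is intent match against ground truth, not
temporal placement; warning-marker correctness additionally requires
preceding error onset, and lead-time statistics use correct warning markers
only. False positives are warning markers in fault-free episodes or outside
any consistent interval; for σ1/Accept only the out-of-interval clause
applies, which makes σ1's 0% false-positive rate structural. The correct-
prediction denominator is per-marker (not per-episode).

## Calibrated parameters (frozen)

The study tunes five free parameters once (see `cogtrace.experiments.calibrate`)
and freezes them as package defaults: `noise_sd = 0.014`; behavioral lag
means per task — motor 4.8 s, inhibition 7.25 s, overload 3.6 s (the
differences compensate for each regime's detection delay so warnings lead
errors comparably across tasks); `behavior_lag_sd = 0.3`;
`commit_confidence = 0.75`; `tolerance = 1.0 s`. The structural signal
constants listed above were chosen during design so that each regime is
detectable but marginal, and are likewise frozen in `cogtrace.simulate`.

At full scale (300 episodes/task, 80% fault-bearing) the frozen
configuration yields, reproducibly across seeds: mean T_trace ≈ 0.92
(per-task ≈ 0.89–0.96), anticipation latency ≈ 2.3 s, σ1 activation 100%
with ≈ 92% intent correctness, DriftEvent activation ≈ 70% over
motor+overload episodes with mean lead ≈ 1.6 s, Reject(H1) ≈ 43% and
ConflictEscalate ≈ 22% over inhibition+overload episodes.

## Known limitations

- **Latency dispersion.** Detection times are quantised to the 2 s window
  grid; the grid phase relative to fault onset is effectively uniform, which
  alone contributes ≈ 2/√12 ≈ 0.58 s of spread. The anticipation-latency SD
  therefore settles near 0.8 s and cannot reach ≈ 0.4 s at the default
  non-overlapping windowing; only a smaller window step would reduce it.
- **Traceability vs. per-marker precision.** A mean T_trace near 0.91
  requires roughly 8% of all markers to be misplaced. With σ1 structurally
  never misplaced and warning-marker false-positive rates in the single
  digits, that mass cannot be distributed without exceeding some marker's
  nominal precision; in this implementation it falls on DriftEvent markers
  (recovery-tail and post-collapse detections), whose correct-prediction
  rate consequently sits near 68% rather than the high 80s. The two
  quantities are jointly over-constrained; the package prioritises the
  traceability, latency, and activation statistics.
- **Synthetic scope.** The generator emulates stationary band-limited
  rhythms with additive, precisely-timed perturbations. Real EEG has
  non-stationary broadband dynamics, artifacts (ocular, muscular), volume
  conduction, and inter-subject variability far beyond the lognormal
  alpha/noise scaling used here. Passing tests demonstrate that the
  detection-and-tracing pipeline behaves as specified under the stated
  model, not that it would achieve comparable statistics on recorded
  signals.
- The synchrony feature is computed and reported but never used as a
  trigger, mirroring the pseudocode's branching; whether it should
  participate is left open.
- The ≤ 5% false-positive gate (fault-free episodes emitting any warning)
  holds with a wide margin under the frozen configuration; it constrains how
  much the free parameters can be moved before baseline windows start
  crossing thresholds.
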