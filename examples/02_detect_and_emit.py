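"""Run the discriminator on a simulated episode and print its symbolic trace.

Sliding 2 s windows are summarised by spectral features (divergence against a
baseline reference, entropy, conflict ratio, alpha power); threshold
crossings become cognitive events, which map onto the user-facing symbolic
vocabulary.
"""

from cogtrace import detect_events, emit, format_timeline, scenario, simulate_episode

episode = simulate_episode(scenario("inhibition", seed=11))
events = detect_events(episode.signal, sampling_rate=episode.config.sampling_rate)
trace = emit(events, episode_id="inhibition-demo")

print(format_timeline(trace, duration=episode.config.duration))
print()
print(f"ground-truth fault onset {episode.truth.fault_onset:.1f} s, "
      f"reversal enacted at {episode.truth.meta.get('flip', float('nan')):.1f} s, "
      f"error onset {episode.truth.error_onset:.1f} s")

# Expected shape of the trace: an early sigma-1 commitment, then a
# RejectH1 (entropy spike / hypothesis flip) ahead of the behavioral error,
# sometimes preceded by a ConflictEscalate while the schemas compete.
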