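"""Run a small version of the full simulation study and print the marker table.

Forty episodes per task (80% fault-bearing) are simulated, detected, emitted,
and scored; the summary table mirrors the per-marker layout of the full
study: activation frequency, correct-prediction rate, false-positive rate,
and lead times per symbolic marker over its task pool.
"""

from cogtrace import StudyConfig, run_study

report = run_study(StudyConfig(n_episodes_per_task=40, root_seed=0))

print(report.marker_table.round(2).to_string(index=False))
print()
print(f"overall mean T_trace:        {report.overall.t_trace:.3f}")
print(f"anticipation latency (mean): {report.overall.anticipation_latency_mean:.2f} s "
      f"over {report.overall.n_latencies} episodes")
for task, metrics in report.per_task.items():
    print(f"  {task.value:14s} T_trace {metrics.t_trace:.3f}")

# At full scale (300 episodes/task; scripts/acceptance.py) these statistics
# stabilise near: T_trace ~ 0.92, anticipation ~ 2.3 s, sigma-1 activation
# 100%, DriftEvent activation ~ 70% over motor+overload episodes.
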