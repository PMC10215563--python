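"""Compute per-trial outcome measures for a session and assemble the
probe-level and trial-level analysis tables.

Outcomes per trial: interception (ball entered the padded racquet box),
bounce-fixation pitch and duration, and peak foreswing velocity.  The trial
table also codes the run of consecutive preceding fed-back 'errors' (capped
at 4) and carries the most recent anxiety rating forward.
"""

from vrintercept import SessionConfig, simulate_session
from vrintercept.metrics import assemble_analysis_table, session_metrics

cfg = SessionConfig()
bundle = simulate_session(cfg, seed=5, participant="p01")

tm = session_metrics(bundle.trials, cfg.physics)
tm["participant"] = "p01"
probe_table, trial_table = assemble_analysis_table(
    bundle.manifest.trials, bundle.manifest.probes, tm)

print(f"interception rate: {tm.intercepted.mean():.3f}")
print(f"mean bounce-fixation pitch: {tm.bounce_fix_pitch.mean():.1f} deg "
      f"(duration {tm.bounce_fix_duration.mean() * 1e3:.0f} ms)")
print(f"mean peak swing velocity: {tm.peak_swing_velocity.mean():.2f} m/s")

print("\nprobe table (one row per self-report):")
cols = ["block", "trial", "pressure", "feedback", "pof", "cof", "anxiety",
        "peak_swing_velocity"]
print(probe_table[cols].head(6).round(2).to_string(index=False))

print("\ntrial table (error-dependency coding):")
cols = ["block", "trial", "feedback_call", "prior_errors", "carried_anxiety",
        "intercepted"]
print(trial_table[cols].iloc[30:38].round(2).to_string(index=False))
print("\nprior_errors counts the uninterrupted run of preceding 'miss' calls; "
      "carried_anxiety repeats the latest probe's rating until the next probe.")
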