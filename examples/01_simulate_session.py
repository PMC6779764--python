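"""Simulate a fixed-interval experiment and inspect the trial table.

Generates 6 virtual animals, each with one saline and one muscimol session
of interleaved stimulation conditions, and prints the condition design and a
few trials.  The printed counts show the pseudo-random interleaving: within
each session the three stimulation conditions differ by at most one trial.
"""

from fitime import demo_config, simulate_behavior

cfg = demo_config(seed=1)
trials = simulate_behavior(cfg)

print(f"{len(trials)} trials across {trials['session_id'].nunique()} sessions\n")
print("Trials per stimulation condition in one session:")
one = trials[trials["session_id"] == trials["session_id"].iloc[0]]
print(one["stim"].value_counts().to_string(), "\n")

cols = ["trial_index", "drug", "stim", "true_start_s", "reward_time_s"]
print("First trials of that session (true_start_s is the generative start):")
print(one[cols].head(6).round(2).to_string(index=False))
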