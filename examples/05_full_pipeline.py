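"""End-to-end run: simulate, analyze, and write every artifact.

Equivalent to `fitime run --out out/`.  Writes the session bundle
(trials.csv / spikes.csv / units.csv / config.yaml / manifest.json), the
analysis tables (behavior_summary.csv, starts.csv, units_classified.csv,
ramping_fits.csv, peth_matrix.csv, model_report.json) and a human-readable
report whose every number comes from those files.
"""

from fitime import demo_config, run_pipeline

cfg = demo_config(seed=7)
res = run_pipeline(cfg, "out_demo", fr_bin_s=0.5)
print(res["report"])
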