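# fitime

Analyses of fixed-interval (FI) timing behavior and striatal spiking for
experiments that cross a reversible frontal inactivation (saline vs.
muscimol infusion) with optogenetic stimulation of corticostriatal axons
(no stimulation, 2 Hz, 20 Hz), plus a seeded synthetic-data generator so
the entire chain runs — and can be validated by parameter recovery — at
desk scale.

## The science

In a 12-s fixed-interval task, a houselight marks trial onset and the first
lever press after 12 s is rewarded. Two behavioral statistics summarize
temporal control:

* **Curvature of the time-response histogram** — the deviation of the
  cumulative response record R(t) from a straight line, a scalar in
  [−1, 1]. With cumulative counts R_i at the ends of n equal segments of
  [0, T]:

  C = [(n − 1)·R_n − 2·Σ_{i<n} R_i] / (n·R_n)

  C = 0 for a constant response rate; C > 0 when responding concentrates
  late in the interval (the FI "scallop"). The index is invariant to overall
  response rate and to time rescaling. A continuous (ECDF-polygon) variant
  is also provided.

* **Single-trial start times** — per trial, the switch from sparse to
  sustained pressing, found by exhaustive search over candidate breakpoints
  s of D(s) = s·(r − r₁) + (T − s)·(r₂ − r), with r the overall and r₁, r₂
  the before/after response rates.

On the neural side, striatal units are classified as medium spiny neurons
(MSN) or fast-spiking interneurons (FSI) by Gaussian-mixture clustering of
waveform peak-to-trough duration and half-peak width; MSNs firing above
0.1 Hz are analyzed. "Time-related ramping" is the regression slope of a
unit's binned firing rate on time in the interval (ramping: p < 0.05 for
the time term). Condition effects are tested with random-intercept mixed
models,

    RT ~ Stim*Drug + (1|Animal)      FR ~ Time*Stim*Drug + (1|Neuron)

reported as term-wise Wald F statistics with a likelihood-ratio test
against the null model, and with paired t tests / Cohen's d for condition
contrasts. The synthetic generator encodes the expected effect pattern:
muscimol shifts start times earlier and attenuates ramping; 20-Hz
stimulation under muscimol shifts starts later and partially restores
ramping slopes.

## Worked example

```bash
python examples/02_curvature_and_starts.py
```

```
Per-condition means over 6 animals:
                 curvature  mean_start_s
drug     stim
muscimol 20Hz        0.579         8.883
         2Hz         0.548         8.317
         NoStim      0.549         8.318
saline   20Hz        0.550         8.563
         2Hz         0.565         8.673
         NoStim      0.568         8.715
```

Under muscimol without stimulation, start times move ≈0.4 s earlier than
saline (8.32 vs 8.72 s) and curvature drops (0.549 vs 0.568) — weaker
temporal control. With 20-Hz stimulation under muscimol, starts move later
than the unstimulated muscimol trials (8.88 vs 8.32 s) and curvature
recovers (0.579): the stimulation compensates for the inactivation. The
other examples cover the simulator (`01`), unit classification and ramping
(`03`), the mixed models (`04`), and the full pipeline with all artifacts
(`05`).

A thin CLI mirrors the stages:

```bash
fitime simulate --seed 1 --out bundle/
fitime behavior --in bundle/ --out results/
fitime run --seed 1 --out results/        # simulate → analyze → report
```

Bundles are plain CSV/YAML/JSON; `run` writes behavior_summary.csv,
starts.csv, units_classified.csv, ramping_fits.csv, peth_matrix.csv,
model_report.json and a human-readable report assembled from them.

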