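# Methods

`fitime` implements the analysis chain of a rodent fixed-interval (FI)
timing experiment in which pharmacological inactivation of medial frontal
cortex (Drug ∈ {saline, muscimol}) is crossed with optogenetic stimulation
of corticostriatal axon terminals (Stim ∈ {NoStim, 2 Hz, 20 Hz}), together
with a synthetic-data generator that emulates the behavioral and spike-train
structure those analyses assume.

## Task and data model

Trials begin at houselight onset (t = 0 on the trial clock); the first lever
press after the fixed interval T = 12 s is rewarded and ends the trial.
Intertrial intervals are drawn uniformly from {6, 8, 10, 12} s; sessions
last 60 minutes; the three stimulation conditions are pseudo-randomly
interleaved in shuffled blocks so per-session counts differ by at most one
trial. All per-trial analyses use the trial clock and only responses within
[0, T].

## Synthetic generator

**Behavior.** Each trial follows a two-state press process: a low Poisson
press rate `rate_low` before an internally timed start `s`, and `rate_high`
after it. Starts are truncated-normal (lognormal available) with mean
`start_mu[drug, stim]` and standard deviation `start_cv · mean` — the scalar
timing property. Each animal carries a normal(0, `animal_start_sd`) offset
on its start means, shared across its sessions, which the mixed models'
random intercept is meant to absorb. Trials without a press after T end at a
timeout of 2T = 24 s (the protocol does not constrain this case; the choice
only affects session tiling). Defaults: `start_mu` = 8.4 s in all saline
cells, 7.8 / 7.9 / 8.8 s in muscimol NoStim / 2 Hz / 20 Hz (typical
condition means for this preparation), `start_cv` = 0.15, `rate_low` = 0.1 /s, `rate_high` =
2 /s, `animal_start_sd` = 0.3 s.

**Spikes.** Units fire as inhomogeneous Poisson processes with rate
λ(t) = max(0, a + b·t) over the interval and baseline `a` elsewhere, sampled
by thinning (exact). A seeded fraction `frac_ramping` = 0.4 of units ramp,
with per-unit gain g ∈ [0.7, 1.3] and cell-dependent slope
b = g·`ramp_slope[drug, stim]`; defaults a = 3 spikes/s and slopes 0.30
(all saline) vs 0.12 / 0.15 / 0.27 spikes/s² (muscimol NoStim / 2 Hz /
20 Hz): inactivation attenuates ramping, 20-Hz stimulation partially
restores it. Units are assigned round-robin to sessions, so Drug varies
between units (as when units are recorded on separate infusion days).
`simulate_fr_counts` draws binned counts directly from the exact integral of
λ per bin — distributionally identical to binning a thinned train and much
faster for repeated-simulation studies.

**Waveforms.** Mean waveforms are biphasic difference-of-Gaussians templates
at 40 kHz parameterized by the two features used downstream: peak-to-trough
duration and half-peak width, drawn per class (MSN broad: 0.65 ± 0.05 /
0.30 ± 0.04 ms; FSI narrow: 0.25 ± 0.03 / 0.13 ± 0.015 ms; `frac_fsi` =
1/3, reflecting that interneurons are recorded about half as often as
projection cells). Configurations whose class distributions overlap within
two pooled standard deviations are flagged, not rejected.

## Behavioral analyses

**Curvature.** Temporal control is quantified by the deviation of the
cumulative response record from a straight line, a scalar in [−1, 1]: 0 for
a constant rate, positive when responding concentrates late (the FI
"scallop"). Two variants are exposed. `fry_discrete` uses cumulative counts
R_i at the ends of n equal segments:

    C = [(n − 1) R_n − 2 Σ_{i<n} R_i] / (n R_n),   |C| ≤ (n − 1)/n.

`trapezoid_continuous` compares the area under the ECDF polygon (unique
response times with full cumulative counts, so ties stack vertically and
k-fold duplication rescales the record exactly) with T·R_n/2. Both are
invariant to overall response rate and to time rescaling, and share the same
dense-record limit; they differ by O(1/total responses), so agreement to
0.01 requires records of a few hundred responses. The headline summary uses
`fry_discrete` with n = 1000 (the index is binning-resistant and large n
approaches the continuous value); n = 4 is retained for hand-checkable
oracle values. Zero-response records yield a flagged undefined result.

**Start times.** Per trial, the switch from low to high pressing is
estimated by exhaustive search over candidate breakpoints (every response
time plus the endpoints) of

    D(s) = s (r − r₁) + (T − s)(r₂ − r),

with r the overall and r₁, r₂ the before/after rates; ties go to the
earliest maximizer. D is piecewise linear and increasing between response
times, so the candidate set contains the continuous optimum. This is the
two-rate (start-only) special case of the classic three-state single-trial
analysis of peak-interval responding; on a fixed-interval schedule only the
start transition is identified. Because the estimate is itself a response
time, its bias is about one inter-press interval of the high state
(≈ 1/`rate_high`); at a 20-fold rate ratio with `rate_high` = 5/s the
estimator's bias is < 0.25 s and RMSE < 0.5 s. Trials with fewer than 2
responses are excluded and counted.

**Time-response curves.** For display, pooled responses per animal are
kernel-density smoothed (Gaussian, bandwidth 1 s, 0.1-s grid, no boundary
correction), normalized to each animal's maximum, then averaged across
animals; raw binned rates are returned alongside.

## Unit analyses

Features are extracted from the mean waveform with polarity normalization
(principal extremum down), sub-sample interpolation for the half-peak
width, and the peak-to-trough duration measured to the subsequent opposite
extremum. Classification is a 2-component full-covariance Gaussian mixture
on the two features (seeded k-means initializations, order-invariant by
sorting before the fit); the broader-waveform component is labeled MSN.
When BIC prefers one component, all units receive one label chosen by a
0.45-ms peak-to-trough boundary. Headline analyses keep MSNs firing
strictly above 0.1 Hz over the session.

Per-neuron ramping is ordinary least squares of unsmoothed, unnormalized
binned firing rate (counts/bin ÷ width; 100-ms bins by default, 10-ms
available) on bin-center time, pooling all trials of a condition cell; a
unit ramps when the time coefficient has p < 0.05, with no correction
across units. Within a single neuron the mixed model reduces to this
regression, since no random effects exist. All-zero units report slope 0,
p = 1 by convention.

Population PETHs are built for display only: trial-averaged rates in 100-ms
bins, z-scored across bins, then Gaussian-smoothed (0.5-s bandwidth;
z-scoring precedes smoothing, and smoothed matrices never feed
regressions). Rows are sorted by loading on the first principal component,
whose sign is fixed by positive correlation with time so ramping profiles
collect at one edge; zero-variance units are excluded with flagged
placeholder rows.

## Mixed models and tests

Both models are identity-link Gaussian with a single random intercept, fit
by maximum likelihood: `RT ~ Stim*Drug + (1|Animal)` on per-press response
times within [0, T] (default granularity; per-trial reward latency is
available) and `FR ~ Time*Stim*Drug + (1|Neuron)` on binned rates with Time
continuous at bin centers. Per-press RTs exclude the rewarded press: its
timing is fixed by the schedule (the first press after T), and including it
makes every term's test conservative because it forms a condition-
independent stratum in each trial. Terms are reported in a fixed order
(mains, two-way, three-way) with Wald F statistics (joint chi-square over
the term's treatment-coded columns divided by its degrees of freedom,
residual denominator df — the F method is a documented approximation), both
marginal and conditional R² (variance-partition definitions), and a
likelihood-ratio test against the intercept-plus-random-intercept null.
Optimizer failures and boundary collapses of the random-intercept variance
fall back to the nested OLS solution, and a fit is never reported with a
log-likelihood below its own zero-variance boundary. A single grouping
level triggers an explicit OLS fallback with a warning. The default FR bin
for desk-scale model fits is 100 ms (10-ms bins reproduce the design
structurally but multiply the row count tenfold; a flag exposes them).

Paired condition contrasts use the paired t test with Cohen's
d = mean(diff)/sd(diff); zero-variance differences are flagged and reported
as signed infinities rather than raised.

## Calibration and power checks

Matched-null simulations use the generator with the relevant effect removed:
for RT, equal press rates and equal start means (press times then carry no
trial-level clustering, so the model's independence assumptions hold); for
FR, every unit ramps with the same slope in every cell, so all stimulation
contrasts are exactly null while a time effect is present (the per-unit
gain cancels within unit, protecting the interaction terms). Power is
assessed under the default effect sizes at reduced scale: the FR three-way
term at 48 units × 20 trials/cell × 1-s bins, the RT interaction at 6
animals × 60-minute sessions (≈17k presses). Under these conditions the FR three-way power is ≈0.95; the RT
interaction power is ≈0.6, because a 1-s shift of the start distribution
moves the within-interval press-time distribution by only ≈0.3 s (a later
start also shortens the high-rate epoch) — a structural property of the
two-state press model at the configured start means, documented rather than
tuned away.

## What the generator does and does not emulate

It reproduces the schedule, the condition design, scalar-timing start
variability, animal-level heterogeneity, Poisson spiking with linear
ramping, and waveform-class structure. It does not emulate graded response
acceleration (real FI responding is not strictly two-state), post-reward
behavior, stop decisions, within-session drift, bursting or refractory
structure in spike trains, D1/D2 subtypes, or direct pulse-locked
stimulation artifacts. Passing tests therefore validate the estimators and
their calibration under this generative model, not the biological claims of
any particular dataset. The emergent curvature level under the default
rates (≈0.55) is higher than typically reported for rats (≈0.1–0.3);
within a two-state press model, lowering it by raising the baseline rate
reverses the sign of the start→curvature coupling, so the defaults
prioritize the coupling's direction over the absolute level.

## Numerical conventions

Spike bins are half-open [t, t + Δ); a spike at exactly T is outside the
interval. Segment counts use right-closed edges so a press exactly at a
segment boundary belongs to that segment, making the uniform record's
curvature exactly zero in floating point. All randomness derives from a
single root seed split per module and per session/unit via CRC-tagged seed
sequences, so identical configurations are byte-identical across runs and
platforms. Start-detection ties resolve to the earliest maximizer;
curvature of empty records, silent units, and single-animal model fits
degrade to flagged results rather than exceptions.
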