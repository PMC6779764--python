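"""Synthetic fixed-interval sessions: behavior, spike trains, waveforms.

The generator emulates the structure of a rodent fixed-interval (FI) timing
experiment with a drug manipulation crossed with optogenetic stimulation:

* **Behavior** — each trial starts at houselight onset (t = 0 on the trial
  clock).  The animal presses at a low Poisson rate until an internally timed
  *start time* ``s``, then at a high rate; the first press after the fixed
  interval is rewarded and ends the trial.  Start times are drawn per trial
  from a truncated-normal (or lognormal) distribution whose mean depends on
  the (drug, stim) condition and whose standard deviation is proportional to
  the mean (scalar timing).  Stimulation conditions are pseudo-randomly
  interleaved in shuffled blocks so per-session condition counts differ by at
  most one trial.

* **Spikes** — each unit fires as an inhomogeneous Poisson process with rate
  ``λ(t) = max(0, a + b·t)`` over the interval (``b = 0`` for non-ramping
  units; ``b`` depends on the condition cell for ramping units) and at the
  baseline ``a`` outside it.  Sampling uses Poisson thinning, which is exact.

* **Waveforms** — each unit receives a biphasic difference-of-Gaussians mean
  waveform whose peak-to-trough duration and half-peak width are drawn from
  its class distribution (broad = medium spiny neuron, narrow = fast-spiking
  interneuron).

Ground truth (start times, ramping parameters, class labels) is recorded so
downstream estimators can be validated by parameter recovery.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig, cell_key

TRIAL_COLUMNS = [
    "animal_id",
    "session_id",
    "trial_index",
    "drug",
    "stim",
    "onset_s",
    "iti_s",
    "reward_time_s",
    "trial_end_s",
    "true_start_s",
    "response_times",
]


@dataclass
class SpikeUnit:
    """One simulated (or loaded) single unit.

    ``spike_times`` are on the session clock, sorted.  ``truth`` carries
    generator ground truth (class label, ramping flag, per-stim slope) when
    the unit is synthetic; it is empty for loaded units.
    """

    unit_id: str
    session_id: str
    animal_id: str
    drug: str
    spike_times: np.ndarray
    waveform: np.ndarray
    sampling_rate_hz: float
    mean_rate_hz: float
    truth: dict = field(default_factory=dict)


def _spawn(seed: int, *labels: str) -> np.random.Generator:
    """Derive an independent, reproducible stream from the root seed."""
    tag = [zlib.crc32(lbl.encode()) for lbl in labels]  # stable across runs
    return np.random.default_rng(np.random.SeedSequence([seed, *tag]))


def stim_sequence(stim_levels, n_trials: int, rng: np.random.Generator) -> list[str]:
    """Pseudo-random interleaving in shuffled blocks.

    Consuming a prefix of a block-shuffled sequence guarantees per-level
    counts differ by at most one.
    """
    levels = list(stim_levels)
    n_blocks = int(np.ceil(n_trials / len(levels))) + 1
    seq: list[str] = []
    for _ in range(n_blocks):
        block = list(levels)
        rng.shuffle(block)
        seq.extend(block)
    return seq[:n_trials]


def _draw_start(mu: float, cv: float, dist: str, rng: np.random.Generator) -> float:
    if cv == 0:
        return mu
    sd = cv * mu
    if dist == "lognormal":
        sigma2 = np.log1p(cv**2)
        return float(rng.lognormal(np.log(mu) - sigma2 / 2, np.sqrt(sigma2)))
    a = (0.0 - mu) / sd  # truncate at zero
    return float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng))


def _poisson_times(rate: float, t0: float, t1: float, rng: np.random.Generator) -> np.ndarray:
    if t1 <= t0 or rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def simulate_behavior(config: SimConfig) -> pd.DataFrame:
    """Simulate the behavioral trial table for every animal and session.

    Returns a DataFrame with one row per trial (columns ``TRIAL_COLUMNS``);
    ``response_times`` holds the sorted press times on the trial clock and
    ``true_start_s`` the generative start time.  Identical seed and config
    give identical output.
    """
    session_s = config.session_minutes * 60.0
    rows = []
    for ai in range(config.n_animals):
        animal = f"rat{ai:02d}"
        a_rng = _spawn(config.seed, "behavior", animal)
        offset = (
            a_rng.normal(0.0, config.animal_start_sd)
            if config.animal_start_sd > 0
            else 0.0
        )
        for drug in config.drug_levels:
            for si in range(config.n_sessions_per_condition):
                session = f"{animal}_{drug}_s{si}"
                rng = _spawn(config.seed, "behavior", session)
                # generous upper bound on trials, trimmed by session time
                max_n = int(np.ceil(session_s / (min(config.iti_choices) + 1))) + 8
                stims = stim_sequence(config.stim_levels, max_n, rng)
                t, idx = 0.0, 0
                while t < session_s:
                    if config.max_trials is not None and idx >= config.max_trials:
                        break
                    stim = stims[idx]
                    mu_cell = config.start_mu_for(drug, stim)
                    mu = float(np.clip(mu_cell + offset, 0.05, config.interval))
                    start = _draw_start(mu, config.start_cv, config.start_dist, rng)
                    lo = _poisson_times(
                        config.rate_low, 0.0, min(start, config.timeout), rng
                    )
                    hi = _poisson_times(
                        config.rate_high, min(start, config.timeout), config.timeout, rng
                    )
                    presses = np.sort(np.concatenate([lo, hi]))
                    after = presses[presses >= config.interval]
                    if after.size:
                        end = float(after[0])
                        reward = end
                        presses = presses[presses <= end]
                    else:
                        end = config.timeout
                        reward = np.nan
                    iti = float(rng.choice(np.asarray(config.iti_choices, dtype=float)))
                    rows.append(
                        {
                            "animal_id": animal,
                            "session_id": session,
                            "trial_index": idx,
                            "drug": drug,
                            "stim": stim,
                            "onset_s": t,
                            "iti_s": iti,
                            "reward_time_s": reward,
                            "trial_end_s": end,
                            "true_start_s": start,
                            "response_times": presses.tolist(),
                        }
                    )
                    t += end + iti
                    idx += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# waveforms


def waveform_template(
    peak_to_trough_ms: float,
    half_peak_width_ms: float,
    fs_hz: float = 40000.0,
    duration_ms: float = 2.0,
    trough_ms: float = 0.6,
    peak_amp: float = 0.5,
) -> np.ndarray:
    """Biphasic difference-of-Gaussians template.

    A negative Gaussian trough (the principal extremum, FWHM equal to
    ``half_peak_width_ms``) followed by a smaller positive peak at
    ``peak_to_trough_ms`` after the trough.
    """
    t = np.arange(int(round(duration_ms * 1e-3 * fs_hz))) / fs_hz * 1e3  # ms
    s1 = half_peak_width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    s2 = 1.5 * s1
    w = -np.exp(-((t - trough_ms) ** 2) / (2 * s1**2)) + peak_amp * np.exp(
        -((t - trough_ms - peak_to_trough_ms) ** 2) / (2 * s2**2)
    )
    return w


def simulate_waveforms(
    config: SimConfig, n_units: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw class labels and mean waveforms for ``n_units`` units.

    Returns a DataFrame with columns ``true_class``, ``true_peak_to_trough_ms``,
    ``true_half_peak_width_ms``, ``waveform`` (ndarray), and a ``warning``
    string flagging overlapping class distributions (separation below two
    pooled standard deviations on either feature axis).
    """
    if rng is None:
        rng = _spawn(config.seed, "waveforms")
    warn = _overlap_warning(config)
    rows = []
    for i in range(n_units):
        klass = "FSI" if rng.random() < config.frac_fsi else "MSN"
        p = config.waveform_params[klass]
        p2t = _positive_normal(rng, *p["peak_to_trough_ms"])
        hw = _positive_normal(rng, *p["half_peak_width_ms"])
        wf = waveform_template(p2t, hw, config.waveform_fs_hz)
        rows.append(
            {
                "true_class": klass,
                "true_peak_to_trough_ms": p2t,
                "true_half_peak_width_ms": hw,
                "waveform": wf,
                "warning": warn,
            }
        )
    return pd.DataFrame(rows)


def _positive_normal(rng, mean, sd, floor=1e-3):
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > floor:
            return float(x)
    return float(max(mean, floor))


def _overlap_warning(config: SimConfig) -> str:
    msgs = []
    wp = config.waveform_params
    for feat in ("peak_to_trough_ms", "half_peak_width_ms"):
        m1, s1 = wp["MSN"][feat]
        m2, s2 = wp["FSI"][feat]
        pooled = np.sqrt((s1**2 + s2**2) / 2)
        if pooled > 0 and abs(m1 - m2) / pooled < 2:
            msgs.append(f"classes overlap on {feat}")
    return "; ".join(msgs)


# ---------------------------------------------------------------------------
# spikes


def _thinned_inhomogeneous(
    a: float, b: float, t0: float, t1: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact sampling of a Poisson process with rate max(0, a + b·t) on
    [t0, t1) (t on the same clock as a, b) by thinning."""
    lam_max = max(a, a + b * t0, a + b * t1, 0.0)
    if lam_max <= 0 or t1 <= t0:
        return np.empty(0)
    cand = _poisson_times(lam_max, t0, t1, rng)
    if cand.size == 0:
        return cand
    lam = np.maximum(0.0, a + b * cand)
    keep = rng.uniform(0, lam_max, cand.size) < lam
    return cand[keep]


def simulate_spikes(
    config: SimConfig, trials: pd.DataFrame, waveforms: pd.DataFrame | None = None
) -> list[SpikeUnit]:
    """Simulate spike trains for ``config.n_units`` units.

    Units are assigned round-robin to the sessions present in ``trials``.
    Ramping units (a seeded ``frac_ramping`` subset) fire at
    ``λ(t) = max(0, a + g·b[drug, stim]·t)`` over the interval, where ``g`` is
    a per-unit gain in [0.7, 1.3]; all units fire at the baseline ``a``
    outside the interval.  Ground truth is stored in ``SpikeUnit.truth``.
    """
    if trials.empty:
        raise ValueError("trials table is empty")
    sessions = trials["session_id"].unique()
    urng = _spawn(config.seed, "units")
    if waveforms is None:
        waveforms = simulate_waveforms(config, config.n_units, _spawn(config.seed, "waveforms"))
    units: list[SpikeUnit] = []
    for i in range(config.n_units):
        session = sessions[i % len(sessions)]
        st = trials[trials["session_id"] == session]
        animal = st["animal_id"].iloc[0]
        drug = st["drug"].iloc[0]
        is_ramping = bool(urng.random() < config.frac_ramping)
        gain = float(urng.uniform(0.7, 1.3)) if is_ramping else 0.0
        a = config.ramp_intercept
        rng = _spawn(config.seed, "spikes", f"u{i:03d}")
        spikes = []
        duration = 0.0
        for _, tr in st.iterrows():
            onset = tr["onset_s"]
            b = gain * config.ramp_slope_for(drug, tr["stim"]) if is_ramping else 0.0
            t_iv = min(tr["trial_end_s"], config.interval)
            spikes.append(onset + _thinned_inhomogeneous(a, b, 0.0, t_iv, rng))
            # baseline firing from end of interval through the ITI
            spikes.append(
                onset + _poisson_times(a, t_iv, tr["trial_end_s"] + tr["iti_s"], rng)
            )
            duration = max(duration, onset + tr["trial_end_s"] + tr["iti_s"])
        spk = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        truth = {
            "is_ramping": is_ramping,
            "a": a,
            "gain": gain,
            "b_by_stim": {
                s: (gain * config.ramp_slope_for(drug, s) if is_ramping else 0.0)
                for s in config.stim_levels
            },
            "true_class": waveforms["true_class"].iloc[i % len(waveforms)],
        }
        units.append(
            SpikeUnit(
                unit_id=f"unit{i:03d}",
                session_id=session,
                animal_id=animal,
                drug=drug,
                spike_times=spk,
                waveform=np.asarray(waveforms["waveform"].iloc[i % len(waveforms)]),
                sampling_rate_hz=config.waveform_fs_hz,
                mean_rate_hz=float(spk.size / duration) if duration > 0 else 0.0,
                truth=truth,
            )
        )
    return units


# ---------------------------------------------------------------------------
# binned shortcut for model-calibration studies


def simulate_fr_counts(
    config: SimConfig,
    n_units: int,
    trials_per_cell: int,
    bin_s: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw binned firing-rate observations directly.

    Bin counts of an inhomogeneous Poisson process are Poisson with mean
    ``∫λ`` over the bin, so drawing counts from that exact integral is
    distributionally identical to binning a thinned spike train — and much
    faster, which matters for repeated-simulation calibration studies.  Units
    alternate between drug levels (drug varies between units, as when units
    are recorded in separate infusion sessions); each unit contributes
    ``trials_per_cell`` trials per stimulation level.

    Returns a long DataFrame: unit_id, drug, stim, trial, time_s, rate_hz.
    """
    edges = np.arange(0.0, config.interval + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    nb = centers.size
    frames = []
    for i in range(n_units):
        drug = config.drug_levels[i % len(config.drug_levels)]
        is_ramping = rng.random() < config.frac_ramping
        gain = rng.uniform(0.7, 1.3) if is_ramping else 0.0
        a = config.ramp_intercept
        for stim in config.stim_levels:
            b = gain * config.ramp_slope_for(drug, stim) if is_ramping else 0.0
            # exact integral of max(0, a + b t) over each bin (a >= 0 here)
            mean = a * bin_s + b * (edges[1:] ** 2 - edges[:-1] ** 2) / 2
            counts = rng.poisson(np.maximum(mean, 0.0), size=(trials_per_cell, nb))
            frames.append(
                pd.DataFrame(
                    {
                        "unit_id": f"unit{i:03d}",
                        "drug": drug,
                        "stim": stim,
                        "trial": np.repeat(np.arange(trials_per_cell), nb),
                        "time_s": np.tile(centers, trials_per_cell),
                        "rate_hz": counts.ravel() / bin_s,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
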