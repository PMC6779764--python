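"""Behavioral analyses of fixed-interval responding.

Three analyses quantify temporal control of operant responding over the
fixed interval ``[0, T]``:

* :func:`curvature_index` — the deviation of the cumulative response record
  from a straight line, a scalar in [−1, 1].  Zero means a constant response
  rate; positive values mean responding concentrated late in the interval
  (the classic fixed-interval "scallop"); negative values mean early
  responding.  The index is invariant to the overall response rate and to
  time rescaling, which makes it comparable across animals and conditions.

* :func:`detect_start_time` — a single-trial change-point estimate of the
  moment the animal switches from a low to a high response rate, found by
  exhaustive search over candidate breakpoints of a two-rate contrast
  objective.  (A two-state specialization of the classic three-state
  single-trial analysis of peak-interval responding; only the start
  transition is modeled on a fixed-interval schedule.)

* :func:`time_response_histogram` — kernel-density time-response curves,
  normalized to each animal's maximum before cross-animal averaging.

All per-trial times are on the trial clock (t = 0 at houselight onset); only
responses within ``[0, T]`` enter the curvature and start-time analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_N_SEGMENTS = 1000


@dataclass
class CurvatureResult:
    """Curvature of a cumulative response record."""

    value: float
    n_segments: int
    method: str
    total_responses: int
    defined: bool = True


@dataclass
class StartTimeResult:
    """Single-trial start-time estimate."""

    start: float
    objective: float
    n_responses: int
    valid: bool
    trial_index: int = -1


def _clean_times(times, T: float) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.size and (t.min() < 0 or t.max() > T):
        raise ValueError("response times must lie within [0, T]")
    return np.sort(t)


def curvature_index(
    times,
    T: float,
    n_segments: int = DEFAULT_N_SEGMENTS,
    method: str = "fry_discrete",
) -> CurvatureResult:
    """Curvature of the cumulative response record over ``[0, T]``.

    ``fry_discrete`` partitions the interval into ``n_segments`` equal
    segments with cumulative counts ``R_i`` at segment ends and evaluates::

        C = [(n - 1) R_n - 2 * sum_{i<n} R_i] / (n * R_n)

    bounded by ±(n − 1)/n.  ``trapezoid_continuous`` compares the area under
    the linearly interpolated cumulative record with the straight line from
    (0, 0) to (T, R_n)::

        C = (A_line - A_record) / A_line,  A_line = T * R_n / 2

    bounded by ±1 (strictly, for responses inside the interval).  Both are 0
    for a perfectly constant response rate and agree as ``n_segments`` grows.

    Zero responses give a flagged undefined result (value NaN) rather than an
    error, so empty condition cells propagate as missing values.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be at least 2")
    if T <= 0:
        raise ValueError("interval T must be positive")
    t = _clean_times(times, T)
    m = t.size
    if m == 0:
        return CurvatureResult(np.nan, n_segments, method, 0, defined=False)
    if method == "fry_discrete":
        edges = np.arange(1, n_segments + 1) * (T / n_segments)
        R = np.searchsorted(t, edges, side="right")
        value = ((n_segments - 1) * m - 2 * int(R[:-1].sum())) / (n_segments * m)
    elif method == "trapezoid_continuous":
        # ECDF polygon through the unique times with full cumulative counts:
        # ties stack vertically, so k-fold duplication rescales the record
        # exactly and the index is rate-invariant.
        xu, counts = np.unique(t, return_counts=True)
        x = np.concatenate([[0.0], xu, [T]])
        y = np.concatenate([[0.0], np.cumsum(counts), [m]])
        a_record = np.trapezoid(y, x)
        a_line = T * m / 2.0
        value = (a_line - a_record) / a_line
    else:
        raise ValueError(f"unknown curvature method {method!r}")
    return CurvatureResult(float(value), n_segments, method, m)


def detect_start_time(
    responses, T: float, r_min: int = 2, trial_index: int = -1
) -> StartTimeResult:
    """Single-trial start time by exhaustive two-rate change-point search.

    For each candidate breakpoint ``s`` (every response time plus the
    endpoints 0 and T) the objective is::

        D(s) = s * (r - r1) + (T - s) * (r2 - r)

    where ``r`` is the overall response rate and ``r1``, ``r2`` the rates
    before and after ``s``.  ``D`` is largest where the low→high transition
    best explains the record; ties are broken in favor of the earliest
    maximizing ``s``.  Trials with fewer than ``r_min`` responses are marked
    invalid and excluded from start-time summaries.
    """
    t = _clean_times(responses, T)
    m = t.size
    if m < r_min:
        return StartTimeResult(np.nan, np.nan, m, False, trial_index)
    cand = np.unique(np.concatenate([[0.0, T], t]))
    r = m / T
    n_before = np.searchsorted(t, cand, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(cand > 0, n_before / cand, 0.0)
        r2 = np.where(cand < T, (m - n_before) / (T - cand), 0.0)
    D = cand * (r - r1) + (T - cand) * (r2 - r)
    best = int(np.argmax(D))  # argmax returns the first (earliest) maximizer
    return StartTimeResult(float(cand[best]), float(D[best]), m, True, trial_index)


def interval_responses(trial: pd.Series, T: float) -> np.ndarray:
    """Responses of one trial restricted to the fixed interval [0, T]."""
    t = np.asarray(trial["response_times"], dtype=float)
    return t[(t >= 0) & (t <= T)]


def time_response_histogram(
    trials: pd.DataFrame,
    T: float = 12.0,
    bandwidth: float = 1.0,
    bin_s: float = 0.1,
) -> dict:
    """Kernel-density time-response curves, normalized per animal.

    Pools every response in ``[0, T]`` per animal, evaluates a Gaussian
    kernel density (bandwidth in seconds) on a regular grid, scales each
    animal's curve to peak at 1, then averages across animals.  Also returns
    the raw binned response rates in presses/s.

    Returns a dict with ``grid`` (bin centers), ``normalized`` (animal ×
    grid DataFrame), ``average`` (mean normalized curve), ``raw_rate``
    (animal × grid DataFrame, presses/s) and ``empty`` (list of animals with
    no responses, returned with all-NaN rows rather than dividing by zero).
    """
    grid = np.arange(bin_s / 2, T, bin_s)
    edges = np.arange(0.0, T + bin_s / 2, bin_s)
    normalized, raw, empty = {}, {}, []
    for animal, sub in trials.groupby("animal_id", sort=True):
        pooled = np.concatenate(
            [interval_responses(tr, T) for _, tr in sub.iterrows()]
        ) if len(sub) else np.empty(0)
        counts, _ = np.histogram(pooled, bins=edges)
        raw[animal] = counts / (len(sub) * bin_s) if len(sub) else counts * np.nan
        if pooled.size == 0:
            empty.append(animal)
            normalized[animal] = np.full(grid.size, np.nan)
            continue
        # fixed-bandwidth Gaussian KDE on the grid
        z = (grid[:, None] - pooled[None, :]) / bandwidth
        dens = np.exp(-0.5 * z**2).sum(axis=1)
        peak = dens.max()
        normalized[animal] = dens / peak if peak > 0 else dens
    norm_df = pd.DataFrame(normalized, index=grid).T
    raw_df = pd.DataFrame(raw, index=grid).T
    return {
        "grid": grid,
        "normalized": norm_df,
        "average": norm_df.mean(axis=0, skipna=True),
        "raw_rate": raw_df,
        "empty": empty,
    }


def detect_start_times(trials: pd.DataFrame, T: float = 12.0, r_min: int = 2) -> pd.DataFrame:
    """Per-trial start-time table for a trial table.

    Returns one row per trial: identifiers, condition labels, the start
    estimate, validity flag and (when present) the generative true start.
    """
    rows = []
    for _, tr in trials.iterrows():
        res = detect_start_time(
            interval_responses(tr, T), T, r_min=r_min, trial_index=tr["trial_index"]
        )
        rows.append(
            {
                "animal_id": tr["animal_id"],
                "session_id": tr["session_id"],
                "trial_index": tr["trial_index"],
                "drug": tr["drug"],
                "stim": tr["stim"],
                "start_s": res.start,
                "objective": res.objective,
                "n_responses": res.n_responses,
                "valid": res.valid,
                "true_start_s": tr.get("true_start_s", np.nan),
            }
        )
    return pd.DataFrame(rows)


def session_behavior_summary(
    trials: pd.DataFrame,
    T: float = 12.0,
    n_segments: int = DEFAULT_N_SEGMENTS,
    method: str = "fry_discrete",
    r_min: int = 2,
) -> pd.DataFrame:
    """Tidy per-(animal, drug, stim) summary of behavior.

    Curvature is computed on the pooled in-interval responses of each
    condition cell; start times are averaged over valid trials.  Empty cells
    yield rows of missing values rather than errors.
    """
    starts = detect_start_times(trials, T, r_min=r_min)
    rows = []
    for (animal, drug, stim), sub in trials.groupby(
        ["animal_id", "drug", "stim"], sort=True
    ):
        pooled = (
            np.concatenate([interval_responses(tr, T) for _, tr in sub.iterrows()])
            if len(sub)
            else np.empty(0)
        )
        curv = curvature_index(pooled, T, n_segments=n_segments, method=method)
        s = starts[
            (starts["animal_id"] == animal)
            & (starts["drug"] == drug)
            & (starts["stim"] == stim)
        ]
        valid = s[s["valid"]]
        rows.append(
            {
                "animal_id": animal,
                "drug": drug,
                "stim": stim,
                "n_trials": len(sub),
                "n_responses": int(pooled.size),
                "curvature": curv.value if curv.defined else np.nan,
                "mean_start_s": valid["start_s"].mean() if len(valid) else np.nan,
                "n_start_trials": len(valid),
                "n_start_excluded": len(s) - len(valid),
            }
        )
    return pd.DataFrame(rows)
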