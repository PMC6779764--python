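"""Striatal unit analyses: classification, binning, ramping, PETHs.

Putative units are classified as medium spiny neurons (MSNs, broad
waveforms) or fast-spiking interneurons (FSIs, narrow waveforms) by Gaussian
mixture clustering of two waveform features: peak-to-trough duration and
half-peak width.  Headline analyses keep MSNs firing above 0.1 Hz.

Per-neuron "time-related ramping" is an ordinary least-squares regression of
unsmoothed, unnormalized binned firing rate on time in the interval; a unit
ramps when the time coefficient has p < 0.05.  Peri-event time histograms
(PETHs) are built for display: 100-ms bins, z-scored across bins, Gaussian
smoothed, and sorted by the loading on the first principal component with
its sign fixed so positive loadings are increasing-in-time profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .synthgen import SpikeUnit


@dataclass
class UnitFeatures:
    unit_id: str
    peak_to_trough_ms: float
    half_peak_width_ms: float
    klass: str | None = None
    posterior: float = np.nan


@dataclass
class RampingFit:
    """Per-unit, per-condition-cell regression of firing rate on time."""

    unit_id: str
    drug: str
    stim: str
    slope: float  # spikes/s per s
    intercept: float  # spikes/s
    p_time: float
    is_ramping: bool
    n_obs: int


class WaveformError(ValueError):
    pass


# ---------------------------------------------------------------------------
# waveform features


def extract_features(
    waveform: np.ndarray, fs_hz: float, unit_id: str = ""
) -> UnitFeatures:
    """Peak-to-trough duration and half-peak width of a mean waveform.

    The principal extremum is the sample of largest magnitude (polarity is
    normalized so it points down); the peak-to-trough duration runs from it
    to the subsequent opposite extremum, and the half-peak width is the width
    of the principal lobe at half its amplitude, with sub-sample linear
    interpolation at the crossings.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 3 or np.ptp(w) == 0:
        raise WaveformError("flat or degenerate waveform")
    if abs(w.max()) > abs(w.min()):
        w = -w  # normalize polarity: principal extremum negative
    ti = int(np.argmin(w))
    if ti >= w.size - 1:
        raise WaveformError("principal extremum at waveform edge")
    pi = ti + int(np.argmax(w[ti:]))
    if pi == ti:
        raise WaveformError("no opposite extremum after the trough")
    dt_ms = 1e3 / fs_hz
    p2t = (pi - ti) * dt_ms
    half = w[ti] / 2.0  # negative threshold
    left = _cross_down(w, ti, half, direction=-1)
    right = _cross_down(w, ti, half, direction=+1)
    hw = (right - left) * dt_ms
    if not (p2t > 0 and hw > 0):
        raise WaveformError("non-positive waveform features")
    return UnitFeatures(unit_id, float(p2t), float(hw))


def _cross_down(w: np.ndarray, ti: int, thresh: float, direction: int) -> float:
    """Fractional index where w crosses ``thresh`` moving out from the trough."""
    i = ti
    while 0 < i < w.size - 1:
        j = i + direction
        if w[j] > thresh:  # crossed back above the (negative) half level
            frac = (thresh - w[i]) / (w[j] - w[i])
            return i + direction * frac
        i = j
    return float(i)


# ---------------------------------------------------------------------------
# classification


def classify_units(
    features: list[UnitFeatures] | pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Two-class Gaussian mixture on (peak-to-trough, half-width).

    Fits full-covariance mixtures with a fixed number of seeded k-means
    initializations, so the result is deterministic given ``seed`` and
    invariant to input order.  The component with the larger mean
    peak-to-trough duration is labeled MSN.  When the Bayesian information
    criterion prefers a single component (all units from one class), every
    unit gets the same label, chosen by comparing the pooled mean
    peak-to-trough duration with a 0.45-ms broad/narrow boundary.

    Returns a DataFrame: unit_id, peak_to_trough_ms, half_peak_width_ms,
    klass, posterior (posterior of the assigned class, ≥ 0.5).
    """
    if isinstance(features, pd.DataFrame):
        df = features.copy()
    else:
        df = pd.DataFrame([vars(f) for f in features])
    if len(df) < 2:
        raise ValueError("need at least 2 units to classify")
    X = df[["peak_to_trough_ms", "half_peak_width_ms"]].to_numpy()
    order = np.lexsort((X[:, 1], X[:, 0]))  # order-invariant fit
    Xs = X[order]

    def _fit(k, cov):
        return GaussianMixture(
            n_components=k,
            covariance_type=cov,
            n_init=10,
            random_state=seed,
            reg_covar=1e-6,
        ).fit(Xs)

    try:
        gm2 = _fit(2, "full")
    except Exception:
        gm2 = _fit(2, "diag")  # degenerate covariance fallback
    gm1 = _fit(1, "full")
    if gm1.bic(Xs) <= gm2.bic(Xs):
        klass = "MSN" if X[:, 0].mean() >= 0.45 else "FSI"
        df["klass"] = klass
        df["posterior"] = 1.0
        return df
    msn_comp = int(np.argmax(gm2.means_[:, 0]))
    post = gm2.predict_proba(X)
    assigned = np.argmax(post, axis=1)
    df["klass"] = np.where(assigned == msn_comp, "MSN", "FSI")
    df["posterior"] = post[np.arange(len(df)), assigned]
    return df


def filter_units(
    units: list[SpikeUnit],
    classified: pd.DataFrame,
    min_rate_hz: float = 0.1,
    klass: str = "MSN",
) -> tuple[list[SpikeUnit], dict]:
    """Keep units of the requested class firing strictly above ``min_rate_hz``.

    Returns the kept units and a report of counts removed per criterion.
    """
    klass_of = dict(zip(classified["unit_id"], classified["klass"]))
    kept, slow, wrong = [], 0, 0
    for u in units:
        if not u.mean_rate_hz > min_rate_hz:
            slow += 1
            continue
        if klass is not None and klass_of.get(u.unit_id) != klass:
            wrong += 1
            continue
        kept.append(u)
    report = {
        "n_input": len(units),
        "n_kept": len(kept),
        "n_below_rate": slow,
        "n_other_class": wrong,
        "min_rate_hz": min_rate_hz,
        "klass": klass,
    }
    return kept, report


# ---------------------------------------------------------------------------
# binning and ramping


def bin_firing(
    unit: SpikeUnit,
    trials: pd.DataFrame,
    bin_s: float = 0.01,
    interval: float = 12.0,
) -> np.ndarray:
    """Trial × bin spike-count matrix over [0, interval).

    Bins are half-open ``[t, t + bin)`` on the trial clock, so a spike at
    exactly the interval boundary is excluded.
    """
    onsets = trials["onset_s"].to_numpy(dtype=float)
    spikes = np.asarray(unit.spike_times, dtype=float)
    if spikes.size and trials.shape[0]:
        span_end = (trials["onset_s"] + trials["trial_end_s"] + trials["iti_s"]).max()
        overlaps = (spikes >= onsets.min()) & (spikes < span_end + interval)
        if spikes.min() < 0 or not overlaps.any():
            raise ValueError(
                "spike times fall outside the session span; "
                "spike and trial clocks appear misaligned"
            )
    nb = int(round(interval / bin_s))
    edges = np.arange(nb + 1) * bin_s
    mat = np.empty((len(onsets), nb), dtype=np.int64)
    for i, onset in enumerate(onsets):
        rel = spikes[(spikes >= onset) & (spikes < onset + interval)] - onset
        mat[i], _ = np.histogram(rel, bins=edges)
    return mat


def fit_ramping(
    unit: SpikeUnit,
    trials: pd.DataFrame,
    drug: str | None = None,
    stim: str | None = None,
    bin_s: float = 0.1,
    interval: float = 12.0,
    alpha: float = 0.05,
) -> RampingFit:
    """OLS regression of binned firing rate on time within the interval.

    Rates (counts/bin ÷ bin width, unsmoothed and unnormalized) from every
    trial of the selected condition cell are pooled and regressed on bin-
    center time.  ``is_ramping`` is true when the time coefficient has
    p < ``alpha``; no multiple-comparison correction is applied across units.
    All-zero firing yields slope 0 with p = 1 by convention.
    """
    sel = trials
    if drug is not None:
        sel = sel[sel["drug"] == drug]
    if stim is not None:
        sel = sel[sel["stim"] == stim]
    if len(sel) < 2:
        raise ValueError("need at least 2 trials in the condition cell")
    counts = bin_firing(unit, sel, bin_s=bin_s, interval=interval)
    rates = counts / bin_s
    centers = (np.arange(counts.shape[1]) + 0.5) * bin_s
    y = rates.ravel()
    x = np.tile(centers, counts.shape[0])
    if not np.any(y):
        return RampingFit(
            unit.unit_id, drug or "*", stim or "*", 0.0, 0.0, 1.0, False, y.size
        )
    fit = sps.linregress(x, y)
    p = float(fit.pvalue)
    return RampingFit(
        unit.unit_id,
        drug or "*",
        stim or "*",
        float(fit.slope),
        float(fit.intercept),
        p,
        bool(p < alpha),
        int(y.size),
    )


def ramping_table(
    units: list[SpikeUnit],
    trials: pd.DataFrame,
    bin_s: float = 0.1,
    interval: float = 12.0,
    by_stim: bool = True,
) -> pd.DataFrame:
    """Ramping fits for every unit, optionally per stimulation condition.

    Each unit is fit within its own session (hence its own drug level).
    """
    rows = []
    for u in units:
        st = trials[trials["session_id"] == u.session_id]
        stims = sorted(st["stim"].unique()) if by_stim else [None]
        for stim in stims:
            try:
                fit = fit_ramping(
                    u, st, drug=u.drug, stim=stim, bin_s=bin_s, interval=interval
                )
            except ValueError:
                continue
            rows.append(
                {
                    "unit_id": u.unit_id,
                    "session_id": u.session_id,
                    "animal_id": u.animal_id,
                    "drug": u.drug,
                    "stim": fit.stim,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "p_time": fit.p_time,
                    "is_ramping": fit.is_ramping,
                    "n_obs": fit.n_obs,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PETH


def build_peth(
    units: list[SpikeUnit],
    trials: pd.DataFrame,
    bin_s: float = 0.1,
    bandwidth_s: float = 0.5,
    interval: float = 12.0,
) -> dict:
    """Population PETH matrix: z-scored, smoothed, PC1-sorted.

    Per unit: trial-averaged firing rate in 100-ms bins over the interval,
    z-scored across bins, then Gaussian-smoothed (display only).  Rows are
    sorted by loading on the first principal component, whose sign is fixed
    so that positive loadings correspond to increasing-in-time (ramping)
    profiles.  Zero-variance units are excluded from z-scoring and appended
    as flagged all-zero placeholder rows at the bottom of the sort.

    Returns dict with ``matrix`` (sorted DataFrame, units × bin centers),
    ``order`` (unit ids, sorted), ``loadings``, ``explained_var_ratio`` and
    ``excluded`` (zero-variance unit ids).
    """
    if len(units) < 2:
        raise ValueError("need at least 2 units for a population PETH")
    centers = (np.arange(int(round(interval / bin_s))) + 0.5) * bin_s
    rows, ids, excluded = [], [], []
    for u in units:
        st = trials[trials["session_id"] == u.session_id]
        mean_rate = bin_firing(u, st, bin_s=bin_s, interval=interval).mean(axis=0) / bin_s
        sd = mean_rate.std()
        if sd == 0:
            excluded.append(u.unit_id)
            continue
        z = (mean_rate - mean_rate.mean()) / sd
        rows.append(gaussian_filter1d(z, sigma=bandwidth_s / bin_s))
        ids.append(u.unit_id)
    if len(rows) < 2:
        raise ValueError("fewer than 2 units with non-degenerate firing")
    M = np.vstack(rows)
    pca = PCA(n_components=min(5, M.shape[0], M.shape[1]), svd_solver="full")
    load = pca.fit_transform(M)[:, 0]
    comp = pca.components_[0]
    if np.corrcoef(comp, centers)[0, 1] < 0:  # sign: positive = ramping up
        comp, load = -comp, -load
    order = np.argsort(-load, kind="stable")
    mat = pd.DataFrame(M[order], index=[ids[i] for i in order], columns=centers)
    for uid in excluded:  # placeholder rows, flagged via `excluded`
        mat.loc[uid] = 0.0
    return {
        "matrix": mat,
        "order": list(mat.index),
        "loadings": pd.Series(load, index=ids).iloc[order].reindex(mat.index),
        "explained_var_ratio": float(pca.explained_variance_ratio_[0]),
        "excluded": excluded,
    }
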