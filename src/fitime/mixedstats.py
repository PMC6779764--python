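"""Mixed-effects models of trial-level behavior and binned firing.

Two linear mixed models (identity-link Gaussian, random intercept) summarize
the condition design:

* response times:  ``RT ~ Stim * Drug + (1 | Animal)``
* firing rate:     ``FR ~ Time * Stim * Drug + (1 | Neuron)``

Fixed-effect terms are reported in a fixed order (main effects, two-way,
three-way) with Wald F statistics (joint chi-square over the term's columns
divided by its degrees of freedom, residual denominator df), marginal and
conditional R², and a likelihood-ratio test against the null model
(intercept plus random intercept), all fit by maximum likelihood.

:func:`paired_comparison` provides the paired t test with Cohen's d on the
paired differences used for condition contrasts of curvature, start times
and ramping slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class TermTest:
    name: str
    fstat: float
    df_num: int
    df_den: int
    pvalue: float


@dataclass
class MixedModelReport:
    formula: str
    terms: list[TermTest]
    n_observations: int
    n_groups: int
    r2_marginal: float
    r2_conditional: float
    loglik: float
    lr_vs_null: float
    lr_df: int
    lr_pvalue: float
    fallback_ols: bool = False
    coefficients: pd.Series = field(default_factory=pd.Series, repr=False)

    def term_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.name,
                    "F": t.fstat,
                    "df_num": t.df_num,
                    "df_den": t.df_den,
                    "p": t.pvalue,
                }
                for t in self.terms
            ]
        )

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "n_observations": self.n_observations,
            "n_groups": self.n_groups,
            "R2_marginal": self.r2_marginal,
            "R2_conditional": self.r2_conditional,
            "terms": [
                {"term": t.name, "F": t.fstat, "df_num": t.df_num, "p": t.pvalue}
                for t in self.terms
            ],
            "vs_null": {"LR": self.lr_vs_null, "df": self.lr_df, "p": self.lr_pvalue},
            "fallback_ols": self.fallback_ols,
        }


@dataclass
class EffectSizeReport:
    label: str
    t: float
    df: int
    pvalue: float
    cohens_d: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    zero_variance: bool = False


# ---------------------------------------------------------------------------
# design-matrix construction (treatment coding, explicit term slices)


def _treatment_dummies(s: pd.Series, levels: list[str]) -> tuple[np.ndarray, list[str]]:
    ref, others = levels[0], levels[1:]
    cols = [(s == lv).to_numpy(dtype=float) for lv in others]
    names = [f"{s.name}[{lv}]" for lv in others]
    return (np.column_stack(cols) if cols else np.empty((len(s), 0))), names


def _build_design(
    df: pd.DataFrame, factors: list[tuple[str, list[str] | None]]
) -> tuple[np.ndarray, list[str], dict[str, slice]]:
    """Full-factorial design matrix with intercept.

    ``factors`` is a list of (column, levels) pairs; ``levels=None`` marks a
    continuous covariate.  Interaction terms are products of the component
    columns.  Returns (X, column names, term → column-slice map) with terms
    ordered mains first, then two-way, then three-way.
    """
    base: dict[str, tuple[np.ndarray, list[str]]] = {}
    for col, levels in factors:
        if levels is None:
            base[col] = (df[col].to_numpy(dtype=float)[:, None], [col])
        else:
            base[col] = _treatment_dummies(df[col], list(levels))
    names = ["Intercept"]
    blocks = [np.ones((len(df), 1))]
    term_slices: dict[str, slice] = {}
    order = [f[0] for f in factors]
    combos: list[tuple[str, ...]] = [(f,) for f in order]
    for size in (2, 3):
        combos += [
            c
            for c in _combinations(order, size)
        ]
    pos = 1
    for combo in combos:
        mats = [base[f][0] for f in combo]
        nm = [base[f][1] for f in combo]
        cols, cnames = _interact(mats, nm)
        if cols.shape[1] == 0:
            continue
        term = ":".join(combo)
        term_slices[term] = slice(pos, pos + cols.shape[1])
        pos += cols.shape[1]
        blocks.append(cols)
        names += cnames
    return np.hstack(blocks), names, term_slices


def _combinations(items, r):
    from itertools import combinations

    return list(combinations(items, r))


def _interact(mats, names):
    cols, cnames = mats[0], list(names[0])
    for m, nm in zip(mats[1:], names[1:]):
        new_cols, new_names = [], []
        for i in range(cols.shape[1]):
            for j in range(m.shape[1]):
                new_cols.append(cols[:, i] * m[:, j])
                new_names.append(f"{cnames[i]}:{nm[j]}")
        cols = np.column_stack(new_cols) if new_cols else np.empty((mats[0].shape[0], 0))
        cnames = new_names
    return cols, cnames


# ---------------------------------------------------------------------------
# core fitting


def _safe_mixedlm(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Fit a random-intercept MixedLM by ML, retrying optimizers.

    Returns ``(llf, fe_params, cov_fe, sigma_re, sigma_e, ok)``.  When the
    random-intercept variance collapses to the boundary the Hessian can be
    singular; in that case the model coincides with OLS (variance 0), which
    is used as the boundary fallback.
    """
    k = X.shape[1]
    ols = sm.OLS(y, X).fit()
    best = (
        float(ols.llf),
        np.asarray(ols.params),
        np.asarray(ols.cov_params()),
        0.0,
        float(ols.scale),
        False,
    )
    for method in (None, "powell", "cg"):
        try:
            res = sm.MixedLM(y, X, groups=groups).fit(reml=False, method=method)
            out = (
                float(res.llf),
                np.asarray(res.fe_params),
                np.asarray(res.cov_params())[:k, :k],
                float(np.asarray(res.cov_re)[0, 0]),
                float(res.scale),
                True,
            )
            if (
                np.isfinite(out[0])
                and np.all(np.isfinite(out[1]))
                and out[0] > best[0]
            ):
                best = out
            if best[5]:  # a mixed fit beat the boundary; stop retrying
                break
        except (np.linalg.LinAlgError, ValueError):
            continue
    return best


def _fit_mixed(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    term_slices: dict[str, slice],
    groups: np.ndarray,
    formula: str,
) -> MixedModelReport:
    n, k = X.shape
    n_groups = len(np.unique(groups))
    fallback = n_groups < 2
    if fallback:
        warnings.warn(
            "single grouping level: random intercept is degenerate; "
            "falling back to a fixed-effects (OLS) model",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fallback:
            res = sm.OLS(y, X).fit()
            beta = res.params
            covb = res.cov_params()
            sig_re, sig_e = 0.0, float(res.scale)
            llf = float(res.llf)
            null = sm.OLS(y, np.ones((n, 1))).fit()
            llf_null = float(null.llf)
        else:
            llf, beta, covb, sig_re, sig_e, _ = _safe_mixedlm(y, X, groups)
            llf_null = _safe_mixedlm(y, np.ones((n, 1)), groups)[0]
    ddf = n - k
    terms = []
    for name, sl in term_slices.items():
        b = beta[sl]
        V = covb[sl, sl]
        q = b.size
        try:
            stat = float(b @ np.linalg.solve(V, b)) / q
        except np.linalg.LinAlgError:
            stat = np.nan
        terms.append(
            TermTest(name, stat, q, ddf, float(sps.f.sf(stat, q, ddf)))
        )
    lr = max(0.0, 2.0 * (llf - llf_null))
    lr_df = k - 1
    var_fix = float(np.var(X @ beta))
    denom = var_fix + sig_re + sig_e
    report = MixedModelReport(
        formula=formula,
        terms=terms,
        n_observations=n,
        n_groups=n_groups,
        r2_marginal=var_fix / denom if denom > 0 else np.nan,
        r2_conditional=(var_fix + sig_re) / denom if denom > 0 else np.nan,
        loglik=llf,
        lr_vs_null=lr,
        lr_df=lr_df,
        lr_pvalue=float(sps.chi2.sf(lr, lr_df)),
        fallback_ols=fallback,
        coefficients=pd.Series(beta, index=names),
    )
    return report


# ---------------------------------------------------------------------------
# public model fits


def rt_table(
    trials: pd.DataFrame, granularity: str = "per_press", interval: float = 12.0
) -> pd.DataFrame:
    """Long response-time table.

    ``per_press``: one row per lever press within the fixed interval
    ``[0, interval]`` (press time on the trial clock); presses after the
    interval are excluded, like in the curvature and start-time analyses —
    the rewarded press is determined by the schedule, not the animal's
    timing.  ``per_trial``: one row per rewarded trial, the latency of the
    first press after the interval.
    """
    rows = []
    for _, tr in trials.iterrows():
        if granularity == "per_press":
            for t in tr["response_times"]:
                if t > interval:
                    continue
                rows.append(
                    {
                        "animal_id": tr["animal_id"],
                        "drug": tr["drug"],
                        "stim": tr["stim"],
                        "rt": float(t),
                    }
                )
        elif granularity == "per_trial":
            if np.isfinite(tr["reward_time_s"]):
                rows.append(
                    {
                        "animal_id": tr["animal_id"],
                        "drug": tr["drug"],
                        "stim": tr["stim"],
                        "rt": float(tr["reward_time_s"]),
                    }
                )
        else:
            raise ValueError(f"unknown granularity {granularity!r}")
    return pd.DataFrame(rows)


def fit_rt_model(
    trials: pd.DataFrame,
    granularity: str = "per_press",
    stim_levels: list[str] = ("NoStim", "2Hz", "20Hz"),
    drug_levels: list[str] = ("saline", "muscimol"),
    interval: float = 12.0,
) -> MixedModelReport:
    """``RT ~ Stim * Drug + (1 | Animal)``.

    Terms are reported in the order Stim, Drug, Stim:Drug, followed by the
    likelihood-ratio comparison against the intercept-plus-random-intercept
    null.  With a single animal the random intercept is degenerate and the
    fit falls back to OLS with a warning.
    """
    df = rt_table(trials, granularity, interval=interval)
    if df.empty:
        raise ValueError("no response-time observations")
    df = df.rename(columns={"stim": "Stim", "drug": "Drug"})
    X, names, slices = _build_design(
        df, [("Stim", list(stim_levels)), ("Drug", list(drug_levels))]
    )
    return _fit_mixed(
        df["rt"].to_numpy(),
        X,
        names,
        slices,
        df["animal_id"].to_numpy(),
        "RT ~ Stim * Drug + (1 | Animal)",
    )


def fit_fr_model(
    fr: pd.DataFrame,
    stim_levels: list[str] = ("NoStim", "2Hz", "20Hz"),
    drug_levels: list[str] = ("saline", "muscimol"),
) -> MixedModelReport:
    """``FR ~ Time * Stim * Drug + (1 | Neuron)``.

    ``fr`` is a long table with columns unit_id, drug, stim, time_s, rate_hz
    (one row per trial × time bin; see :func:`fr_table`).  Time enters as a
    continuous covariate (bin centers in seconds).  Terms are ordered Times,
    Stim, Drug, Times:Stim, Times:Drug, Stim:Drug, Times:Stim:Drug.
    """
    df = fr.rename(
        columns={"time_s": "Times", "stim": "Stim", "drug": "Drug", "rate_hz": "fr"}
    )
    X, names, slices = _build_design(
        df,
        [("Times", None), ("Stim", list(stim_levels)), ("Drug", list(drug_levels))],
    )
    return _fit_mixed(
        df["fr"].to_numpy(),
        X,
        names,
        slices,
        df["unit_id"].to_numpy(),
        "FR ~ Time * Stim * Drug + (1 | Neuron)",
    )


def fr_table(
    units,
    trials: pd.DataFrame,
    bin_s: float = 0.1,
    interval: float = 12.0,
) -> pd.DataFrame:
    """Long firing-rate table (unit × trial × bin) for :func:`fit_fr_model`."""
    from .ephys import bin_firing

    centers = (np.arange(int(round(interval / bin_s))) + 0.5) * bin_s
    frames = []
    for u in units:
        st = trials[trials["session_id"] == u.session_id].reset_index(drop=True)
        if st.empty:
            continue
        counts = bin_firing(u, st, bin_s=bin_s, interval=interval)
        nt, nb = counts.shape
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": u.unit_id,
                    "drug": np.repeat(st["drug"].to_numpy(), nb),
                    "stim": np.repeat(st["stim"].to_numpy(), nb),
                    "trial": np.repeat(st["trial_index"].to_numpy(), nb),
                    "time_s": np.tile(centers, nt),
                    "rate_hz": counts.ravel() / bin_s,
                }
            )
        )
    if not frames:
        raise ValueError("no firing-rate observations")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# paired comparisons


def paired_comparison(values_a, values_b, label: str = "") -> EffectSizeReport:
    """Paired t test with Cohen's d on the paired differences.

    ``d = mean(diff) / sd(diff)``.  Zero-variance differences are flagged and
    reported as a signed infinite t (d likewise), rather than raising.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    diff = a - b
    n = a.size
    sd = diff.std(ddof=1)
    sem = lambda x: x.std(ddof=1) / np.sqrt(n)  # noqa: E731
    if sd == 0:
        sign = float(np.sign(diff.mean()))
        t = sign * np.inf if diff.mean() != 0 else 0.0
        return EffectSizeReport(
            label, t, n - 1, 1.0 if t == 0 else 0.0, sign * np.inf if t != 0 else 0.0,
            float(a.mean()), float(sem(a)), float(b.mean()), float(sem(b)),
            zero_variance=True,
        )
    t, p = sps.ttest_rel(a, b)
    return EffectSizeReport(
        label,
        float(t),
        n - 1,
        float(p),
        float(diff.mean() / sd),
        float(a.mean()),
        float(sem(a)),
        float(b.mean()),
        float(sem(b)),
    )
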