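"""Session-bundle formats and the end-to-end pipeline.

A *session bundle* is a directory of plain-text files:

* ``trials.csv``  — one row per trial; press times are semicolon-joined
  seconds in a single ``response_times`` cell so the table stays one row per
  trial.
* ``spikes.csv``  — unit_id, session_id, spike_time_s (session clock).
* ``units.csv``   — unit metadata plus the mean waveform as ``wf_###``
  sample columns and its sampling rate.
* ``config.yaml`` — echo of the generating configuration.
* ``manifest.json`` — SHA-256 checksums, seed, package version.

:func:`run_pipeline` chains simulate → behavior → ephys → mixed models and
writes every analysis artifact plus a human-readable report; all numbers in
the report come from the emitted CSV/JSON files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimConfig
from .synthgen import SpikeUnit, simulate_behavior, simulate_spikes
from . import behavior as bhv
from . import ephys
from . import mixedstats as mx

log = logging.getLogger("fitime")

TRIALS_COLUMNS = [
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


class BundleError(ValueError):
    """Raised with every validation violation found, not just the first."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_bundle(
    out_dir,
    trials: pd.DataFrame,
    units: list[SpikeUnit],
    config: SimConfig,
) -> Path:
    """Write a session bundle; returns the bundle directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tdf = trials.copy()
    tdf["response_times"] = [
        ";".join(f"{t:.6f}" for t in rt) for rt in tdf["response_times"]
    ]
    tdf.to_csv(out / "trials.csv", index=False)

    spike_rows = []
    unit_rows = []
    for u in units:
        for t in u.spike_times:
            spike_rows.append((u.unit_id, u.session_id, f"{t:.6f}"))
        row = {
            "unit_id": u.unit_id,
            "session_id": u.session_id,
            "animal_id": u.animal_id,
            "drug": u.drug,
            "sampling_rate_hz": u.sampling_rate_hz,
            "mean_rate_hz": u.mean_rate_hz,
            "true_class": u.truth.get("true_class", ""),
            "true_is_ramping": u.truth.get("is_ramping", ""),
        }
        for i, v in enumerate(np.asarray(u.waveform)):
            row[f"wf_{i:03d}"] = f"{v:.6f}"
        unit_rows.append(row)
    pd.DataFrame(spike_rows, columns=["unit_id", "session_id", "spike_time_s"]).to_csv(
        out / "spikes.csv", index=False
    )
    pd.DataFrame(unit_rows).to_csv(out / "units.csv", index=False)
    config.to_yaml(out / "config.yaml")
    manifest = {
        "seed": config.seed,
        "version": __version__,
        "files": {
            name: _sha256(out / name)
            for name in ("trials.csv", "spikes.csv", "units.csv", "config.yaml")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_bundle(path) -> tuple[pd.DataFrame, list[SpikeUnit], SimConfig]:
    """Read and validate a session bundle.

    Collects *every* validation problem (missing files, checksum mismatches,
    dangling unit references, inconsistent session ids) before raising a
    single :class:`BundleError` that enumerates them all.
    """
    root = Path(path)
    errors: list[str] = []
    needed = ["trials.csv", "spikes.csv", "units.csv", "config.yaml"]
    for name in needed:
        if not (root / name).exists():
            errors.append(f"missing file: {name}")
    if errors:
        raise BundleError("; ".join(errors))
    manifest_path = root / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        for name, digest in manifest.get("files", {}).items():
            if (root / name).exists() and _sha256(root / name) != digest:
                errors.append(f"checksum mismatch: {name}")

    config = SimConfig.from_yaml(root / "config.yaml")
    trials = pd.read_csv(root / "trials.csv")
    trials["response_times"] = [
        [float(x) for x in str(s).split(";") if x not in ("", "nan")]
        for s in trials["response_times"].fillna("")
    ]
    spikes = pd.read_csv(root / "spikes.csv")
    units_df = pd.read_csv(root / "units.csv")

    known_units = set(units_df["unit_id"])
    dangling = sorted(set(spikes["unit_id"]) - known_units)
    for uid in dangling:
        errors.append(f"spikes.csv references unknown unit: {uid}")
    known_sessions = set(trials["session_id"])
    if len(trials):
        bad_sessions = sorted(set(units_df["session_id"]) - known_sessions)
        for sid in bad_sessions:
            errors.append(f"units.csv references unknown session: {sid}")
    if errors:
        raise BundleError("; ".join(errors))

    wf_cols = sorted(c for c in units_df.columns if c.startswith("wf_"))
    units = []
    for _, row in units_df.iterrows():
        spk = np.sort(
            spikes.loc[spikes["unit_id"] == row["unit_id"], "spike_time_s"]
            .to_numpy(dtype=float)
        )
        truth = {}
        if "true_class" in row and isinstance(row["true_class"], str) and row["true_class"]:
            truth["true_class"] = row["true_class"]
        if "true_is_ramping" in row and row["true_is_ramping"] == row["true_is_ramping"]:
            truth["is_ramping"] = bool(row["true_is_ramping"])
        units.append(
            SpikeUnit(
                unit_id=row["unit_id"],
                session_id=row["session_id"],
                animal_id=row.get("animal_id", ""),
                drug=row.get("drug", ""),
                spike_times=spk,
                waveform=row[wf_cols].to_numpy(dtype=float),
                sampling_rate_hz=float(row["sampling_rate_hz"]),
                mean_rate_hz=float(row["mean_rate_hz"]),
                truth=truth,
            )
        )
    return trials, units, config


# ---------------------------------------------------------------------------
# pipeline stages


def analyze_behavior(trials: pd.DataFrame, out_dir, config: SimConfig) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = bhv.session_behavior_summary(trials, T=config.interval)
    starts = bhv.detect_start_times(trials, T=config.interval)
    summary.to_csv(out / "behavior_summary.csv", index=False)
    starts.to_csv(out / "starts.csv", index=False)
    log.info(
        "behavior: %d trials, %d start-valid, %d excluded",
        len(starts),
        int(starts["valid"].sum()),
        int((~starts["valid"]).sum()),
    )
    return {"summary": summary, "starts": starts}


def analyze_ephys(
    units: list[SpikeUnit],
    trials: pd.DataFrame,
    out_dir,
    config: SimConfig,
    ramp_bin_s: float = 0.1,
) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats = [
        ephys.extract_features(u.waveform, u.sampling_rate_hz, u.unit_id) for u in units
    ]
    classified = ephys.classify_units(feats, seed=config.seed)
    rates = pd.DataFrame(
        {"unit_id": [u.unit_id for u in units], "mean_rate_hz": [u.mean_rate_hz for u in units]}
    )
    classified = classified.merge(rates, on="unit_id")
    classified.to_csv(out / "units_classified.csv", index=False)
    kept, filter_report = ephys.filter_units(units, classified)
    log.info("ephys: %s", filter_report)
    ramping = ephys.ramping_table(kept, trials, bin_s=ramp_bin_s, interval=config.interval)
    ramping.to_csv(out / "ramping_fits.csv", index=False)
    peth = None
    if len(kept) >= 2:
        peth = ephys.build_peth(kept, trials, interval=config.interval)
        peth["matrix"].to_csv(out / "peth_matrix.csv")
    return {
        "classified": classified,
        "kept": kept,
        "filter_report": filter_report,
        "ramping": ramping,
        "peth": peth,
    }


def analyze_stats(
    trials: pd.DataFrame,
    kept_units: list[SpikeUnit],
    out_dir,
    config: SimConfig,
    fr_bin_s: float = 0.1,
    rt_granularity: str = "per_press",
) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rt_report = mx.fit_rt_model(
        trials,
        granularity=rt_granularity,
        stim_levels=list(config.stim_levels),
        drug_levels=list(config.drug_levels),
    )
    fr_report = None
    if len(kept_units) >= 2:
        fr = mx.fr_table(kept_units, trials, bin_s=fr_bin_s, interval=config.interval)
        fr_report = mx.fit_fr_model(
            fr,
            stim_levels=list(config.stim_levels),
            drug_levels=list(config.drug_levels),
        )
    payload = {
        "rt_model": rt_report.to_dict(),
        "fr_model": fr_report.to_dict() if fr_report else None,
        "fr_bin_s": fr_bin_s,
        "rt_granularity": rt_granularity,
    }
    (out / "model_report.json").write_text(json.dumps(payload, indent=2))
    return {"rt": rt_report, "fr": fr_report}


def run_pipeline(
    config: SimConfig,
    out_dir,
    fr_bin_s: float = 0.1,
    ramp_bin_s: float = 0.1,
    save_bundle: bool = True,
) -> dict:
    """Simulate a full experiment and run every analysis stage.

    Deterministic given ``config.seed``.  Writes the session bundle, the
    behavioral and ephys artifacts, ``model_report.json`` and ``report.txt``;
    any stage failure aborts with the stage name while earlier artifacts
    remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        trials = simulate_behavior(config)
        units = simulate_spikes(config, trials)
        if save_bundle:
            write_bundle(out, trials, units, config)
        stage = "behavior"
        b = analyze_behavior(trials, out, config)
        stage = "ephys"
        e = analyze_ephys(units, trials, out, config, ramp_bin_s=ramp_bin_s)
        stage = "stats"
        s = analyze_stats(trials, e["kept"], out, config, fr_bin_s=fr_bin_s)
        stage = "report"
        text = render_report(b, e, s)
        (out / "report.txt").write_text(text)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    return {"trials": trials, "units": units, **b, **e, **s, "report": text}


def render_report(b: dict, e: dict, s: dict) -> str:
    lines = ["fixed-interval timing pipeline report", "=" * 38, ""]
    lines.append("Curvature and start times per (drug, stim), averaged over animals:")
    cond = (
        b["summary"]
        .groupby(["drug", "stim"])[["curvature", "mean_start_s"]]
        .mean()
        .round(3)
    )
    lines.append(cond.to_string())
    lines.append("")
    ramp = e["ramping"]
    if len(ramp):
        lines.append("Ramping fractions and mean slopes per (drug, stim):")
        agg = (
            ramp.groupby(["drug", "stim"])
            .agg(frac_ramping=("is_ramping", "mean"), mean_slope=("slope", "mean"))
            .round(3)
        )
        lines.append(agg.to_string())
        lines.append("")
    lines.append(f"Unit filtering: {e['filter_report']}")
    lines.append("")
    lines.append("RT model (" + s["rt"].formula + "):")
    lines.append(s["rt"].term_table().round(4).to_string(index=False))
    lines.append(
        f"  LR vs null: {s['rt'].lr_vs_null:.2f} (df={s['rt'].lr_df}, "
        f"p={s['rt'].lr_pvalue:.3g}); R2m={s['rt'].r2_marginal:.3f}"
    )
    if s["fr"] is not None:
        lines.append("")
        lines.append("FR model (" + s["fr"].formula + "):")
        lines.append(s["fr"].term_table().round(4).to_string(index=False))
        lines.append(
            f"  LR vs null: {s['fr'].lr_vs_null:.2f} (df={s['fr'].lr_df}, "
            f"p={s['fr'].lr_pvalue:.3g}); R2m={s['fr'].r2_marginal:.3f}"
        )
    return "\n".join(lines) + "\n"
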