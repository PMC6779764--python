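"""Simulation and analysis configuration.

:class:`SimConfig` collects every parameter of the synthetic fixed-interval
session generator: the task schedule (12-s interval, variable intertrial
interval), the condition design (drug infusion crossed with optogenetic
stimulation frequency, pseudo-randomly interleaved), the two-state behavioral
response model (a low press rate before an internally timed "start", a high
rate after it, with scalar-timing variability), and the striatal unit model
(linear time-ramping firing for a subset of units, plus biphasic waveform
templates for the two putative cell classes).

Per-condition parameters (``start_mu``, ``ramp_slope``) are mappings keyed by
``(drug, stim)`` tuples; :func:`cell_key` normalizes the key form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

DRUG_LEVELS = ("saline", "muscimol")
STIM_LEVELS = ("NoStim", "2Hz", "20Hz")

#: Mean behavioral start time (s) per (drug, stim) cell.  Saline sessions are
#: unaffected by stimulation; muscimol shifts starts earlier, and 20-Hz
#: corticostriatal stimulation under muscimol shifts them later again.
DEFAULT_START_MU = {
    ("saline", "NoStim"): 8.4,
    ("saline", "2Hz"): 8.4,
    ("saline", "20Hz"): 8.4,
    ("muscimol", "NoStim"): 7.8,
    ("muscimol", "2Hz"): 7.9,
    ("muscimol", "20Hz"): 8.8,
}

#: Ramping slope (spikes/s per s) per (drug, stim) cell for ramping units.
#: Muscimol attenuates ramping; 20-Hz stimulation partially restores it.
DEFAULT_RAMP_SLOPE = {
    ("saline", "NoStim"): 0.30,
    ("saline", "2Hz"): 0.30,
    ("saline", "20Hz"): 0.30,
    ("muscimol", "NoStim"): 0.12,
    ("muscimol", "2Hz"): 0.15,
    ("muscimol", "20Hz"): 0.27,
}

#: Waveform feature distributions per class, in ms.  Medium spiny neurons
#: (MSN) have broad waveforms, fast-spiking interneurons (FSI) narrow ones.
DEFAULT_WAVEFORM_PARAMS = {
    "MSN": {"peak_to_trough_ms": (0.65, 0.05), "half_peak_width_ms": (0.30, 0.04)},
    "FSI": {"peak_to_trough_ms": (0.25, 0.03), "half_peak_width_ms": (0.13, 0.015)},
}


def cell_key(drug: str, stim: str) -> tuple[str, str]:
    """Normalized (drug, stim) key used by per-condition parameter maps."""
    return (str(drug), str(stim))


class ConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic session generator.

    Parameters
    ----------
    n_animals
        Number of virtual animals; each contributes one session per drug level.
    session_minutes
        Session duration in minutes; trials tile the session.
    max_trials
        Optional cap on trials per session (applied after tiling); ``None``
        means time-limited only.
    interval
        Fixed interval in seconds; the first press after this time is rewarded.
    iti_choices
        Intertrial intervals (s), sampled uniformly.
    start_mu
        Mean start time (s) per (drug, stim) cell.
    start_cv
        Coefficient of variation of start times (scalar timing: the standard
        deviation of a timed behavior is proportional to its mean).
    start_dist
        ``"truncnorm"`` (default) or ``"lognormal"`` start-time distribution.
    animal_start_sd
        Between-animal standard deviation (s) of a per-animal additive offset
        on mean start times, shared across that animal's sessions.
    rate_low, rate_high
        Press rates (presses/s) before and after the start time.
    timeout
        Trial end (s) when no press occurs after the interval.
    n_units
        Total number of simulated units, spread round-robin over sessions.
    frac_ramping
        Proportion of units with time-ramping firing.
    ramp_intercept
        Baseline firing rate ``a`` (spikes/s).
    ramp_slope
        Ramping slope ``b`` (spikes/s per s) per (drug, stim) cell.
    frac_fsi
        Proportion of narrow-waveform (FSI) units.
    waveform_params
        Per-class (mean, sd) of the two waveform features, in ms.
    waveform_fs_hz
        Waveform sampling rate (Hz).
    """

    seed: int = 0
    n_animals: int = 6
    n_sessions_per_condition: int = 1
    session_minutes: float = 60.0
    max_trials: int | None = None
    interval: float = 12.0
    iti_choices: Sequence[float] = (6.0, 8.0, 10.0, 12.0)
    stim_levels: Sequence[str] = STIM_LEVELS
    drug_levels: Sequence[str] = DRUG_LEVELS
    start_mu: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_START_MU)
    )
    start_cv: float = 0.15
    start_dist: str = "truncnorm"
    animal_start_sd: float = 0.3
    rate_low: float = 0.1
    rate_high: float = 2.0
    timeout: float = 24.0
    n_units: int = 48
    frac_ramping: float = 0.4
    ramp_intercept: float = 3.0
    ramp_slope: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_RAMP_SLOPE)
    )
    frac_fsi: float = 1.0 / 3.0
    waveform_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_WAVEFORM_PARAMS.items()
        }
    )
    waveform_fs_hz: float = 40000.0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.interval <= 0:
            raise ConfigError("interval must be positive")
        if self.rate_low < 0 or self.rate_high < 0:
            raise ConfigError("press rates must be non-negative")
        if self.ramp_intercept < 0:
            raise ConfigError("ramp_intercept must be non-negative")
        if not (0 <= self.frac_ramping <= 1 and 0 <= self.frac_fsi <= 1):
            raise ConfigError("proportions must lie in [0, 1]")
        if self.start_cv < 0:
            raise ConfigError("start_cv must be non-negative")
        if self.start_dist not in ("truncnorm", "lognormal"):
            raise ConfigError(f"unknown start_dist {self.start_dist!r}")
        if self.timeout < self.interval:
            raise ConfigError("timeout must be at least the interval")
        for cell in self.cells():
            mu = self.start_mu_for(*cell)
            if not (0 < mu <= self.interval):
                raise ConfigError(
                    f"start_mu for {cell} must lie in (0, interval]; got {mu}"
                )

    def cells(self) -> list[tuple[str, str]]:
        return [(d, s) for d in self.drug_levels for s in self.stim_levels]

    def start_mu_for(self, drug: str, stim: str) -> float:
        return float(self.start_mu[cell_key(drug, stim)])

    def ramp_slope_for(self, drug: str, stim: str) -> float:
        return float(self.ramp_slope[cell_key(drug, stim)])

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["iti_choices"] = list(self.iti_choices)
        d["stim_levels"] = list(self.stim_levels)
        d["drug_levels"] = list(self.drug_levels)
        d["start_mu"] = _cells_to_nested(self.start_mu)
        d["ramp_slope"] = _cells_to_nested(self.ramp_slope)
        d["waveform_params"] = {
            klass: {feat: list(ms) for feat, ms in feats.items()}
            for klass, feats in self.waveform_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "start_mu" in d:
            d["start_mu"] = _nested_to_cells(d["start_mu"])
        if "ramp_slope" in d:
            d["ramp_slope"] = _nested_to_cells(d["ramp_slope"])
        if "waveform_params" in d:
            d["waveform_params"] = {
                klass: {feat: tuple(ms) for feat, ms in feats.items()}
                for klass, feats in d["waveform_params"].items()
            }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _cells_to_nested(m: Mapping[tuple[str, str], float]) -> dict:
    out: dict = {}
    for (drug, stim), v in m.items():
        out.setdefault(drug, {})[stim] = float(v)
    return out


def _nested_to_cells(m: Mapping) -> dict:
    if m and isinstance(next(iter(m.keys())), tuple):
        return {cell_key(*k): float(v) for k, v in m.items()}
    return {
        cell_key(drug, stim): float(v)
        for drug, stims in m.items()
        for stim, v in stims.items()
    }


def demo_config(seed: int = 0, **overrides) -> SimConfig:
    """A desk-scale configuration: 6 virtual animals, 20-minute sessions,
    24 units.  Effect directions follow the defaults (muscimol shifts starts
    earlier and attenuates ramping; 20-Hz stimulation under muscimol rescues
    both)."""
    params = dict(seed=seed, n_animals=6, session_minutes=20.0, n_units=24)
    params.update(overrides)
    return SimConfig(**params)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """Effects-off configuration: identical start means in every condition,
    no state change in press rate, identical (zero) ramping everywhere.
    Useful for type-I-error simulations."""
    flat_mu = {cell: 8.0 for cell in DEFAULT_START_MU}
    flat_slope = {cell: 0.0 for cell in DEFAULT_RAMP_SLOPE}
    params = dict(
        seed=seed,
        n_animals=6,
        session_minutes=10.0,
        start_mu=flat_mu,
        ramp_slope=flat_slope,
        frac_ramping=0.0,
        rate_low=0.5,
        rate_high=0.5,
        n_units=12,
    )
    params.update(overrides)
    return SimConfig(**params)
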