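import numpy as np
import pandas as pd
import pytest

from fitime.config import SimConfig
from fitime.synthgen import SpikeUnit, simulate_behavior, simulate_spikes


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Two animals, short sessions: fast but structurally complete."""
    return SimConfig(seed=11, n_animals=2, session_minutes=6.0, n_units=8)


@pytest.fixture(scope="session")
def small_trials(small_config) -> pd.DataFrame:
    return simulate_behavior(small_config)


@pytest.fixture(scope="session")
def small_units(small_config, small_trials) -> list[SpikeUnit]:
    return simulate_spikes(small_config, small_trials)


def make_trials(
    n_trials: int,
    interval: float = 12.0,
    iti: float = 0.0,
    drug: str = "saline",
    stim: str = "NoStim",
    animal: str = "a0",
    session: str = "s0",
) -> pd.DataFrame:
    """Bare back-to-back trial table for unit-level spike analyses."""
    return pd.DataFrame(
        {
            "animal_id": animal,
            "session_id": session,
            "trial_index": np.arange(n_trials),
            "drug": drug,
            "stim": stim,
            "onset_s": np.arange(n_trials) * (interval + iti),
            "iti_s": iti,
            "reward_time_s": np.nan,
            "trial_end_s": interval,
            "true_start_s": np.nan,
            "response_times": [[] for _ in range(n_trials)],
        }
    )


def poisson_unit(
    rate_fn,
    lam_max: float,
    n_trials: int,
    rng: np.random.Generator,
    interval: float = 12.0,
    unit_id: str = "u0",
) -> SpikeUnit:
    """Inhomogeneous-Poisson unit over back-to-back trials, by thinning."""
    spikes = []
    for k in range(n_trials):
        cand = np.sort(rng.uniform(0, interval, rng.poisson(lam_max * interval)))
        keep = rng.uniform(0, lam_max, cand.size) < rate_fn(cand)
        spikes.append(k * interval + cand[keep])
    spk = np.concatenate(spikes)
    return SpikeUnit(
        unit_id,
        "s0",
        "a0",
        "saline",
        np.sort(spk),
        np.zeros(8),
        40000.0,
        spk.size / (n_trials * interval),
    )
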