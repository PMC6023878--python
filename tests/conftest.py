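import numpy as np
import pandas as pd
import pytest

from popshift.data_model import EpochTemplate, SessionData
from popshift.decoder import PopulationPool, build_pool
from popshift.synthetic import GeneratorConfig, generate_cohort

COHORT_SEED = 101


@pytest.fixture(scope="session")
def default_cohort():
    """Two-session cohort at the default study conditions (50 units total)."""
    cfg = GeneratorConfig(n_units=25, n_sessions=2, n_trials=40)
    return generate_cohort(cfg, COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_pools(default_cohort):
    sessions, _ = default_cohort
    return {st: build_pool(sessions, state=st) for st in ("passive", "engaged")}


@pytest.fixture()
def tiny_session():
    """Hand-built 3-unit, 4-trial session with known spike placements."""
    trials = pd.DataFrame(
        {
            "trial_id": ["t0", "t1", "t2", "t3"],
            "state": ["passive", "passive", "engaged", "engaged"],
            "stimulus": ["reference", "target", "reference", "target"],
            "outcome": ["correct"] * 4,
            "click_rate_hz": [8.0, 24.0, 8.0, 24.0],
        }
    )
    spikes = pd.DataFrame(
        {
            "unit_id": ["u0", "u0", "u1", "u1", "u2", "u2", "u0"],
            "trial_id": ["t0", "t0", "t1", "t2", "t2", "t3", "t3"],
            "time_s": [0.05, 1.80, 0.35, 2.00, 1.70, 3.10, 0.10],
        }
    )
    clicks = pd.DataFrame(
        {"trial_id": ["t0", "t0", "t1"], "time_s": [1.65, 1.775, 1.70]}
    )
    licks = pd.DataFrame({"trial_id": ["t2"], "time_s": [0.5]})
    units = pd.DataFrame({"unit_id": ["u0", "u1", "u2"], "session_id": "tiny"})
    return SessionData(
        session_id="tiny",
        units=units,
        trials=trials,
        spikes=spikes,
        clicks=clicks,
        licks=licks,
        template=EpochTemplate(),
    )


def gaussian_pool(
    rng: np.random.Generator,
    n_units: int = 30,
    n_trials: int = 40,
    separation: float = 3.0,
    sigma: float = 1.0,
    n_bins: int = 1,
    direction: np.ndarray | None = None,
) -> PopulationPool:
    """Spherical-Gaussian two-class pool built directly from arrays."""
    if direction is None:
        direction = rng.standard_normal(n_units)
    else:
        n_units = len(direction)
    direction = direction / np.linalg.norm(direction)
    mu = {"reference": np.zeros(n_units), "target": separation * direction}
    rates = {
        c: [mu[c][:, None, None] + sigma * rng.standard_normal((n_units, n_trials, n_bins))]
        for c in ("reference", "target")
    }
    return PopulationPool(
        class_rates=rates,
        unit_ids=np.array([f"g{i}" for i in range(n_units)]),
        bin_starts=np.arange(n_bins) * 0.1,
        width=0.1,
        step=0.1,
    )
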