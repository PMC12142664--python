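import numpy as np
import pandas as pd
import pytest

from shockpanel import CohortConfig, FeatureTable, simulate_cohort


def small_config(**kw) -> CohortConfig:
    """A scaled-down cohort for unit mechanics (fast to simulate)."""
    base = dict(
        n_shock=16, n_control=12, n_infection=14, n_sepsis_nonshock=14,
        n_features=120, n_markers=8, n_markers_up=3, seed=11,
    )
    base.update(kw)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def default_cohort():
    """Full-scale cohort at the study's default geometry."""
    return simulate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def toy_table():
    """Hand-built 4-sample x 3-feature table with known values."""
    inten = pd.DataFrame(
        {"A": [1e6, 2e6, 3e6, 4e6],
         "B": [2e5, 2e5, 4e5, 4e5],
         "C": [5e5, 6e5, 7e5, 8e5]},
        index=["s1", "s2", "s3", "s4"],
    )
    feats = pd.DataFrame(
        {"mz": [200.0, 300.0, 400.0], "rt": [1.0, 5.0, 9.0],
         "snr": [50.0, 30.0, 20.0]},
        index=pd.Index(["A", "B", "C"], name="feature_id"),
    )
    return FeatureTable(inten, feats)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
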