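import numpy as np
import pandas as pd
import pytest

from plasmad.datamodel import ProteomicsMatrix
from plasmad.simulate import SimulationConfig, simulate_cohort


def make_matrix(values, plates=None, scale_factor=None, lod=None, scale="rfu"):
    """Build a small ProteomicsMatrix from a dict/DataFrame of values."""
    values = pd.DataFrame(values)
    if plates is None:
        plates = pd.Series("P1", index=values.index)
    else:
        plates = pd.Series(plates, index=values.index)
    return ProteomicsMatrix(
        values=values.astype(float),
        plate_of_sample=plates,
        scale_factor=scale_factor,
        lod=lod,
        scale=scale,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    vals = pd.DataFrame(
        {"A1": [10.0, 20.0, 30.0], "A2": [5.0, 6.0, 7.0]},
        index=["s1", "s2", "s3"],
    )
    return make_matrix(vals)


@pytest.fixture
def tiny_samples():
    return pd.DataFrame(
        {
            "age_at_draw": [70.0, 75.0, 80.0],
            "sex": ["female", "male", "female"],
            "cohort": ["K1", "K1", "K1"],
            "dataset_cluster": ["c1", "c1", "c1"],
            "clinical_status": ["CO", "AD", "CO"],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )


@pytest.fixture(scope="session")
def small_study():
    """A small but non-trivial simulated study shared across tests."""
    cfg = SimulationConfig(
        cohorts={"K1": (150, 100)},
        n_analytes=60,
        fraction_nonnull=0.1,
        effect_size_sd_units=0.8,
        lod_quantile=0.005,
        missing_rate=0.01,
        biomarkers={},
        seed=42,
    )
    return simulate_cohort(cfg)
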