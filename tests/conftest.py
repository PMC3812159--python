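import numpy as np
import pandas as pd
import pytest

from degronkinetics import (
    FitConfig,
    NoiseModel,
    TimeCourseDataset,
    aggregate_replicates,
    generate_timecourse,
    normalize_to_parent,
    reference_parameters,
)


def make_dataset(times, species_values, n=3):
    """Build a TimeCourseDataset directly from per-species value arrays."""
    times = np.asarray(times, dtype=float)
    mean = pd.DataFrame(species_values, index=pd.Index(times, name="time_min"))
    sd = mean * 0.0
    counts = mean * 0 + n
    return TimeCourseDataset(times=times, mean=mean, sd=sd, counts=counts, n=n)


@pytest.fixture(scope="session")
def bonger():
    return reference_parameters("Bonger")


@pytest.fixture(scope="session")
def bonger_dataset(bonger):
    """Noisy 3-replicate synthetic time course from the Bonger constants."""
    table = generate_timecourse(bonger, noise=NoiseModel(cv=0.10), n_reps=3, seed=42)
    return aggregate_replicates(normalize_to_parent(table))


@pytest.fixture(scope="session")
def noiseless_dataset(bonger):
    table = generate_timecourse(bonger, noise=NoiseModel(cv=0.0), n_reps=1, seed=0)
    return aggregate_replicates(normalize_to_parent(table))


@pytest.fixture
def quick_config():
    """Short chain for structural tests where accuracy is irrelevant."""
    return FitConfig(iterations=2_000, seed=11)
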