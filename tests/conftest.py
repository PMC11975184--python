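import numpy as np
import pytest

from choopt import datastore, preprocess
from choopt.simulator import (
    STD_CONDITION,
    SimulatorParams,
    build_design,
    generate_dataset,
    simulate_run,
)

#: flagged-sample rate matching the observed QC-failure rate (19 of 754)
FLAG_FRACTION = 19 / 754


@pytest.fixture(scope="session")
def noise_free_params():
    return SimulatorParams(noise_cv=0.0)


@pytest.fixture(scope="session")
def std_run(noise_free_params):
    """One noise-free standard-condition cultivation."""
    return simulate_run(STD_CONDITION, noise_free_params, seed=0)


@pytest.fixture(scope="session")
def full58_runs():
    """The 58-run dataset at the study noise level, with QC flags."""
    return generate_dataset(build_design("FULL_58"), SimulatorParams(noise_cv=0.05),
                            seed=11, flag_fraction=FLAG_FRACTION)


@pytest.fixture(scope="session")
def full58_points(full58_runs):
    return datastore.flatten_to_points(full58_runs)


@pytest.fixture(scope="session")
def full58_clean(full58_points):
    return preprocess.clean_points(full58_points)
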