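import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from neuroage.brainage import BrainAgeModel
from neuroage.config import SimulationConfig
from neuroage.simulate import generate_longitudinal_cohort, generate_training_cohort


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale generative conditions shared by fast tests."""
    return SimulationConfig(n_train=300, n_longitudinal=120, n_idps=60, seed=42)


@pytest.fixture(scope="session")
def small_training(small_config):
    return generate_training_cohort(small_config)


@pytest.fixture(scope="session")
def small_longitudinal(small_config):
    return generate_longitudinal_cohort(small_config)


@pytest.fixture(scope="session")
def fitted_stratum(small_config, small_training):
    """One fitted (female, grey-matter) model plus its training inputs."""
    cohort, idps = small_training
    idp = idps[("F", "GM")]
    ages = (
        cohort.set_index("participant_id").loc[idp.data.index, "age"].to_numpy(float)
    )
    model = BrainAgeModel(
        idp.data, ages, idp.confounds, k=15, stratum=("F", "GM")
    )
    return model.fit(), idp, ages
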