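import numpy as np
import pytest

from neurobag.bagsel import BagConfig
from neurobag.pipeline import cohort_to_features
from neurobag.synthcohort import (
    PlantedEffect,
    SimulationConfig,
    generate_profile_cohort,
)

F0 = 2.0**1.5  # lowest default carrier (delta); carriers are F0 * 2**k


@pytest.fixture(scope="session")
def planted_cohort():
    """Profile cohort with one planted component per coupling mode."""
    cfg = SimulationConfig(
        seed=11,
        planted_effects=(
            PlantedEffect("amplitude", F0 * 4, 2.0, rank=0),
            PlantedEffect("phase", F0 * 2, 2.0, rank=1),
        ),
    )
    return generate_profile_cohort(cfg)


@pytest.fixture(scope="session")
def planted_features(planted_cohort):
    features, _ = cohort_to_features(planted_cohort)
    return features


@pytest.fixture(scope="session")
def null_features():
    """Feature matrix from a no-effect cohort."""
    cohort = generate_profile_cohort(SimulationConfig(seed=23))
    features, _ = cohort_to_features(cohort)
    return features


@pytest.fixture(scope="session")
def small_bag_config():
    return BagConfig(n_draw=5000, seed=7)
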