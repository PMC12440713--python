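import numpy as np
import pytest

from pbpop.datagen import DemographicsConfig, SamplingDesign, build_regimen, generate_tdm_dataset
from pbpop.model import IndividualParameters, PopulationParameters, SubjectCovariates


@pytest.fixture(scope="session")
def pop_params() -> PopulationParameters:
    """Final-model population parameters (defaults)."""
    return PopulationParameters()


@pytest.fixture(scope="session")
def reference_dog() -> SubjectCovariates:
    """The 20 kg / 5 y covariate-median dog."""
    return SubjectCovariates(weight=20.0, age=5.0, sex=1)


@pytest.fixture(scope="session")
def reference_individual() -> IndividualParameters:
    """Typical individual at the covariate medians (eta = 0)."""
    return IndividualParameters(CL_i=0.015, V_i=20.0)


@pytest.fixture(scope="session")
def rich_dataset_small(pop_params) -> object:
    """20 dogs, rich 48/168/672 h design — shared across estimation tests."""
    return generate_tdm_dataset(
        DemographicsConfig(n_subjects=20),
        SamplingDesign.rich(),
        pop_params,
        seed=42,
        regimen=lambda c: build_regimen(c, 5.0, 12.0, 28.0),
    )


@pytest.fixture(scope="session")
def sparse_dataset(pop_params) -> object:
    """Study-structured sparse dataset (predose troughs, ~1.2 obs/dog)."""
    return generate_tdm_dataset(
        DemographicsConfig(n_subjects=100),
        SamplingDesign.sparse_tdm(),
        pop_params,
        seed=7,
    )
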