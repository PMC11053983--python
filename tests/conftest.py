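import numpy as np
import pytest

from teicopk import CohortSpec, PopPKModel, sample_cohort


@pytest.fixture(scope="session")
def model() -> PopPKModel:
    return PopPKModel.default()


@pytest.fixture(scope="session")
def typical(model):
    """Typical-subject parameters at the reference covariates."""
    return model.typical_params()


@pytest.fixture(scope="session")
def small_cohort(model):
    """A modest shared cohort for dosing tests (kept small for speed)."""
    return sample_cohort(model, CohortSpec(n=400, seed=20240405))


def random_params(rng: np.random.Generator):
    """A random physiologically plausible parameter set."""
    from teicopk import IndividualParams

    return IndividualParams(
        CL=rng.uniform(0.2, 3.0),
        V1=rng.uniform(1.0, 20.0),
        Q2=rng.uniform(0.5, 15.0),
        V2=rng.uniform(2.0, 40.0),
        Q3=rng.uniform(0.2, 8.0),
        V3=rng.uniform(10.0, 200.0),
    )
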