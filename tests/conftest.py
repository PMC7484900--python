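import numpy as np
import pytest

from restid import (CohortSpec, DecompositionConfig, FeatureCache,
                    generate_cohort)


@pytest.fixture(scope="session")
def cohort():
    """The default 12-subject, 8-channel separable cohort (seed 7)."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def dwt_cache(cohort):
    """Full-channel DWT feature cache for the session cohort."""
    return FeatureCache.from_cohort(cohort, DecompositionConfig(method="dwt"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
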