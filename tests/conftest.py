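import numpy as np
import pytest

from vppg import CohortSpec, ManeuverProtocol


@pytest.fixture
def protocol() -> ManeuverProtocol:
    return ManeuverProtocol()


@pytest.fixture
def small_cohort_spec() -> CohortSpec:
    """A 20-patient cohort with every side-status represented."""
    return CohortSpec(
        n_patients=20, right_only=3, left_only=4, bilateral=5, none=8, seed=11
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
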