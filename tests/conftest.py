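import numpy as np
import pytest

from swarmsafe.models import (
    BlamDimensionlessParams,
    SimplifiedParams,
    SwarmbotState,
    TransportParams,
    TwoCompartmentSimplifiedParams,
)


@pytest.fixture(scope="session")
def ref_params() -> SimplifiedParams:
    """The printed bistable collective-survival parameter set."""
    return SimplifiedParams(mu=1.75, n_max=1.0, death_max=2.0, survival_k=0.5, hill_alpha=4.0)


@pytest.fixture(scope="session")
def two_compartment_params() -> TwoCompartmentSimplifiedParams:
    """The printed two-compartment set (small K, cell escape f_N = 0.1)."""
    return TwoCompartmentSimplifiedParams(
        base=SimplifiedParams(mu=1.75, n_max=1.0, death_max=2.0, survival_k=0.01, hill_alpha=4.0),
        f_n_cells=0.1,
        v_ratio=10.0,
    )


@pytest.fixture(scope="session")
def blam_params() -> BlamDimensionlessParams:
    return BlamDimensionlessParams()


@pytest.fixture(scope="session")
def transport() -> TransportParams:
    return TransportParams()


@pytest.fixture(scope="session")
def rich_state() -> SwarmbotState:
    """High capsule density in fresh medium with antibiotic everywhere."""
    return SwarmbotState(n1=0.5, s1=10.0, a1=0.4, b1=0.0, n2=0.0, s2=10.0, a2=0.4, b2=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160229)
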