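import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20220331)


@pytest.fixture(scope="session")
def formula_db():
    from crossfeednet.io import bundled_formula_db

    return bundled_formula_db()


@pytest.fixture
def toy_spec():
    """A 3-species consortium with known cross-feeding, noiseless.

    P1 secretes X (absent from fresh medium) and consumes A;
    C1 consumes X and B, secretes Y; C2 consumes X and Y.
    True edges: (P1,C1,X), (P1,C2,X), (C1,C2,Y).
    """
    from crossfeednet.synthetic import GrowthParams, SyntheticCommunitySpec

    growth = {
        "P1": GrowthParams(A=0.05, K=1.5, r=1.2, t0=4.0),
        "C1": GrowthParams(A=0.04, K=1.2, r=1.5, t0=5.0),
        "C2": GrowthParams(A=0.06, K=1.8, r=1.0, t0=6.0),
    }
    return SyntheticCommunitySpec(
        species=["P1", "C1", "C2"],
        growth_params=growth,
        medium={"A": 2000.0, "B": 1500.0, "bg1": 800.0, "bg2": 3000.0},
        interactions={
            "P1": {"X": 2000.0 / (1.5 - 0.05), "A": -0.8},
            "C1": {"X": -0.9, "B": -0.7, "Y": 1200.0 / (1.2 - 0.04)},
            "C2": {"X": -0.85, "Y": -0.75},
        },
        noise_cv=0.0,
        replicates=1,
        seed=11,
    )
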