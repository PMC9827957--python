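import numpy as np
import pytest

# The published mean-scaled G matrix for the three blossom traits
# (GAD, GSD, ASD), percent units: evolvabilities on the diagonal,
# additive genetic covariances off-diagonal.
PUBLISHED_G = np.array(
    [
        [0.409, 0.193, 0.309],
        [0.193, 0.801, -0.591],
        [0.309, -0.591, 6.567],
    ]
)


@pytest.fixture(scope="session")
def published_G():
    return PUBLISHED_G.copy()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
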