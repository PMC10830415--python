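import numpy as np
import pytest

from enhancerkit.oracle import SurrogateOracle, fly_surrogate, human_surrogate
from enhancerkit.seqcore import Sequence, default_profile, generate_random_sequences


@pytest.fixture(scope="session")
def fly() -> SurrogateOracle:
    return fly_surrogate()


@pytest.fixture(scope="session")
def human() -> SurrogateOracle:
    return human_surrogate()


@pytest.fixture(scope="session")
def profile500():
    return default_profile(500)


@pytest.fixture(scope="session")
def random500(profile500):
    return generate_random_sequences(profile500, 20, seed=1234)


@pytest.fixture()
def short_random():
    """A handful of short sequences for brute-force comparisons."""
    return generate_random_sequences(default_profile(40), 5, seed=77)


class ConstantOracle:
    """Oracle returning the same score for every sequence (for degenerate cases)."""

    input_length = "any"
    class_names = ("flat",)

    def __init__(self, value: float = 0.5):
        self.value = value

    def score_batch(self, sequences):
        return np.full((len(sequences), 1), self.value)


@pytest.fixture()
def constant_oracle():
    return ConstantOracle()
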