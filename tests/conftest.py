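import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tahmm import build_ta_model, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ta_model():
    return build_ta_model(2)


@pytest.fixture(scope="session")
def small_ta_dataset():
    """A small reusable TA dataset (session-scoped: generation is cheap but
    not free)."""
    return generate_dataset("TA", 30, seed=7, length_min=60, length_max=300,
                            length_median=150)


def random_protein(rng, length):
    from tahmm.alphabet import ALPHABET

    return "".join(ALPHABET[i] for i in rng.integers(0, 20, length))
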