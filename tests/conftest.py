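import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from helitronkit.synthetic import default_consensus


@pytest.fixture(scope="session")
def consensus():
    """The fixed synthetic 134-bp family core used across tests."""
    return default_consensus()


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
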