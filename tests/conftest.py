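import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from intronprom.inr import InrPWM


@pytest.fixture
def rng():
    return np.random.default_rng(20190731)


@pytest.fixture
def toy_pwm():
    """Width-7 initiator-like matrix with a unique consensus (TCAATCT)."""
    freq = np.array(
        [
            [0.08, 0.36, 0.10, 0.46],
            [0.07, 0.49, 0.06, 0.38],
            [0.82, 0.04, 0.08, 0.06],
            [0.30, 0.22, 0.24, 0.24],
            [0.39, 0.11, 0.09, 0.41],
            [0.10, 0.42, 0.08, 0.40],
            [0.09, 0.37, 0.11, 0.43],
        ]
    )
    return InrPWM(frequencies=freq, pseudocount=0.01, plus_one_offset=2)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
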