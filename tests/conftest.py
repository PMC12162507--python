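import numpy as np
import pytest

from surreg.motif_scan import default_patterns


@pytest.fixture
def patterns():
    return default_patterns()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
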