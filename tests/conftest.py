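import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def toy_index():
    """Index of the single contig ACGTACGT at k=4."""
    from kmeridx.index import GenomeIndex

    return GenomeIndex.build({"c1": "ACGTACGT"}, 4)


@pytest.fixture
def homopolymer_index():
    """Index of AAAAAAA at k=4 (every window is AAAA)."""
    from kmeridx.index import GenomeIndex

    return GenomeIndex.build({"c1": "AAAAAAA"}, 4)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
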