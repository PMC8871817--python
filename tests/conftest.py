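import numpy as np
import pytest

from hybcap.registry import LocusRegistry, TargetSequence, registry_from_sequences

BASES = np.array(list("ACGT"))


def random_dna(rng, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20220350)


@pytest.fixture
def small_registry() -> LocusRegistry:
    """Three sequences over two loci with known lengths (100/150/200)."""
    return registry_from_sequences(
        [
            TargetSequence("g1", "TaxA", "A" * 50 + "C" * 50),
            TargetSequence("g1", "TaxB", "ACGT" * 37 + "AC"),
            TargetSequence("g2", "TaxA", "ACGT" * 50),
        ]
    )
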