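import numpy as np
import pytest

from rnascan import (
    EntropyTrack,
    SecondaryStructure,
    half_structured_spec,
    make_entropy,
    make_structure,
)

HAIRPIN_PAIRING = [12, 11, 10, 9, 0, 0, 0, 0, 4, 3, 2, 1]

HAIRPIN_CT = "\n".join(
    ["12 hairpin"]
    + [
        f"{i} N {i - 1} {(i + 1) % 13 if i < 12 else 0} {p} {i}"
        for i, p in enumerate(HAIRPIN_PAIRING, start=1)
    ]
) + "\n"


@pytest.fixture
def hairpin():
    return SecondaryStructure(
        sequence="N" * 12, pairing=np.array(HAIRPIN_PAIRING)
    )


@pytest.fixture
def half_structured():
    """120-nt fixture: fully paired low-SE 5' half, unpaired high-SE 3' half."""
    spec = half_structured_spec(length=120, low_se=0.05, high_se=0.8)
    structure, paired = make_structure(spec)
    entropy = make_entropy(spec, noise_sd=0.01, seed=7)
    return structure, entropy, paired


def random_valid_structure(rng, n):
    """Nested-interval random structure; always satisfies the invariants."""
    from rnascan.fixtures import random_structure

    return random_structure(n, rng, paired_fraction=float(rng.uniform(0.1, 0.9)))
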