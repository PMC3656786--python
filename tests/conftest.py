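import numpy as np
import pytest

from ssrpopkit.genotypes import MISSING, NULL, GenotypeMatrix


@pytest.fixture
def toy_matrix():
    """4 individuals x 3 loci with a het, a null homozygote and a missing cell."""
    calls = np.array(
        [
            [[100, 100], [150, 152], [200, 200]],
            [[100, 102], [150, 150], [200, 204]],
            [[102, 102], [NULL, NULL], [200, 200]],
            [[102, 102], [MISSING, MISSING], [204, 204]],
        ],
        dtype=np.int32,
    )
    return GenotypeMatrix(
        ["a", "b", "c", "d"],
        ["L1", "L2", "L3"],
        calls,
        {"a": "p1", "b": "p1", "c": "p2", "d": "p2"},
    )


@pytest.fixture(scope="session")
def flax_dataset():
    """One flax-like simulated dataset shared across tests."""
    import ssrpopkit as sk

    gm, lmap, grouping, truth = sk.simulate(sk.flaxlike_preset(seed=11, n_loci=40))
    return gm, lmap, grouping, truth
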