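import numpy as np
import pytest

from popcollapse.genotypes import GenotypeMatrix


@pytest.fixture
def two_site_matrix() -> GenotypeMatrix:
    """Hand-built table: 4 individuals, 2 sites, 3 loci, one missing call."""
    calls = np.array(
        [
            [[100, 102], [90, 90], [120, 122]],
            [[100, 100], [90, 92], [120, 120]],
            [[102, 104], [92, 92], [0, 0]],
            [[104, 104], [90, 92], [122, 124]],
        ]
    )
    return GenotypeMatrix(
        ["a1", "a2", "b1", "b2"], ["A", "A", "B", "B"],
        ["L1", "L2", "L3"], calls,
    )


def random_matrix(rng: np.random.Generator, n_ind: int = 8, n_loci: int = 4,
                  n_sites: int = 2, missing_rate: float = 0.1) -> GenotypeMatrix:
    """Random valid genotype table for property tests."""
    calls = rng.integers(90, 120, size=(n_ind, n_loci, 2))
    miss = rng.random((n_ind, n_loci)) < missing_rate
    calls[miss] = 0
    sites = [f"s{rng.integers(n_sites)}" for _ in range(n_ind)]
    # every declared individual needs a site; ensure at least one of each
    for k in range(min(n_sites, n_ind)):
        sites[k] = f"s{k}"
    return GenotypeMatrix([f"i{k}" for k in range(n_ind)], sites,
                          [f"L{j}" for j in range(n_loci)], calls)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120915)
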