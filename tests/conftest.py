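import numpy as np
import pytest

from radmiss import MISSING, GenotypeMatrix


@pytest.fixture
def hand_matrix() -> GenotypeMatrix:
    """Two populations of two diploids at one locus:
    pop1 = {A/A, A/a}, pop2 = {a/a, a/a} (A=0, a=1)."""
    return GenotypeMatrix(
        individual_ids=["i1", "i2", "i3", "i4"],
        populations=["p1", "p1", "p2", "p2"],
        locus_ids=["L1"],
        calls=np.array([[[0, 0]], [[0, 1]], [[1, 1]], [[1, 1]]]),
    )


def make_random_matrix(
    seed: int,
    n_per_pop: int = 5,
    n_pops: int = 3,
    n_loci: int = 12,
    missing_rate: float = 0.2,
    max_allele: int = 1,
    with_tags: bool = False,
) -> GenotypeMatrix:
    """Small random matrix with missing calls, for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = n_per_pop * n_pops
    calls = rng.integers(0, max_allele + 1, size=(n, n_loci, 2)).astype(np.int16)
    drop = rng.random((n, n_loci)) < missing_rate
    calls[drop] = MISSING
    tags = None
    if with_tags:
        tags = [f"t{rng.integers(0, max(2, n_loci // 2))}" for _ in range(n_loci)]
    return GenotypeMatrix(
        individual_ids=[f"ind{i}" for i in range(n)],
        populations=[f"pop{i // n_per_pop}" for i in range(n)],
        locus_ids=[f"L{j}" for j in range(n_loci)],
        calls=calls,
        tags=tags,
    )
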