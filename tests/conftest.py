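import numpy as np
import pytest

from msatpop.io import GenotypeMatrix, Locus
from msatpop.synthetic import StudyConfig, generate_study


@pytest.fixture
def toy_two_pop():
    """Two populations, two loci: pop A fixed-ish, pop B shifted alleles."""
    calls = np.array([
        [[184, 188], [100, 100]],
        [[184, 184], [100, 102]],
        [[188, 188], [102, 102]],
        [[184, 188], [100, 102]],
    ])
    return GenotypeMatrix(
        ["a1", "a2", "b1", "b2"],
        np.array(["A", "A", "B", "B"], dtype=object),
        [Locus("L1", repeat_unit_length=4), Locus("L2", repeat_unit_length=2)],
        calls,
    )


@pytest.fixture(scope="session")
def smoke_study():
    cfg = StudyConfig(n_pops_per_group=(2, 2, 2), n_loci=6)
    return generate_study(seed=11, config=cfg)


@pytest.fixture(scope="session")
def desk_study():
    return generate_study(seed=7)


def random_genotypes(rng, n_pops=3, n_ind=8, n_loci=4, n_alleles=5,
                     missing_rate=0.0):
    """Small random genotype matrix for brute-force comparisons."""
    pops = np.repeat([f"P{i}" for i in range(n_pops)], n_ind)
    n = len(pops)
    calls = rng.integers(10, 10 + n_alleles, size=(n, n_loci, 2))
    if missing_rate:
        miss = rng.random((n, n_loci)) < missing_rate
        calls[miss] = 0
    return GenotypeMatrix(
        [f"i{k}" for k in range(n)], pops.astype(object),
        [Locus(f"L{j}", allele_encoding="repeat_count") for j in range(n_loci)],
        calls,
    )
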