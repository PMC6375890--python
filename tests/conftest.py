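import numpy as np
import pytest

from aimpanel import GenotypeMatrix, GroupSpec, MISSING, SimulationConfig, simulate


def random_genotype_matrix(seed: int, n: int = 8, m: int = 12, missing_rate: float = 0.1) -> GenotypeMatrix:
    """A small random genotype fixture with two populations and missing calls."""
    rng = np.random.default_rng(seed)
    gt = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    gt[rng.random((n, m)) < missing_rate] = MISSING
    return GenotypeMatrix(
        individual_ids=[f"ind{i}" for i in range(n)],
        family_ids=["popA"] * (n // 2) + ["popB"] * (n - n // 2),
        snp_ids=[f"rs{j}" for j in range(m)],
        chromosomes=[str(1 + j % 3) for j in range(m)],
        positions=[100 + 10 * j for j in range(m)],
        genotypes=gt,
        ref_alleles=["A"] * m,
        alt_alleles=["G"] * m,
    )


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    return random_genotype_matrix(seed=42)


@pytest.fixture(scope="session")
def two_pop_dataset():
    """A well-separated two-population cohort used by several recovery tests."""
    groups = [
        GroupSpec(n=15, label="a", q=[1.0, 0.0]),
        GroupSpec(n=15, label="b", q=[0.0, 1.0]),
        GroupSpec(n=10, label="adm", alpha=[1.0, 1.0]),
    ]
    return simulate(SimulationConfig(K=2, groups=groups, m=2000, F=0.25, seed=11))
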