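import pytest

from kecpipe import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset shared across read-only tests."""
    return simulate_dataset(SimConfig(seed=11, n_genes=120))


@pytest.fixture(scope="session")
def recovery_dataset():
    """The parameter-recovery dataset: 2,000 genes at the default
    co-occupancy probabilities (0.6 paused, 0.9 7SK|paused, 0.9 KAP1|7SK)."""
    return simulate_dataset(
        SimConfig(
            seed=20,
            n_genes=2000,
            n_chroms=2,
            chrom_length=8_000_000,
        )
    )
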