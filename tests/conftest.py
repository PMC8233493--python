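import numpy as np
import pytest

from bgsinfer import HaplotypeSample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sample(
    rng: np.random.Generator,
    n_hap: int = 10,
    n_sites: int = 30,
    chrom_lengths: tuple[int, ...] = (100_000,),
) -> HaplotypeSample:
    """A random polymorphic haplotype sample for estimator tests."""
    total = sum(chrom_lengths)
    pos_global = np.sort(
        rng.choice(total, size=min(n_sites, total), replace=False)
    )
    offsets = np.cumsum([0] + list(chrom_lengths))
    chrom = np.searchsorted(offsets, pos_global, side="right") - 1
    positions = pos_global - offsets[chrom]
    H = np.zeros((n_hap, pos_global.size), dtype=np.uint8)
    for j in range(pos_global.size):
        k = rng.integers(1, n_hap)  # guaranteed polymorphic
        H[rng.choice(n_hap, size=k, replace=False), j] = 1
    return HaplotypeSample(
        haplotypes=H,
        positions=positions,
        chrom=chrom.astype(np.int32),
        chrom_lengths=chrom_lengths,
        n_diploids=n_hap // 2,
    )


@pytest.fixture
def small_sample(rng):
    return random_sample(rng)
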