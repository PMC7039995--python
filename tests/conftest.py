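import pytest

from hlapop import (
    Cohort,
    SyntheticConfig,
    demo_pool,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def demo_cohort_truth():
    """Default nine-locus synthetic cohort (218 unrelated + 12 trios)."""
    cfg = SyntheticConfig(pool=demo_pool(), seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def demo_cohort(demo_cohort_truth) -> Cohort:
    return demo_cohort_truth[0]


@pytest.fixture(scope="session")
def truth_table(demo_cohort_truth):
    return demo_cohort_truth[1]


def two_locus_pool(freqs=(0.4, 0.3, 0.2, 0.1)):
    """A known 4-haplotype pool on two loci (for EM recovery tests)."""
    from hlapop import PoolEntry, parse_haplotype

    loci = ("A", "B")
    names = ["A*01:01~B*07:02", "A*01:01~B*08:01", "A*02:01~B*07:02", "A*02:01~B*08:01"]
    return [
        PoolEntry(parse_haplotype(n, loci), f, "NativeAmerican")
        for n, f in zip(names, freqs)
    ]
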