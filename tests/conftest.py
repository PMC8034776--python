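import numpy as np
import pytest

from bartcore import FixtureConfig, generate_reference
from bartcore.library_io import UDHSIndex

# Reduced study conditions shared across test modules: same generative
# structure as the defaults, scaled for fast repeated runs.  The QC
# threshold scales with the site count so the synthetic peak counts
# (~peak_rate * n_udhs_sites) sit above it as they do at full scale.
SMALL = FixtureConfig(seed=3, n_genes=2000, n_samples=50, n_udhs_sites=4000,
                      n_trs=20, n_target_genes=120, n_background_runs=30,
                      min_peaks=300, n_reads=200_000)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_udhs(intervals):
    """UDHSIndex from a list of (chrom, start, end)."""
    return UDHSIndex(np.array([i[0] for i in intervals], dtype=object),
                     np.array([i[1] for i in intervals], dtype=np.int64),
                     np.array([i[2] for i in intervals], dtype=np.int64))


def random_udhs(rng, n_sites, chroms=("chr1", "chr2"), span=100_000):
    """Random sorted non-overlapping sites for oracle comparisons."""
    per = np.array_split(np.arange(n_sites), len(chroms))
    out = []
    for chrom, block in zip(chroms, per):
        k = len(block)
        if k == 0:
            continue
        edges = np.sort(rng.choice(span, size=2 * k, replace=False))
        for i in range(k):
            out.append((chrom, int(edges[2 * i]), int(edges[2 * i + 1])))
    return make_udhs(out)
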