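import numpy as np
import pytest

from peakreg.formats_io import CoverageTrack, GenomicInterval, Peak
from peakreg.synthetic_data import SyntheticConfig, make_dataset


def make_peak(chrom, start, end, name="p", summit=None, strand="."):
    return Peak(GenomicInterval(chrom, start, end, strand), name, 0.0, summit)


def random_track(rng, chrom="chr1", max_steps=30, span=400, total_reads=1e6):
    """Small random step-function track with gaps, for oracle comparisons."""
    n = int(rng.integers(1, max_steps + 1))
    edges = np.sort(rng.choice(np.arange(span), size=2 * n, replace=False))
    steps = []
    for i in range(0, 2 * n, 2):
        if edges[i] < edges[i + 1]:
            steps.append((int(edges[i]), int(edges[i + 1]),
                          float(rng.uniform(0, 5))))
    if not steps:
        steps = [(0, 1, 1.0)]
    return CoverageTrack({chrom: steps}, total_reads), {chrom: steps}


@pytest.fixture(scope="session")
def dataset():
    """Default-noise synthetic dataset, seed 0."""
    return make_dataset(SyntheticConfig(), seed=0)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free synthetic dataset, seed 0."""
    return make_dataset(SyntheticConfig(noise_sigma=0.0), seed=0)
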