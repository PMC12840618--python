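import numpy as np
import pytest

from tepair.contacts import BinnedContactMap


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def sparse_map(
    rng: np.random.Generator,
    n_bins: int = 200,
    density: float = 0.02,
    max_count: int = 6,
    chrom: str = "chrS1",
    bin_size: int = 600,
) -> BinnedContactMap:
    """Random sparse upper-triangular map over one chromosome."""
    counts = {}
    total = 0
    for bi in range(n_bins):
        for bj in range(bi, min(bi + 70, n_bins)):
            if rng.random() < density:
                c = int(rng.integers(1, max_count + 1))
                counts[(chrom, bi, bj)] = c
                total += c
    return BinnedContactMap(
        bin_size=bin_size,
        counts=counts,
        total_records=total,
        chrom_sizes={chrom: n_bins * bin_size},
    )
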