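import numpy as np
import pytest

from hicdyn import simulate
from hicdyn.contacts import BinTable, ContactMap


@pytest.fixture
def small_config():
    """Small but structured time course: 4 chromosomes x 50 bins at 500 kb."""
    return simulate.HiCSimConfig(
        bins_per_chrom=50,
        seed=7,
        switch_fraction=0.2,
        switch_category_mix=(0.33, 0.49, 0.08, 0.10),
    )


@pytest.fixture
def toy_bins():
    """Two toy chromosomes of 10 x 1 kb bins."""
    return BinTable.from_chrom_sizes({"chr1": 10_000, "chr2": 10_000}, 1_000)


@pytest.fixture
def random_map(toy_bins):
    """Random positive symmetric map on the toy genome."""
    rng = np.random.default_rng(42)
    n = toy_bins.n_bins
    m = rng.uniform(1.0, 10.0, size=(n, n))
    m = (m + m.T) / 2
    return ContactMap(toy_bins, m)
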