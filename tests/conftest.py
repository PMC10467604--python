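import numpy as np
import pandas as pd
import pytest

from methylotype import (
    CountMatrix,
    FilterConfig,
    SimConfig,
    combine_samples,
    filter_sites,
    simulate_cohort,
    tile_100bp,
)

SMALL_COHORT = dict(n_chroms=2, chrom_len_bp=24_000_000, seed=7)


@pytest.fixture(scope="session")
def small_bundle():
    """One-chromosome synthetic cohort shared across the suite."""
    return simulate_cohort(SimConfig(**SMALL_COHORT))


@pytest.fixture(scope="session")
def small_tiles(small_bundle):
    sites = combine_samples(small_bundle.reports)
    return tile_100bp(filter_sites(sites, FilterConfig()))


def make_tile_matrix(meth, total, samples=None, chrom="chr1"):
    """Tiny tile matrix from 2-D count arrays (tiles x samples)."""
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    n = meth.shape[0]
    if samples is None:
        samples = [f"S{i+1}" for i in range(meth.shape[1])]
    feats = pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n) * 100,
        "end": (np.arange(n) + 1) * 100,
        "n_cpgs": 1,
    })
    return CountMatrix(feats,
                       pd.DataFrame(meth, columns=samples),
                       pd.DataFrame(total, columns=samples))
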