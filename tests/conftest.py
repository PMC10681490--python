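import logging

import numpy as np
import pandas as pd
import pytest

from adaptscan.simdata import SimConfig, simulate_dataset
from adaptscan.variants import GenotypeTable

logging.getLogger("adaptscan").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, small synthetic study with planted signal."""
    cfg = SimConfig(
        n_pops=4,
        n_per_pop=6,
        L_neutral=600,
        L_adaptive=20,
        beta=0.5,
        drift_scale=0.15,
        pop_coords=[(500.0, 500.0), (1500.0, 500.0), (500.0, 1500.0), (1500.0, 1500.0)],
        raster_extent=(0.0, 0.0, 2000.0, 2000.0),
        raster_cell=50.0,
        smooth_len=400.0,
        seed=7,
    )
    return simulate_dataset(cfg)


def make_table(dosage, positions=None, chrom="chr1", pops=None, **site_cols):
    """Hand-build a GenotypeTable from a (sites x samples) dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    L, n = dosage.shape
    if positions is None:
        positions = 1000 * (np.arange(L) + 1)
    sites = pd.DataFrame(
        {
            "chrom": chrom, "pos": positions,
            "ref": "A", "alt": "G", **site_cols,
        }
    )
    if pops is None:
        pops = ["p1"] * n
    samples = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n)], "population": pops}
    )
    return GenotypeTable(sites=sites, dosage=dosage, samples=samples)
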