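import numpy as np
import pandas as pd
import pytest

import stereopipe as spp
from stereopipe.binning import bin_spots


@pytest.fixture(scope="session")
def small_tissue():
    """40x40 5-stripe tissue with 5 markers per region: quick, well-powered."""
    spec = spp.TissueSimSpec(
        grid_width=40, grid_height=40, n_genes=100, markers_per_region=5, seed=1
    )
    matrix, truth = spp.generate_expression(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def small_bins(small_tissue):
    spec, matrix, truth = small_tissue
    bins = bin_spots(matrix, 1)
    labels = truth.region_of_spots(
        bins.obs["bin_x"].to_numpy(), bins.obs["bin_y"].to_numpy()
    )
    return bins, labels, truth


@pytest.fixture(scope="session")
def default_tissue():
    """The benchmark tissue: 100x100 grid, 5 stripes, fold 8, seed 0."""
    spec = spp.TissueSimSpec(seed=0)
    matrix, truth = spp.generate_expression(spec)
    return spec, matrix, truth


def toy_spot_matrix(records):
    """Build a SpotMatrix from (gene, x, y, count) tuples."""
    df = pd.DataFrame(records, columns=["geneID", "x", "y", "MIDCount"])
    return spp.SpotMatrix(df)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
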