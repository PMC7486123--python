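"""Shared fixtures: scaled-down simulations and toy matrices.

Unit tests run on small synthetic instances for speed; the acceptance tests
in test_acceptance.py use the generator defaults.
"""

import numpy as np
import pandas as pd
import pytest

from amygmap import synthdata as sd
from amygmap.containers import CountMatrix


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down two-population simulation for unit tests."""
    return sd.ScSimConfig(
        n_cells=400, n_genes=2500, n_de_genes=120, n_gradient_genes_per_pop=15, seed=11
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return sd.gen_counts(small_cfg)


@pytest.fixture(scope="session")
def template():
    return sd.default_template("intermediate")


@pytest.fixture(scope="session")
def spatial_sim(template):
    cfg = sd.SpatialSimConfig(template=template, n_cells_per_section=600, seed=21)
    return sd.gen_spatial_cells(cfg)


def toy_counts(mat, genes=None, cells=None):
    """Build a CountMatrix from a nested list (genes x cells)."""
    mat = np.asarray(mat)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    cells = cells or [f"c{j}" for j in range(mat.shape[1])]
    return CountMatrix(pd.DataFrame(mat, index=genes, columns=cells))


@pytest.fixture
def toy_counts_factory():
    return toy_counts
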