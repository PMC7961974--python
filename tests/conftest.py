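"""Shared fixtures: one default synthetic cohort and its trained SOM.

Session-scoped so the (most expensive) SOM training runs once; all
randomness is seeded for bit-reproducible runs.
"""

import numpy as np
import pytest

from cdsom import CohortConfig, preprocess, simulate_cohort, train_som

SEED = 1
GRID = 20
EPOCHS = 50


@pytest.fixture(scope="session")
def cohort():
    """(raw expression, phenotype table, truth) at the default config."""
    return simulate_cohort(CohortConfig(seed=SEED))


@pytest.fixture(scope="session")
def centralized(cohort):
    em, _, _ = cohort
    return preprocess(em)


@pytest.fixture(scope="session")
def som_model(centralized):
    return train_som(centralized, grid_rows=GRID, grid_cols=GRID,
                     epochs=EPOCHS, seed=SEED)


@pytest.fixture(scope="session")
def truth(cohort):
    return cohort[2]


@pytest.fixture(scope="session")
def phenotype(cohort):
    return cohort[1]


@pytest.fixture(scope="session")
def footprints(som_model, truth):
    """Planted-module BMU footprints: module label -> set of node indices."""
    g2n = dict(zip(som_model.gene_ids, som_model.gene_to_node))
    return {
        lab: {int(g2n[g]) for g in truth.module_genes(lab)} for lab in "ABCDE"
    }


@pytest.fixture(scope="session")
def cd_labels(phenotype):
    return (phenotype["diagnosis"] == "CD").to_numpy()
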