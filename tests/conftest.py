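"""Shared fixtures: small synthetic studies and trained models.

All fixtures are generated programmatically and seeded; the expensive ones
(trained models) are session-scoped so the suite trains each model once.
"""

from __future__ import annotations

import numpy as np
import pytest

from gmvae import (
    EncoderSpec,
    SimulationConfig,
    TrainConfig,
    build_mask,
    init_model,
    plant_differential,
    simulate,
    train,
)

# study conditions for the fast shared fixtures: 600 cells, 300 genes,
# 10 modules of 28 genes (10% overlap), 20 unannotated genes -- the
# smallest study at which module recovery is reliable (median r ~ 0.9)
SMALL_CONFIG = SimulationConfig(
    n_cells_per_group=300,
    n_genes=300,
    n_modules=10,
    genes_per_module=28,
    module_overlap_fraction=0.1,
    n_unannotated_genes=20,
    seed=3,
)

# a graded set of condition effects so differential rankings are nontrivial
PLANTED_SHIFTS = {
    "module_02": 3.0,
    "module_05": -2.0,
    "module_06": 1.5,
}


def train_small(adata, collection, seed=0, n_fc=2, max_epochs=120):
    mask = build_mask(collection, list(adata.var_names), n_fc=n_fc)
    model = init_model(mask, encoder_spec=EncoderSpec(n_hidden=64, seed=seed))
    model, history = train(
        model, adata, TrainConfig(max_epochs=max_epochs, patience=20, seed=seed)
    )
    return model, history


@pytest.fixture(scope="session")
def small_sim():
    """Null study: no condition effects planted."""
    adata, collection, truth = simulate(SMALL_CONFIG)
    return adata, collection, truth


@pytest.fixture(scope="session")
def planted_sim():
    """Study with graded condition effects on three modules."""
    cfg = SMALL_CONFIG
    for mod, eff in PLANTED_SHIFTS.items():
        cfg = plant_differential(cfg, [mod], eff)
    adata, collection, truth = simulate(cfg)
    return adata, collection, truth


@pytest.fixture(scope="session")
def trained_null(small_sim):
    adata, collection, truth = small_sim
    model, history = train_small(adata, collection)
    return adata, collection, truth, model, history


@pytest.fixture(scope="session")
def trained_planted(planted_sim):
    adata, collection, truth = planted_sim
    model, history = train_small(adata, collection)
    return adata, collection, truth, model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
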