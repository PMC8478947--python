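"""Projection of (possibly out-of-sample) data onto a trained model.

A trained model defines a fixed gene universe.  New data are reconciled to
it: genes the model knows but the data lack are zero-filled (with a
warning), extra genes are dropped, and projection refuses to run below 50%
gene overlap, where module activities would be meaningless.  Activities are
the raw posterior means of the module (GMV) nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .data import dense_X
from .model import GeneModuleVAE

logger = logging.getLogger(__name__)

__all__ = ["ActivityMatrix", "project", "reconstruct", "reconcile_genes"]


@dataclass
class ActivityMatrix:
    """Cells x gene-module activity matrix (posterior means of GMV nodes)."""

    values: np.ndarray
    latent_names: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_ids), len(self.latent_names)):
            raise ValueError("activity matrix shape inconsistent with labels")
        if not np.isfinite(self.values).all():
            raise ValueError("activity matrix must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.latent_names)

    def attach(self, adata: ad.AnnData, key: str = "X_gmv") -> None:
        """Store the activities in ``adata.obsm[key]`` (cell order must
        match) with the module names in ``adata.uns[key + "_names"]``."""
        if list(map(str, adata.obs_names)) != self.cell_ids:
            raise ValueError("cell identifiers do not match adata.obs_names")
        adata.obsm[key] = self.values
        adata.uns[key + "_names"] = list(self.latent_names)


def reconcile_genes(
    model: GeneModuleVAE, data: ad.AnnData, min_overlap: float = 0.5
) -> np.ndarray:
    """Return the data matrix reordered to the model's gene order.

    Missing model genes are zero-filled (warned); genes unknown to the model
    are dropped.  Raises when fewer than ``min_overlap`` of the model's
    genes are present.
    """
    X = dense_X(data)
    data_genes = list(data.var_names)
    if data_genes == model.genes:
        return X
    index = {g: i for i, g in enumerate(data_genes)}
    cols = np.array([index.get(g, -1) for g in model.genes])
    present = cols >= 0
    overlap = present.mean()
    if overlap < min_overlap:
        raise ValueError(
            f"only {overlap:.0%} of the model's {len(model.genes)} genes are in "
            f"the dataset (< {min_overlap:.0%}); projection would be meaningless"
        )
    if not present.all():
        logger.warning(
            "zero-filling %d of %d model genes missing from the dataset",
            int((~present).sum()), len(model.genes),
        )
    out = np.zeros((X.shape[0], len(model.genes)))
    out[:, present] = X[:, cols[present]]
    return out


def project(
    model: GeneModuleVAE,
    data: ad.AnnData,
    covariate_key: str | None = None,
) -> ActivityMatrix:
    """Gene-module activities (posterior means of GMV nodes) for each cell.

    Deterministic: dropout disabled, no sampling.
    """
    X = reconcile_genes(model, data)
    covs = _covariates(model, data, covariate_key)
    post = model.encode(X, covariates=covs)
    gmv_cols = model.mask.columns_of("gmv")
    return ActivityMatrix(
        post.mu[:, gmv_cols], model.gmv_names, list(map(str, data.obs_names))
    )


def reconstruct(
    model: GeneModuleVAE,
    data: ad.AnnData,
    covariate_key: str | None = None,
) -> np.ndarray:
    """Deterministic reconstruction: decode the posterior mean, with
    covariate coordinates set from each cell's label."""
    X = reconcile_genes(model, data)
    covs = _covariates(model, data, covariate_key)
    post = model.encode(X, covariates=covs)
    return model.decode(post.mu)


def _covariates(
    model: GeneModuleVAE, data: ad.AnnData, covariate_key: str | None
) -> Sequence | None:
    if model.layout.n_covariate == 0:
        return None
    if covariate_key is None:
        raise ValueError("model has covariate nodes; covariate_key is required")
    return data.obs[covariate_key].astype(str).to_numpy()
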