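"""ELBO training loop.

The objective maximized is the evidence lower bound

    L(x) = E_q[log p(x | z)] - KL(q(z | x) || N(0, I)),

with a Gaussian unit-variance observation model on log-normalized input
(the reconstruction term is mean squared error up to constants), a single
reparameterized draw per cell per step, and the closed-form KL to the
standard-normal prior.  Optimization is Adam; after every step the decoder
is projected back onto its constraint set (masked entries zero, weights
nonnegative).  Early stopping monitors the validation ELBO and restores the
best checkpoint.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from ._nn import Adam
from .data import dense_X
from .model import GeneModuleVAE

__all__ = ["TrainConfig", "TrainHistory", "kl_to_standard_normal", "elbo_terms", "train"]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults follow the published run (lr 5e-4, up to 300 epochs, 80/20
    train/validation split, early-stopping patience 20); batch size and KL
    weight are free choices.
    """

    learning_rate: float = 5e-4
    max_epochs: int = 300
    batch_size: int = 128
    train_fraction: float = 0.8
    patience: int = 20
    kl_weight: float = 1.0
    kl_warmup_epochs: int = 0  # optional linear warm-up of the KL weight
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be nonnegative")


@dataclass
class TrainHistory:
    """Per-epoch ELBO bookkeeping (negative ELBO = loss being minimized)."""

    train_elbo: list[float] = field(default_factory=list)
    val_elbo: list[float] = field(default_factory=list)
    train_recon: list[float] = field(default_factory=list)
    train_kl: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_elbo)),
                "train_elbo": self.train_elbo,
                "val_elbo": self.val_elbo,
                "train_recon": self.train_recon,
                "train_kl": self.train_kl,
            }
        )


def kl_to_standard_normal(mu: np.ndarray, sigma: np.ndarray) -> float:
    """Closed-form KL( N(mu, diag sigma^2) || N(0, I) ).

    Equals ``sum_j 0.5 * (mu_j^2 + sigma_j^2 - 1 - ln sigma_j^2)``; zero iff
    mu = 0 and sigma = 1.
    """
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if (sigma <= 0).any():
        raise ValueError("sigma must be strictly positive")
    return float(0.5 * np.sum(mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma)))


def elbo_terms(
    model: GeneModuleVAE,
    batch: np.ndarray,
    covariates: Sequence | None = None,
    seed: int | np.random.Generator = 0,
    kl_weight: float = 1.0,
) -> tuple[float, float, float]:
    """Evaluate ``(elbo, reconstruction, kl)`` on a batch, one Monte-Carlo
    draw per cell, no dropout (evaluation mode).

    ``elbo = -(reconstruction + kl_weight * kl)``, both terms per-cell
    means; the reconstruction term omits the constant ``G/2 * ln(2 pi)``.
    """
    batch = np.asarray(batch, dtype=np.float64)
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    rng = np.random.default_rng(seed)
    onehot = model.covariate_onehot(covariates, batch.shape[0])
    recon, kl, _ = model.loss_and_grads(
        batch, onehot, rng, kl_weight=kl_weight, train=False
    )
    return -(recon + kl_weight * kl), recon, kl


def train(
    model: GeneModuleVAE,
    data: ad.AnnData,
    config: TrainConfig | None = None,
    covariate_key: str | None = None,
) -> tuple[GeneModuleVAE, TrainHistory]:
    """Fit the model on an AnnData of log-normalized expression.

    The cells are split once into train/validation by ``train_fraction``
    (seeded); each epoch shuffles minibatches, takes Adam steps on the
    negative ELBO, re-projects the decoder constraints, then scores the
    validation ELBO.  Stops after ``patience`` epochs without improvement
    and returns the model restored to its best validation checkpoint.
    """
    config = config or TrainConfig()
    if list(data.var_names) != model.genes:
        raise ValueError("dataset gene order does not match the model's mask")
    X = dense_X(data)
    n = X.shape[0]
    covs = None
    if model.layout.n_covariate:
        if covariate_key is None:
            raise ValueError("model has covariate nodes; covariate_key is required")
        covs = data.obs[covariate_key].astype(str).to_numpy()
    onehot_all = model.covariate_onehot(covs, n) if covs is not None else None

    history = TrainHistory()
    if config.max_epochs == 0:
        return model, history

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_train = max(1, int(round(config.train_fraction * n)))
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    if config.train_fraction < 1 and len(val_idx) == 0:
        raise ValueError("validation split is empty; lower train_fraction or add cells")
    monitor_idx = val_idx if len(val_idx) else train_idx

    # fit the encoder input offset and warm-start the decoder bias at the
    # per-gene training mean: Adam's bounded per-step movement would
    # otherwise spend most of the run fitting the mean expression level
    gene_mean = X[train_idx].mean(axis=0)
    model.x_center = gene_mean
    if model.use_bias:
        model.params["bias"][:] = gene_mean

    opt = Adam(model.params, lr=config.learning_rate)
    best_state: dict[str, np.ndarray] | None = None
    best_val = -np.inf
    stale = 0

    for epoch in range(config.max_epochs):
        if config.kl_warmup_epochs > 0:
            klw = config.kl_weight * min(1.0, (epoch + 1) / config.kl_warmup_epochs)
        else:
            klw = config.kl_weight
        order = rng.permutation(train_idx)
        ep_recon = ep_kl = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            oh = onehot_all[idx] if onehot_all is not None else None
            try:
                recon, kl, grads = model.loss_and_grads(
                    X[idx], oh, rng, kl_weight=klw, train=True
                )
            except FloatingPointError as e:
                raise FloatingPointError(f"divergence at epoch {epoch}: {e}") from e
            opt.step(grads)
            model.constrain()
            ep_recon += recon
            ep_kl += kl
            n_batches += 1
        ep_recon /= n_batches
        ep_kl /= n_batches
        val_elbo, _, _ = elbo_terms(
            model,
            X[monitor_idx],
            covs[monitor_idx] if covs is not None else None,
            seed=np.random.default_rng(config.seed + 1),
            kl_weight=config.kl_weight,
        )
        history.train_recon.append(ep_recon)
        history.train_kl.append(ep_kl)
        history.train_elbo.append(-(ep_recon + klw * ep_kl))
        history.val_elbo.append(val_elbo)
        if val_elbo > best_val:
            best_val = val_elbo
            best_state = {k: v.copy() for k, v in model.params.items()}
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        model.params.update({k: v.copy() for k, v in best_state.items()})
    model.constrain()
    return model, history
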