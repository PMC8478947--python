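"""The interpretable VAE: nonlinear Gaussian encoder, masked linear decoder.

The generative model assumes log-normalized expression ``x`` arises from
latent gene-module activities ``z`` through a single linear layer whose
weights are (a) restricted by the binary mask ``M`` to each module's member
genes and (b) constrained nonnegative, so that a larger ``z_j`` can only
increase the predicted expression of module ``j``'s genes.  The variational
posterior ``q(z | x) = N(mu(x), diag sigma^2(x))`` is produced by a
multilayer ReLU encoder; the prior is standard normal.  Latent nodes come in
three kinds:

* ``gmv``  -- one per gene module; the interpretable activities;
* ``fc``   -- optional fully-connected nodes that absorb variance the
  modules cannot explain (recommended: 16 or fewer, so the module nodes
  keep the biological signal);
* ``covariate`` -- one per level of a categorical covariate (e.g. batch);
  before decoding, these coordinates are overwritten with the cell's one-hot
  covariate code, conditioning the generative process on the label.

Gradients are written out explicitly (see the backward pass in
:meth:`GeneModuleVAE.loss_and_grads`); a finite-difference check in the test
suite guards the derivation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import kaiming_uniform, xavier_uniform
from .modules import NODE_COVARIATE, NODE_FC, NODE_GMV, MaskMatrix

logger = logging.getLogger(__name__)

_LOGVAR_MIN, _LOGVAR_MAX = -12.0, 10.0
_FC_RECOMMENDED_MAX = 16


@dataclass
class LatentLayout:
    """Bookkeeping of the latent-space composition."""

    n_gmv: int
    n_fc: int
    n_covariate: int
    covariate_levels: list[str]
    latent_names: list[str]

    def __post_init__(self) -> None:
        if self.n_gmv + self.n_fc + self.n_covariate != len(self.latent_names):
            raise ValueError("latent_names length must equal n_gmv + n_fc + n_covariate")
        if self.n_covariate and len(self.covariate_levels) != self.n_covariate:
            raise ValueError(
                f"{self.n_covariate} covariate nodes require "
                f"{self.n_covariate} covariate levels, got {len(self.covariate_levels)}"
            )
        if self.n_fc > _FC_RECOMMENDED_MAX:
            logger.warning(
                "n_fc=%d fully-connected nodes exceeds the recommended maximum "
                "of %d; module activities may lose biological signal",
                self.n_fc, _FC_RECOMMENDED_MAX,
            )

    @property
    def n_latent(self) -> int:
        return self.n_gmv + self.n_fc + self.n_covariate

    @classmethod
    def from_mask(
        cls, mask: MaskMatrix, covariate_levels: Sequence[str] = ()
    ) -> "LatentLayout":
        kinds = mask.node_kinds
        return cls(
            n_gmv=sum(k == NODE_GMV for k in kinds),
            n_fc=sum(k == NODE_FC for k in kinds),
            n_covariate=sum(k == NODE_COVARIATE for k in kinds),
            covariate_levels=list(covariate_levels),
            latent_names=list(mask.latent_names),
        )


@dataclass
class EncoderSpec:
    """Encoder hyperparameters: ``n_layers`` hidden ReLU layers of
    ``n_hidden`` units with input dropout ``dropout_rate`` between layers."""

    n_hidden: int = 800
    n_layers: int = 2
    dropout_rate: float = 0.2
    seed: int = 0


@dataclass
class LatentPosterior:
    """Per-cell Gaussian posterior: mean and diagonal standard deviation."""

    mu: np.ndarray     # (cells, latent)
    sigma: np.ndarray  # (cells, latent), strictly positive

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma shapes differ")
        if not np.isfinite(self.mu).all() or not np.isfinite(self.sigma).all():
            raise ValueError("posterior parameters must be finite")
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be strictly positive")

    @property
    def n_cells(self) -> int:
        return self.mu.shape[0]

    @property
    def n_latent(self) -> int:
        return self.mu.shape[1]


def sample_latent(posterior: LatentPosterior, seed: int | np.random.Generator) -> np.ndarray:
    """Reparameterized draw ``z = mu + sigma * eps`` with ``eps ~ N(0, I)``."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(posterior.mu.shape)
    return posterior.mu + posterior.sigma * eps


class GeneModuleVAE:
    """Masked-decoder VAE over a fixed gene universe.

    Parameters are NumPy arrays; training happens in :mod:`gmvae.training`.
    Two invariants hold at all times after :meth:`constrain`: decoder
    weights are exactly zero wherever the mask is zero, and nonnegative
    elsewhere.
    """

    def __init__(
        self,
        mask: MaskMatrix,
        layout: LatentLayout | None = None,
        encoder_spec: EncoderSpec | None = None,
        latent_dropout_rate: float = 0.3,
        use_bias: bool = True,
    ):
        spec = encoder_spec or EncoderSpec()
        layout = layout or LatentLayout.from_mask(mask)
        if layout.n_latent != mask.n_latent:
            raise ValueError(
                f"layout latent dim {layout.n_latent} != mask columns {mask.n_latent}"
            )
        kinds_from_mask = mask.node_kinds
        if (layout.n_gmv, layout.n_fc, layout.n_covariate) != (
            sum(k == NODE_GMV for k in kinds_from_mask),
            sum(k == NODE_FC for k in kinds_from_mask),
            sum(k == NODE_COVARIATE for k in kinds_from_mask),
        ):
            raise ValueError("layout node counts inconsistent with mask node kinds")
        self.mask = mask
        self.layout = layout
        self.spec = spec
        self.latent_dropout_rate = float(latent_dropout_rate)
        self.use_bias = bool(use_bias)
        self.genes = list(mask.genes)
        self._gmv_cols = mask.columns_of(NODE_GMV)
        self._cov_cols = mask.columns_of(NODE_COVARIATE)
        # per-gene encoder input offset, fit from training data; without it
        # the shared mean-expression direction dominates the encoder input
        # and swamps the per-cell signal
        self.x_center = np.zeros(mask.n_genes)
        self._init_params(spec)

    # ---------------------------------------------------------------- init
    def _init_params(self, spec: EncoderSpec) -> None:
        rng = np.random.default_rng(spec.seed)
        G, D = self.mask.n_genes, self.mask.n_latent
        sizes = [G] + [spec.n_hidden] * spec.n_layers
        self.params: dict[str, np.ndarray] = {}
        for i in range(spec.n_layers):
            self.params[f"W{i}"] = kaiming_uniform(rng, sizes[i], sizes[i + 1])
            self.params[f"b{i}"] = np.zeros(sizes[i + 1])
        self.params["Wm"] = xavier_uniform(rng, sizes[-1], D)
        self.params["bm"] = np.zeros(D)
        self.params["Wv"] = xavier_uniform(rng, sizes[-1], D)
        self.params["bv"] = np.zeros(D)
        # decoder: Xavier draw clamped to >= 0; masked entries exactly zero
        theta = xavier_uniform(rng, D, G).T  # (G, D)
        self.params["theta"] = np.maximum(theta, 0.0) * self.mask.mask
        self.params["bias"] = np.zeros(G)

    # ----------------------------------------------------------- utilities
    @property
    def n_genes(self) -> int:
        return self.mask.n_genes

    @property
    def n_latent(self) -> int:
        return self.mask.n_latent

    @property
    def gmv_names(self) -> list[str]:
        return self.mask.gmv_names

    def constrain(self) -> "GeneModuleVAE":
        """Project the decoder back onto the constraint set: masked entries
        to exact zero, negative unmasked entries to zero.  Idempotent."""
        theta = self.params["theta"]
        np.maximum(theta, 0.0, out=theta)
        theta *= self.mask.mask
        return self

    def covariate_onehot(self, covariates: Sequence | None, n_cells: int) -> np.ndarray | None:
        """Map per-cell covariate labels (or integer codes) to one-hot rows."""
        if self.layout.n_covariate == 0:
            return None
        if covariates is None:
            raise ValueError(
                "model has covariate nodes; per-cell covariate labels are required"
            )
        covariates = np.asarray(covariates)
        if len(covariates) != n_cells:
            raise ValueError("covariates length must match number of cells")
        levels = self.layout.covariate_levels
        if np.issubdtype(covariates.dtype, np.integer):
            codes = covariates.astype(int)
            if (codes < 0).any() or (codes >= len(levels)).any():
                raise ValueError("covariate code out of range")
        else:
            lut = {lv: i for i, lv in enumerate(levels)}
            try:
                codes = np.array([lut[str(c)] for c in covariates])
            except KeyError as e:
                raise ValueError(f"unknown covariate level {e.args[0]!r}") from None
        onehot = np.zeros((n_cells, len(levels)))
        onehot[np.arange(n_cells), codes] = 1.0
        return onehot

    # ------------------------------------------------------------- forward
    def _encoder_forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None
    ) -> dict:
        """Run the encoder MLP; ``rng`` enables dropout (training mode)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_genes:
            raise ValueError(
                f"expected cells x {self.n_genes} genes matrix, got shape {X.shape}"
            )
        p = self.spec.dropout_rate
        Xc = X - self.x_center
        cache: dict = {"a": [Xc], "s": [], "drop": []}
        a = Xc
        for i in range(self.spec.n_layers):
            s = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
            r = np.maximum(s, 0.0)
            if rng is not None and p > 0:
                keep = (rng.random(r.shape) >= p) / (1.0 - p)
                r = r * keep
                cache["drop"].append(keep)
            else:
                cache["drop"].append(None)
            cache["s"].append(s)
            cache["a"].append(r)
            a = r
        mu = a @ self.params["Wm"] + self.params["bm"]
        logvar_raw = a @ self.params["Wv"] + self.params["bv"]
        logvar = np.clip(logvar_raw, _LOGVAR_MIN, _LOGVAR_MAX)
        cache["mu"] = mu
        cache["logvar"] = logvar
        cache["clip"] = (logvar_raw > _LOGVAR_MIN) & (logvar_raw < _LOGVAR_MAX)
        return cache

    def encode(
        self, X: np.ndarray, covariates: Sequence | None = None
    ) -> LatentPosterior:
        """Variational posterior in evaluation mode (dropout disabled).

        Covariate coordinates of the posterior are deterministically set
        from the covariate codes: mean = one-hot code, std = 1e-6 (they are
        labels, not inferred quantities).
        """
        cache = self._encoder_forward(np.asarray(X, dtype=np.float64), rng=None)
        mu = cache["mu"].copy()
        sigma = np.exp(0.5 * cache["logvar"])
        onehot = self.covariate_onehot(covariates, mu.shape[0])
        if onehot is not None:
            mu[:, self._cov_cols] = onehot
            sigma[:, self._cov_cols] = 1e-6
        return LatentPosterior(mu, sigma)

    def decode(self, Z: np.ndarray) -> np.ndarray:
        """Linear reconstruction ``Z @ (theta * M)^T (+ bias)``."""
        Z = np.asarray(Z, dtype=np.float64)
        if Z.ndim != 2 or Z.shape[1] != self.n_latent:
            raise ValueError(
                f"expected cells x {self.n_latent} latent matrix, got shape {Z.shape}"
            )
        W = self.params["theta"] * self.mask.mask
        Xhat = Z @ W.T
        if self.use_bias:
            Xhat = Xhat + self.params["bias"]
        return Xhat

    # ------------------------------------------------- loss and gradients
    def loss_and_grads(
        self,
        X: np.ndarray,
        covariate_onehot: np.ndarray | None,
        rng: np.random.Generator,
        kl_weight: float = 1.0,
        train: bool = True,
    ) -> tuple[float, float, dict[str, np.ndarray]]:
        """One stochastic evaluation of the negative ELBO and its gradients.

        Returns ``(recon, kl, grads)`` where ``recon`` is the mean per-cell
        Gaussian reconstruction error ``0.5 * ||x - xhat||^2`` (the negative
        log-likelihood up to an additive constant, unit observation
        variance), ``kl`` the mean per-cell KL to the standard-normal prior,
        and the loss being minimized is ``recon + kl_weight * kl``.  A
        single reparameterized draw per cell approximates the expectation.
        """
        X = np.asarray(X, dtype=np.float64)
        B = X.shape[0]
        if B == 0:
            raise ValueError("empty batch")
        cache = self._encoder_forward(X, rng=rng if train else None)
        mu, logvar = cache["mu"], cache["logvar"]
        sigma = np.exp(0.5 * logvar)
        eps = rng.standard_normal(mu.shape)
        z = mu + sigma * eps
        zmask = None
        if train and self.latent_dropout_rate > 0:
            pz = self.latent_dropout_rate
            zmask = (rng.random(z.shape) >= pz) / (1.0 - pz)
            z = z * zmask
        if covariate_onehot is not None:
            z[:, self._cov_cols] = covariate_onehot
        W = self.params["theta"] * self.mask.mask
        Xhat = z @ W.T
        if self.use_bias:
            Xhat = Xhat + self.params["bias"]

        resid = Xhat - X
        recon = 0.5 * float(np.sum(resid**2)) / B
        kl = 0.5 * float(np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar)) / B
        for name, val in (("reconstruction", recon), ("kl", kl)):
            if not np.isfinite(val):
                raise FloatingPointError(f"non-finite {name} term in the loss")

        # ---- backward ----
        d_xhat = resid / B
        grads: dict[str, np.ndarray] = {}
        grads["theta"] = (d_xhat.T @ z) * self.mask.mask
        grads["bias"] = (
            d_xhat.sum(axis=0) if self.use_bias else np.zeros(self.n_genes)
        )
        d_z = d_xhat @ W
        if covariate_onehot is not None:
            d_z[:, self._cov_cols] = 0.0
        if zmask is not None:
            d_z = d_z * zmask
        d_mu = d_z + kl_weight * mu / B
        d_logvar = (
            d_z * eps * 0.5 * sigma + kl_weight * 0.5 * (np.exp(logvar) - 1.0) / B
        )
        d_logvar = d_logvar * cache["clip"]
        aL = cache["a"][-1]
        grads["Wm"] = aL.T @ d_mu
        grads["bm"] = d_mu.sum(axis=0)
        grads["Wv"] = aL.T @ d_logvar
        grads["bv"] = d_logvar.sum(axis=0)
        d_a = d_mu @ self.params["Wm"].T + d_logvar @ self.params["Wv"].T
        for i in reversed(range(self.spec.n_layers)):
            keep = cache["drop"][i]
            if keep is not None:
                d_a = d_a * keep
            d_s = d_a * (cache["s"][i] > 0)
            grads[f"W{i}"] = cache["a"][i].T @ d_s
            grads[f"b{i}"] = d_s.sum(axis=0)
            d_a = d_s @ self.params[f"W{i}"].T
        return recon, kl, grads

    # ----------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        """Write a checkpoint: an ``.npz`` of arrays plus a JSON sidecar with
        names, shapes and configuration so a projection is reproducible."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = dict(self.params)
        arrays["__mask__"] = self.mask.mask
        arrays["__x_center__"] = self.x_center
        np.savez(path, **arrays)
        sidecar = {
            "genes": self.genes,
            "latent_names": self.mask.latent_names,
            "node_kinds": self.mask.node_kinds,
            "covariate_levels": self.layout.covariate_levels,
            "encoder": {
                "n_hidden": self.spec.n_hidden,
                "n_layers": self.spec.n_layers,
                "dropout_rate": self.spec.dropout_rate,
                "seed": self.spec.seed,
            },
            "latent_dropout_rate": self.latent_dropout_rate,
            "use_bias": self.use_bias,
            "param_shapes": {k: list(v.shape) for k, v in self.params.items()},
        }
        with path.with_suffix(path.suffix + ".json").open("w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "GeneModuleVAE":
        path = Path(path)
        with path.with_suffix(path.suffix + ".json").open() as fh:
            side = json.load(fh)
        arrays = np.load(path)
        mask = MaskMatrix(
            arrays["__mask__"], side["genes"], side["latent_names"], side["node_kinds"]
        )
        model = cls(
            mask,
            layout=LatentLayout.from_mask(mask, side["covariate_levels"]),
            encoder_spec=EncoderSpec(**side["encoder"]),
            latent_dropout_rate=side["latent_dropout_rate"],
            use_bias=side["use_bias"],
        )
        for k in model.params:
            model.params[k] = np.asarray(arrays[k], dtype=np.float64)
        model.x_center = np.asarray(arrays["__x_center__"], dtype=np.float64)
        return model


def init_model(
    mask: MaskMatrix,
    layout: LatentLayout | None = None,
    encoder_spec: EncoderSpec | None = None,
    **kwargs,
) -> GeneModuleVAE:
    """Construct a model with seeded, reproducible initialization."""
    return GeneModuleVAE(mask, layout=layout, encoder_spec=encoder_spec, **kwargs)
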