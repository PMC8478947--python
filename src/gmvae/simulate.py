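"""Synthetic single-cell data with planted gene-module structure.

The generator mirrors the model's own generative assumptions so that every
downstream component is testable with known ground truth: per-cell module
activities ``Z*`` are drawn from per-condition normal priors, expression is
``X = Z* W*^T`` with sparse nonnegative loadings ``W*`` whose support
defines the emitted gene-module collection, plus optional additive per-gene
batch offsets and Gaussian noise, shifted to a nonnegative
log-normalized-like scale.  Unannotated genes carry pure noise.  Condition
effects are planted by shifting a module's activity mean between
conditions (:func:`plant_differential`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .modules import GeneModule, GeneModuleCollection, write_gmt

__all__ = ["SimulationConfig", "GroundTruth", "simulate", "plant_differential"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults give a 2,000-cell, 1,000-gene, 20-module dataset: two
    conditions of 1,000 cells each, one batch, unit-variance module
    activities, moderate observation noise.  ``activity_shift`` maps a
    module name to its per-condition mean offsets (the planted condition
    effect); ``module_overlap_fraction`` makes consecutive modules share
    that fraction of their genes.
    """

    n_cells_per_group: int = 1000
    conditions: tuple[str, ...] = ("control", "perturbed")
    batches: tuple[str, ...] = ("batch0",)
    n_genes: int = 1000
    n_modules: int = 20
    genes_per_module: int = 45
    module_overlap_fraction: float = 0.1
    n_unannotated_genes: int = 100
    activity_mean: float = 0.0
    activity_std: float = 1.0
    activity_shift: dict = field(default_factory=dict)  # module -> {condition: delta}
    loading_scale: float = 1.0
    gene_baseline_std: float = 1.0
    noise_std: float = 0.5
    batch_offset_std: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells_per_group, self.n_genes, self.n_modules,
               self.genes_per_module) <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.module_overlap_fraction < 1:
            raise ValueError("module_overlap_fraction must be in [0, 1)")
        if self.noise_std <= 0 or self.loading_scale <= 0:
            raise ValueError("noise_std and loading_scale must be positive")
        if self.n_unannotated_genes < 0 or self.batch_offset_std < 0:
            raise ValueError("n_unannotated_genes and batch_offset_std must be >= 0")

    @property
    def module_names(self) -> list[str]:
        return [f"module_{i:02d}" for i in range(self.n_modules)]


@dataclass
class GroundTruth:
    """What the generator planted, for comparison with what a model infers."""

    activities: pd.DataFrame       # cells x modules (Z*)
    loadings: np.ndarray           # genes x modules (W*, sparse nonnegative)
    gene_baseline: np.ndarray      # per-gene baseline expression level
    conditions: np.ndarray
    batches: np.ndarray
    differential: pd.DataFrame     # module, condition, effect_size rows


def _module_supports(config: SimulationConfig) -> list[np.ndarray]:
    """Consecutive gene blocks; adjacent modules share ``overlap`` genes."""
    gpm = config.genes_per_module
    shared = int(round(config.module_overlap_fraction * gpm))
    step = gpm - shared
    needed = gpm + step * (config.n_modules - 1)
    budget = config.n_genes - config.n_unannotated_genes
    if needed > budget:
        raise ValueError(
            f"module construction impossible: {config.n_modules} modules of "
            f"{gpm} genes with overlap {config.module_overlap_fraction} need "
            f"{needed} genes but only {budget} annotated genes are available"
        )
    return [np.arange(j * step, j * step + gpm) for j in range(config.n_modules)]


def simulate(
    config: SimulationConfig | None = None,
) -> tuple[ad.AnnData, GeneModuleCollection, GroundTruth]:
    """Draw one dataset; fully reproducible from ``config.seed``."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genes = [f"gene_{i:04d}" for i in range(config.n_genes)]
    supports = _module_supports(config)

    # sparse nonnegative loadings on each module's support
    W = np.zeros((config.n_genes, config.n_modules))
    for j, sup in enumerate(supports):
        W[sup, j] = rng.uniform(0.3, 1.0, size=len(sup)) * config.loading_scale

    groups = [(c, b) for c in config.conditions for b in config.batches]
    n_cells = config.n_cells_per_group * len(groups)
    conditions = np.empty(n_cells, dtype=object)
    batches = np.empty(n_cells, dtype=object)
    Z = np.zeros((n_cells, config.n_modules))
    names = config.module_names
    row = 0
    for cond, batch in groups:
        nc = config.n_cells_per_group
        sl = slice(row, row + nc)
        conditions[sl] = cond
        batches[sl] = batch
        means = np.full(config.n_modules, config.activity_mean)
        for j, name in enumerate(names):
            means[j] += config.activity_shift.get(name, {}).get(cond, 0.0)
        Z[sl] = rng.normal(means, config.activity_std, size=(nc, config.n_modules))
        row += nc

    # per-gene baseline expression: real log-normalized data has strong
    # gene-to-gene mean differences, which the decoder bias must absorb
    baseline = rng.normal(0.0, config.gene_baseline_std, size=config.n_genes)
    X = baseline + Z @ W.T
    if config.batch_offset_std > 0:
        offsets = {
            b: rng.normal(0.0, config.batch_offset_std, size=config.n_genes)
            for b in config.batches
        }
        for b, off in offsets.items():
            X[batches == b] += off
    X += rng.normal(0.0, config.noise_std, size=X.shape)
    X -= X.min()  # shift to a nonnegative, log-normalized-like scale

    obs = pd.DataFrame(
        {
            "condition": pd.Categorical(conditions.astype(str)),
            "batch": pd.Categorical(batches.astype(str)),
        },
        index=[f"cell_{i:05d}" for i in range(n_cells)],
    )
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))

    collection = GeneModuleCollection(
        [
            GeneModule(name, "synthetic", frozenset(genes[i] for i in sup))
            for name, sup in zip(names, supports)
        ]
    )
    diff_rows = [
        {"module": m, "condition": c, "effect_size": d}
        for m, shifts in config.activity_shift.items()
        for c, d in shifts.items()
    ]
    truth = GroundTruth(
        activities=pd.DataFrame(Z, index=obs.index, columns=names),
        loadings=W,
        gene_baseline=baseline,
        conditions=conditions.astype(str),
        batches=batches.astype(str),
        differential=pd.DataFrame(diff_rows, columns=["module", "condition", "effect_size"]),
    )
    return adata, collection, truth


def plant_differential(
    config: SimulationConfig,
    module_ids: list[str],
    effect_size: float,
    condition: str | None = None,
) -> SimulationConfig:
    """Return a config whose named modules differ in activity mean between
    conditions by ``effect_size`` (added to ``condition``, by default the
    last condition listed)."""
    names = set(config.module_names)
    unknown = [m for m in module_ids if m not in names]
    if unknown:
        raise ValueError(f"unknown module id(s): {unknown}")
    condition = condition or config.conditions[-1]
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    shift = {m: dict(v) for m, v in config.activity_shift.items()}
    for m in module_ids:
        shift.setdefault(m, {})
        shift[m][condition] = shift[m].get(condition, 0.0) + effect_size
    return replace(config, activity_shift=shift)


def write_simulation(
    out_dir: str | Path,
    adata: ad.AnnData,
    collection: GeneModuleCollection,
    truth: GroundTruth,
    format: str = "h5ad",
) -> None:
    """Persist a simulated study: dataset (h5ad, dense CSV, or MTX + TSVs),
    modules as GMT, ground truth as TSVs -- so the full pipeline can run
    from files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if format == "h5ad":
        adata.write_h5ad(out / "dataset.h5ad")
    elif format == "csv":
        pd.DataFrame(
            np.asarray(adata.X), index=adata.obs_names, columns=adata.var_names
        ).to_csv(out / "dataset.csv")
        adata.obs.to_csv(out / "obs.tsv", sep="\t")
    elif format == "mtx":
        import scipy.io
        import scipy.sparse

        # genes x cells on disk, 10x convention
        scipy.io.mmwrite(
            str(out / "matrix.mtx"), scipy.sparse.csr_matrix(np.asarray(adata.X).T)
        )
        (out / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
        (out / "features.tsv").write_text("\n".join(adata.var_names) + "\n")
        adata.obs.to_csv(out / "obs.tsv", sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")
    write_gmt(collection, out / "modules.gmt")
    truth.activities.to_csv(out / "true_activities.tsv", sep="\t")
    truth.differential.to_csv(out / "planted_differential.tsv", sep="\t", index=False)
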