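"""Evaluation metrics: silhouette, mean-expression R-squared, top-k overlap.

These are the three quantities used to judge a latent representation: how
well labeled groups separate in the latent space (silhouette, Euclidean
distance), how faithfully the decoder reconstructs gene-level expression
(squared Pearson correlation of per-gene means), and how stable a
differential-module ranking is across settings (proportion of shared
modules among the top k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

__all__ = [
    "MetricReport",
    "silhouette",
    "mean_expression_r2",
    "topk_overlap",
    "repeated_subsample",
]

_EXACT_MAX_CELLS = 10_000


@dataclass
class MetricReport:
    metric: str
    value: float
    grouping: str = ""
    n_cells: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def silhouette(
    embedding: np.ndarray,
    labels: Sequence,
    subsample: int | None = None,
    seed: int = 0,
) -> float:
    """Mean silhouette coefficient ``s(i) = (b(i) - a(i)) / max(a(i), b(i))``
    over cells, with Euclidean distance in the embedding.

    Exact for up to 10^4 cells; above that, pass ``subsample`` for a seeded
    random subset.  Raises if any label has fewer than two cells (its
    intra-cluster distance is undefined).
    """
    X = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ValueError("embedding must be cells x dims matching labels")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette needs >= 2 categories")
    single = uniq[counts < 2]
    if single.size:
        raise ValueError(f"singleton category: {single[0]!r}")
    if subsample is not None and X.shape[0] > subsample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(X.shape[0], size=subsample, replace=False)
        X, labels = X[idx], labels[idx]
    elif subsample is None and X.shape[0] > _EXACT_MAX_CELLS:
        raise ValueError(
            f"exact silhouette limited to {_EXACT_MAX_CELLS} cells; "
            "pass subsample= for a seeded subset"
        )
    return float(silhouette_score(X, labels, metric="euclidean"))


def mean_expression_r2(real: np.ndarray, recon: np.ndarray) -> float:
    """Squared Pearson correlation between the per-gene mean expression of
    the real and reconstructed matrices (not a regression R^2)."""
    real = np.asarray(real, dtype=np.float64)
    recon = np.asarray(recon, dtype=np.float64)
    if real.shape[1] != recon.shape[1]:
        raise ValueError("real and reconstructed matrices must share genes")
    a = real.mean(axis=0)
    b = recon.mean(axis=0)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a mean-expression vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)


def topk_overlap(ranking_a: Sequence[str], ranking_b: Sequence[str], k: int = 50) -> float:
    """Proportion of shared names among the top ``k`` of two rankings."""
    a = list(ranking_a)
    b = list(ranking_b)
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise ValueError("rankings must not contain duplicate names")
    if k > min(len(a), len(b)):
        raise ValueError(f"k={k} exceeds a ranking's length")
    return len(set(a[:k]) & set(b[:k])) / k


def repeated_subsample(
    statistic: Callable[[np.ndarray], float],
    n_items: int,
    subsample: int,
    n_repeats: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and standard deviation of a statistic over seeded random
    subsamples (the error-bar protocol: 100 repetitions by default).

    ``statistic`` receives an index array of length ``subsample``.
    """
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_repeats):
        idx = rng.choice(n_items, size=min(subsample, n_items), replace=False)
        vals.append(statistic(idx))
    vals = np.asarray(vals, dtype=np.float64)
    return float(vals.mean()), float(vals.std())
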