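"""Gene-module collections and the binary decoder mask.

Gene modules (pathways, regulons, marker sets) are the prior knowledge that
wires the decoder: each gene-module variable (GMV) in the latent space may
only reconstruct the genes annotated to its module.  This module parses the
two standard on-disk representations -- GMT gene-set files and two-column
regulator/target edge lists -- reconciles them with a dataset's gene
universe, and builds the binary mask ``M`` (genes x latent nodes) where
``M[i, j]`` is 1 iff gene ``i`` belongs to module ``j``.  Extra
fully-connected (FC) and covariate nodes get all-ones columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NODE_GMV = "gmv"
NODE_FC = "fc"
NODE_COVARIATE = "covariate"


@dataclass(frozen=True)
class GeneModule:
    """A named gene set: ``name``, free-text ``description``, member genes."""

    name: str
    description: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneModuleCollection:
    """Ordered, named gene sets; iteration order is file order.

    Invariants: module names unique; every module non-empty.
    """

    modules: list[GeneModule] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.name for m in self.modules]
        if len(names) != len(set(names)):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate module name: {dup!r}")
        for m in self.modules:
            if len(m.genes) == 0:
                raise ValueError(f"module {m.name!r} has no genes")

    def __iter__(self) -> Iterator[GeneModule]:
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def __getitem__(self, key: int | str) -> GeneModule:
        if isinstance(key, str):
            for m in self.modules:
                if m.name == key:
                    return m
            raise KeyError(key)
        return self.modules[key]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.modules]

    def uppercased(self) -> "GeneModuleCollection":
        """Return a copy with all gene identifiers upper-cased.

        Convenience for reconciling symbol conventions (e.g. mouse Abc1 vs
        human ABC1); matching elsewhere is exact and case-sensitive.
        """
        return GeneModuleCollection(
            [
                GeneModule(m.name, m.description, frozenset(g.upper() for g in m.genes))
                for m in self.modules
            ]
        )


def read_gmt(path: str | Path) -> GeneModuleCollection:
    """Parse a GMT file (tab-separated: name, description, genes...).

    One module per line, genes deduplicated, file order preserved.  Lines
    with fewer than three fields raise with the offending line number.
    """
    path = Path(path)
    modules: list[GeneModule] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: module {name!r} has no genes")
            modules.append(GeneModule(name, description, frozenset(genes)))
    return GeneModuleCollection(modules)


def write_gmt(collection: GeneModuleCollection, path: str | Path) -> None:
    """Write a collection as GMT; genes within a module are sorted so the
    read/write round-trip is deterministic."""
    path = Path(path)
    with path.open("w") as fh:
        for m in collection:
            fh.write("\t".join([m.name, m.description, *sorted(m.genes)]) + "\n")


def read_regulon_table(
    path: str | Path, *, header: bool = False, sep: str = "\t"
) -> GeneModuleCollection:
    """Parse a two-column (regulator, target) edge list into modules.

    One module per regulator, in order of first appearance; a regulator
    listed as its own target keeps the self-edge.  Used for ARACNe-style
    networks where each transcription factor's predicted targets form a
    regulon.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, header=0 if header else None, dtype=str)
    except pd.errors.EmptyDataError:
        return GeneModuleCollection([])
    if df.shape[1] < 2:
        if df.shape[0] == 0 and df.shape[1] == 0:
            return GeneModuleCollection([])
        raise ValueError(
            f"{path}: regulon table needs >= 2 columns (regulator, target), "
            f"got {df.shape[1]}"
        )
    regs = df.iloc[:, 0].astype(str)
    targets = df.iloc[:, 1].astype(str)
    order: list[str] = []
    members: dict[str, set[str]] = {}
    for reg, tgt in zip(regs, targets):
        if reg not in members:
            members[reg] = set()
            order.append(reg)
        members[reg].add(tgt)
    return GeneModuleCollection(
        [GeneModule(r, f"regulon:{r}", frozenset(members[r])) for r in order]
    )


@dataclass
class MaskMatrix:
    """Binary genes x latent-nodes connectivity mask.

    GMV columns connect a latent node only to its module's genes; ``fc`` and
    ``covariate`` columns are all-ones (fully connected).  ``genes`` records
    the row order the mask was built against.
    """

    mask: np.ndarray  # (n_genes, n_latent) of {0., 1.}
    genes: list[str]
    latent_names: list[str]
    node_kinds: list[str]  # per column: gmv | fc | covariate

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.float64)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D (genes x latent)")
        if self.mask.shape != (len(self.genes), len(self.latent_names)):
            raise ValueError(
                f"mask shape {self.mask.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.latent_names)} nodes"
            )
        if len(self.node_kinds) != len(self.latent_names):
            raise ValueError("node_kinds length must match latent_names")
        if not np.isin(self.mask, (0.0, 1.0)).all():
            raise ValueError("mask entries must be binary")

    @property
    def n_genes(self) -> int:
        return self.mask.shape[0]

    @property
    def n_latent(self) -> int:
        return self.mask.shape[1]

    @property
    def n_gmv(self) -> int:
        return sum(k == NODE_GMV for k in self.node_kinds)

    @property
    def gmv_names(self) -> list[str]:
        return [n for n, k in zip(self.latent_names, self.node_kinds) if k == NODE_GMV]

    def columns_of(self, kind: str) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.node_kinds) if k == kind], dtype=int)


def build_mask(
    collection: GeneModuleCollection,
    genes: Sequence[str],
    n_fc: int = 0,
    n_covariate: int = 0,
    min_genes: int = 5,
) -> MaskMatrix:
    """Build the decoder mask for a gene universe.

    Modules are intersected with ``genes``; those retaining fewer than
    ``min_genes`` members are dropped with a warning.  FC then covariate
    all-ones columns are appended after the GMV columns.

    Raises if no GMV column survives: either lower ``min_genes`` or check
    that gene identifier conventions (symbol case, species) match.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene universe is empty")
    if len(set(genes)) != len(genes):
        raise ValueError("gene universe contains duplicates")
    if n_fc < 0 or n_covariate < 0:
        raise ValueError("n_fc and n_covariate must be >= 0")

    index = {g: i for i, g in enumerate(genes)}
    cols: list[np.ndarray] = []
    names: list[str] = []
    kinds: list[str] = []
    for m in collection:
        hit = sorted(index[g] for g in m.genes if g in index)
        if len(hit) < min_genes:
            logger.warning(
                "module %r dropped: %d of %d genes present (< min_genes=%d)",
                m.name, len(hit), len(m.genes), min_genes,
            )
            continue
        col = np.zeros(len(genes))
        col[hit] = 1.0
        cols.append(col)
        names.append(m.name)
        kinds.append(NODE_GMV)
    if not cols:
        raise ValueError(
            "no gene module overlaps the dataset's genes with >= "
            f"{min_genes} members; lower min_genes or check that gene "
            "identifier conventions match (case, species, symbol vs ID)"
        )
    for i in range(n_fc):
        cols.append(np.ones(len(genes)))
        names.append(f"fc_{i}")
        kinds.append(NODE_FC)
    for i in range(n_covariate):
        cols.append(np.ones(len(genes)))
        names.append(f"covariate_{i}")
        kinds.append(NODE_COVARIATE)
    return MaskMatrix(np.column_stack(cols), genes, names, kinds)
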