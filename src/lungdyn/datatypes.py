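"""Shared in-memory containers for the atlas pipeline.

Counts are kept as dense integer arrays: the synthetic test-bed and the
analyses here run at a few thousand cells by a few hundred genes, where
dense linear algebra is both simpler and faster than sparse bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd


class LungdynError(Exception):
    """Base class for package errors."""


class ConfigError(LungdynError):
    """Invalid configuration; the message names the offending field."""


class EmptyAfterQCError(LungdynError):
    """All cells were removed by quality-control filtering."""


@dataclass
class CountMatrix:
    """Raw cells x genes counts with per-cell metadata.

    ``cell_meta`` is indexed by cell id and must carry ``sample_id``;
    ``gestational_week`` (integer weeks) and a cell-type label are optional
    but used by the temporal and annotation analyses. Mitochondrial genes
    are recognised by a configurable gene-id prefix.
    """

    counts: np.ndarray
    cell_meta: pd.DataFrame
    gene_ids: pd.Index
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.gene_ids = pd.Index(self.gene_ids)
        if self.counts.shape != (len(self.cell_meta), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_meta)} cells x {len(self.gene_ids)} genes"
            )
        if "sample_id" not in self.cell_meta.columns:
            raise ValueError("cell_meta must contain a 'sample_id' column")
        if "gestational_week" in self.cell_meta.columns:
            gw = self.cell_meta["gestational_week"].dropna()
            if len(gw) and (gw.min() < 10 or gw.max() > 19):
                raise ValueError("gestational_week must lie in [10, 19]")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    def mito_mask(self) -> np.ndarray:
        return np.asarray(self.gene_ids.str.startswith(self.mito_prefix))

    def subset(self, cell_mask: np.ndarray | None = None,
               gene_mask: np.ndarray | None = None) -> "CountMatrix":
        counts = self.counts
        meta = self.cell_meta
        genes = self.gene_ids
        if cell_mask is not None:
            counts = counts[cell_mask]
            meta = meta.loc[cell_mask] if cell_mask.dtype == bool else meta.iloc[cell_mask]
        if gene_mask is not None:
            counts = counts[:, gene_mask]
            genes = genes[gene_mask]
        return CountMatrix(counts.copy(), meta.copy(), genes, self.mito_prefix)


@dataclass
class ExprMatrix:
    """Log-normalised expression (cells x genes, floats >= 0)."""

    values: np.ndarray
    cell_meta: pd.DataFrame
    gene_ids: pd.Index
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = pd.Index(self.gene_ids)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("log-normalised expression must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    def gene_index(self, genes) -> np.ndarray:
        idx = self.gene_ids.get_indexer(pd.Index(genes))
        if np.any(idx < 0):
            missing = list(pd.Index(genes)[idx < 0])
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        return idx


@dataclass
class ClusterLabels:
    """Per-cell categorical labels, contiguous 0..K-1."""

    labels: np.ndarray
    resolution: float
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            # relabel to contiguous 0..K-1 preserving order of first appearance
            remap = {old: new for new, old in enumerate(uniq)}
            self.labels = np.array([remap[v] for v in self.labels])

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)
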