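"""Quality control, normalisation, dimensionality reduction and clustering.

QC follows fixed thresholds (cells with <200 detected genes or >15%
mitochondrial counts removed, then genes detected in <3 cells removed;
cell filters are evaluated on the raw matrix, once, before the gene
filter). Normalisation is library-size scaling to the median library
followed by log(1+x). Highly variable genes are ranked by within-bin
dispersion (variance/mean of normalised counts, z-scored inside 20
equal-frequency mean bins). Clustering is seeded modularity community
detection on a shared-nearest-neighbour graph, plus a cluster-tree
stability diagnostic across resolutions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .datatypes import ClusterLabels, CountMatrix, EmptyAfterQCError, ExprMatrix

log = logging.getLogger(__name__)

SNN_PRUNE = 1.0 / 15.0  # drop SNN edges with Jaccard overlap below this


def qc_filter(raw: CountMatrix, min_features: int = 200,
              max_mito_frac: float = 0.15,
              min_cells_per_gene: int = 3) -> CountMatrix:
    """Remove low-complexity / high-mitochondrial cells, then rare genes.

    A cell survives iff it has >= ``min_features`` detected genes and a
    mitochondrial count fraction <= ``max_mito_frac`` (both computed on the
    raw matrix). A gene survives iff it is detected in >=
    ``min_cells_per_gene`` surviving cells. Filters are applied once, cells
    first.
    """
    if raw.n_cells == 0:
        raise EmptyAfterQCError("input matrix has no cells")
    detected = (raw.counts > 0).sum(axis=1)
    total = raw.counts.sum(axis=1)
    mito = raw.counts[:, raw.mito_mask()].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    keep_cells = (detected >= min_features) & (mito_frac <= max_mito_frac)
    if not keep_cells.any():
        raise EmptyAfterQCError(
            f"no cells survive QC (min_features={min_features}, "
            f"max_mito_frac={max_mito_frac})")
    sub = raw.counts[keep_cells]
    keep_genes = (sub > 0).sum(axis=0) >= min_cells_per_gene
    log.info("qc_filter: %d/%d cells kept, %d/%d genes kept",
             keep_cells.sum(), raw.n_cells, keep_genes.sum(), raw.n_genes)
    return CountMatrix(sub[:, keep_genes].copy(),
                       raw.cell_meta.loc[keep_cells].copy(),
                       raw.gene_ids[keep_genes], raw.mito_prefix)


@dataclass
class TransformModel:
    """Normalisation + HVG + PCA parameters, reusable on query data."""

    target_sum: float
    hvg: pd.Index
    center: np.ndarray           # per-HVG mean of log values
    scale: np.ndarray            # per-HVG sd of log values
    components: np.ndarray       # (n_pcs, n_hvg) loadings
    explained_variance_ratio: np.ndarray
    clip: float = 10.0
    dispersion_table: pd.DataFrame | None = field(default=None, repr=False)


def normalize_log(counts: np.ndarray, target_sum: float) -> np.ndarray:
    lib = counts.sum(axis=1, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    return np.log1p(counts / lib * target_sum)


def highly_variable_genes(norm_counts: np.ndarray, gene_ids: pd.Index,
                          n_hvg: int, n_bins: int = 20) -> pd.DataFrame:
    """Rank genes by binned normalised dispersion of normalised counts."""
    mean = norm_counts.mean(axis=0)
    var = norm_counts.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), np.nan)
    usable = np.isfinite(disp) & (var > 0)
    z = np.full(len(mean), -np.inf)
    if usable.sum():
        order = np.argsort(mean[usable], kind="stable")
        idx = np.flatnonzero(usable)[order]
        bins = np.array_split(idx, min(n_bins, len(idx)))
        for b in bins:
            d = disp[b]
            sd = d.std()
            z[b] = (d - d.mean()) / sd if sd > 0 else 0.0
    tab = pd.DataFrame({"mean": mean, "dispersion": disp, "dispersion_z": z},
                       index=gene_ids)
    tab["highly_variable"] = False
    top = tab["dispersion_z"].nlargest(min(n_hvg, int(usable.sum()))).index
    tab.loc[top, "highly_variable"] = True
    return tab


def pca(X: np.ndarray, n_pcs: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic full-SVD PCA: returns (scores, components, evr)."""
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign convention: largest-|loading| entry positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    n_pcs = min(n_pcs, len(S))
    evr = S ** 2 / max((S ** 2).sum(), 1e-300)
    return U[:, :n_pcs] * S[:n_pcs], Vt[:n_pcs], evr[:n_pcs]


def transform(qc: CountMatrix, n_hvg: int = 3000, n_pcs: int = 30,
              target_sum: float | str = "median",
              ) -> tuple[ExprMatrix, np.ndarray, TransformModel]:
    """Normalise, select HVGs, and embed into principal components.

    Returns the log-normalised matrix over all genes, the cells x n_pcs
    embedding, and the fitted :class:`TransformModel` (needed to project
    query data onto the same axes).
    """
    if n_hvg > qc.n_genes:
        warnings.warn(f"n_hvg={n_hvg} > {qc.n_genes} genes; clamping")
        n_hvg = qc.n_genes
    lib = qc.counts.sum(axis=1)
    target = float(np.median(lib)) if target_sum == "median" else float(target_sum)
    norm = qc.counts / np.maximum(lib[:, None], 1) * target
    X = np.log1p(norm)
    hvg_tab = highly_variable_genes(norm, qc.gene_ids, n_hvg)
    hvg = hvg_tab.index[hvg_tab["highly_variable"]]
    cols = qc.gene_ids.get_indexer(hvg)
    H = X[:, cols]
    center = H.mean(axis=0)
    scale = H.std(axis=0)
    scale[scale == 0] = 1.0
    Z = np.clip((H - center) / scale, -10.0, 10.0)
    scores, components, evr = pca(Z, n_pcs)
    expr = ExprMatrix(X, qc.cell_meta.copy(), qc.gene_ids,
                      provenance={"target_sum": target, "n_hvg": len(hvg),
                                  "n_pcs": scores.shape[1]})
    model = TransformModel(target, hvg, center, scale, components, evr,
                           dispersion_table=hvg_tab)
    return expr, scores, model


def snn_graph(embedding: np.ndarray, k_neighbors: int) -> sparse.csr_matrix:
    """Shared-nearest-neighbour graph with Jaccard-style edge weights."""
    n = embedding.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    # query without X: a point is not its own neighbour; add self explicitly
    # so shared-neighbour counts follow the usual convention
    A = nn.kneighbors_graph(mode="connectivity") + sparse.identity(n, format="csr")
    k = k_neighbors + 1
    shared = A @ A.T
    shared = shared.tocoo()
    w = shared.data / (2 * k - shared.data)
    keep = (w >= SNN_PRUNE) & (shared.row != shared.col)
    G = sparse.csr_matrix((w[keep], (shared.row[keep], shared.col[keep])),
                          shape=(n, n))
    return G


def cluster_graph(embedding: np.ndarray, k_neighbors: int = 30,
                  resolution: float = 1.0, seed: int = 0) -> ClusterLabels:
    """Seeded modularity community detection on the SNN graph."""
    if not np.all(np.isfinite(embedding)):
        raise ValueError("embedding must be finite")
    G = snn_graph(embedding, k_neighbors)
    coo = sparse.triu(G, k=1).tocoo()
    g = ig.Graph(n=G.shape[0],
                 edges=list(zip(coo.row.tolist(), coo.col.tolist())),
                 edge_attrs={"weight": coo.data.tolist()})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=int(seed),
        n_iterations=2)
    labels = np.asarray(part.membership)
    # relabel by decreasing size (ties by smallest member index) for stability
    sizes = np.bincount(labels)
    first = np.full(sizes.shape, np.iinfo(np.int64).max)
    for i, lab in enumerate(labels):
        first[lab] = min(first[lab], i)
    order = np.lexsort((first, -sizes))
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    return ClusterLabels(remap[labels], resolution, seed)


@dataclass
class StabilityReport:
    """Cluster-tree stability across increasing resolutions.

    ``edges`` holds, for each (parent cluster at resolution r, child cluster
    at resolution r'), the fraction of the child's cells contributed by that
    parent (the "in-proportion"). A resolution is flagged over-clustered when
    any of its clusters draws an in-proportion >= ``threshold`` from two or
    more parents.
    """

    edges: pd.DataFrame
    flagged_resolutions: list[float]
    threshold: float
    recommended_resolution: float | None


def resolution_stability(labelings: list[ClusterLabels],
                         in_prop_threshold: float = 0.1) -> StabilityReport:
    if len(labelings) < 2:
        raise ValueError("need labelings at >= 2 resolutions")
    n = len(labelings[0].labels)
    for lab in labelings[1:]:
        if len(lab.labels) != n:
            raise ValueError("labelings must cover the same cells")
    labelings = sorted(labelings, key=lambda l: l.resolution)
    rows = []
    flagged: set[float] = set()
    for parent, child in zip(labelings[:-1], labelings[1:]):
        tab = pd.crosstab(parent.labels, child.labels)
        in_prop = tab / tab.sum(axis=0)
        for c in tab.columns:
            col = in_prop[c]
            parents = col[col > 0]
            for p, frac in parents.items():
                rows.append({"parent_resolution": parent.resolution,
                             "child_resolution": child.resolution,
                             "parent": int(p), "child": int(c),
                             "in_proportion": float(frac)})
            if (parents >= in_prop_threshold).sum() >= 2:
                flagged.add(child.resolution)
    edges = pd.DataFrame(rows)
    unflagged = [l.resolution for l in labelings if l.resolution not in flagged]
    recommended = max(unflagged) if unflagged else None
    return StabilityReport(edges, sorted(flagged), in_prop_threshold, recommended)
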