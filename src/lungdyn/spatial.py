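"""Spatial statistics on cell centroids and spot deconvolution weights.

Implements radius-based co-occurrence profiles around a focal cell type,
label-permutation neighbourhood enrichment (z-scores at a 75-unit radius),
correlation of per-spot deconvolution weights with hierarchical ordering,
and the "spatially close types" rule used to restrict signalling senders.
All neighbourhoods use closed Euclidean balls (distance <= r).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .synthetic import SpatialMap, SpotWeights

DEFAULT_RADIUS = 75.0


def _check_map(smap: SpatialMap) -> pd.DataFrame:
    t = smap.table
    if not np.all(np.isfinite(t[["x", "y"]].to_numpy())):
        raise ValueError("spatial coordinates must be finite")
    return t


def cooccurrence_profile(smap: SpatialMap, focal_type: str,
                         radii: list[float]) -> pd.DataFrame:
    """Type composition of the pooled neighbourhood of a focal type.

    For each radius r, every non-focal cell lying within distance r of any
    focal cell joins the pool (once); the profile is the proportion of each
    type in that pool. Radii with an empty pool yield missing values rather
    than zeros. Focal-type cells never enter the pool.
    """
    t = _check_map(smap)
    focal = t["type"] == focal_type
    if not focal.any():
        raise ValueError(f"no cells of focal type {focal_type!r}")
    radii = list(radii)
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be > 0")
    xy = t[["x", "y"]].to_numpy()
    types = sorted(t["type"].unique())
    other_types = [ty for ty in types if ty != focal_type]
    tree = cKDTree(xy[~focal.to_numpy()])
    other_type_arr = t.loc[~focal, "type"].to_numpy()
    focal_xy = xy[focal.to_numpy()]
    rows = []
    for r in sorted(radii):
        neigh = tree.query_ball_point(focal_xy, r)
        flat = [np.asarray(v, dtype=int) for v in neigh]
        pool = np.unique(np.concatenate(flat)) if flat else np.array([], dtype=int)
        if pool.size == 0:
            rows.append({ty: np.nan for ty in other_types})
            continue
        vc = pd.Series(other_type_arr[pool]).value_counts()
        total = float(vc.sum())
        rows.append({ty: vc.get(ty, 0) / total for ty in other_types})
    return pd.DataFrame(rows, index=pd.Index(sorted(radii), name="radius"))


def radius_edges(xy: np.ndarray, radius: float) -> np.ndarray:
    """Unique undirected pairs within closed distance <= radius, as (m, 2)."""
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    return pairs  # query_pairs uses closed balls and i < j


def neighborhood_enrichment(smap: SpatialMap, radius: float = DEFAULT_RADIUS,
                            n_perms: int = 1000, seed: int = 0
                            ) -> pd.DataFrame:
    """Permutation z-scores for type-pair adjacency in a radius graph.

    Observed counts of edges joining each (unordered) pair of types are
    compared against ``n_perms`` label shufflings; z = (obs - mean)/sd.
    Pairs whose null count never varies get z = 0 with a warning.
    """
    t = _check_map(smap)
    types = sorted(t["type"].unique())
    if len(types) < 2:
        raise ValueError("need >= 2 cell types for enrichment")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    code = pd.Categorical(t["type"], categories=types).codes.astype(int)
    K = len(types)
    edges = radius_edges(t[["x", "y"]].to_numpy(), radius)
    rng = np.random.default_rng(seed)

    def pair_counts(lbl: np.ndarray) -> np.ndarray:
        c = np.zeros((K, K))
        if len(edges):
            a = lbl[edges[:, 0]]
            b = lbl[edges[:, 1]]
            np.add.at(c, (np.minimum(a, b), np.maximum(a, b)), 1.0)
        return c[np.triu_indices(K)]

    obs = pair_counts(code)
    null = np.empty((n_perms, len(obs)))
    for p in range(n_perms):
        null[p] = pair_counts(rng.permutation(code))
    mean = null.mean(axis=0)
    sd = null.std(axis=0)
    z = np.zeros_like(obs)
    ok = sd > 0
    z[ok] = (obs[ok] - mean[ok]) / sd[ok]
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} type pairs had a degenerate null; "
                      "their z was set to 0")
    Z = np.zeros((K, K))
    Z[np.triu_indices(K)] = z
    Z = Z + np.triu(Z, k=1).T
    return pd.DataFrame(Z, index=types, columns=types)


@dataclass
class Colocalization:
    correlation: pd.DataFrame
    order: list[str]          # dendrogram leaf order
    linkage: np.ndarray


def weight_colocalization(weights: SpotWeights) -> Colocalization:
    """Pearson correlation of deconvolution weights across spots.

    Average-linkage hierarchical clustering on 1 - correlation supplies a
    display order; zero-variance types are excluded with a warning.
    """
    W = weights.weights
    if W.shape[1] < 2 or W.shape[0] < 3:
        raise ValueError("need >= 2 types and >= 3 spots")
    sd = W.std(axis=0)
    drop = sd[sd == 0].index.tolist()
    if drop:
        warnings.warn(f"zero-variance weight columns excluded: {drop}")
        W = W.drop(columns=drop)
    corr = W.corr(method="pearson")
    D = np.clip(1.0 - corr.to_numpy(), 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.average(squareform(D, checks=False))
    leaves = hierarchy.leaves_list(Z)
    order = [corr.columns[i] for i in leaves]
    return Colocalization(corr, order, Z)


def proximal_types(statistic: pd.DataFrame, focal_type: str,
                   threshold: float = 0.0) -> set[str]:
    """Types "spatially close" to the focal type.

    ``statistic`` is a symmetric score matrix (e.g. enrichment z-scores or a
    co-occurrence row broadcast to a frame); a type is close when its score
    with the focal type exceeds ``threshold``. The focal type itself is
    excluded. Default threshold 0 on enrichment z-scores means
    "more adjacent than the label-shuffled expectation".
    """
    if focal_type not in statistic.index:
        raise ValueError(f"focal type {focal_type!r} absent from statistic")
    row = statistic.loc[focal_type].drop(labels=[focal_type], errors="ignore")
    return set(row[row > threshold].index)
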