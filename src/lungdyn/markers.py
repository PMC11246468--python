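"""Marker statistics: one-vs-rest Wilcoxon differential expression,
control-matched gene-set scoring, marker-list overlap, and Spearman staging.

The rank-sum test is exact (tie-aware enumeration over group assignments)
when both groups have at most :data:`EXACT_MAX_N` observations, and uses a
normal approximation with tie and continuity corrections otherwise. Fold
changes follow the convention ln((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1)),
so they are natural-log ratios of de-logged means with a pseudocount.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ClusterLabels, ExprMatrix

EXACT_MAX_N = 8  # per-group size at or below which the exact test is used


# ---------------------------------------------------------------------------
# rank-sum test


def _ranksum_exact(ranks: np.ndarray, in_group: np.ndarray) -> float:
    """Exact two-sided p for the rank-sum W of ``in_group`` observations.

    Enumerates all C(n, n1) assignments of the pooled (possibly tied)
    midranks; two-sided p = min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    n = len(ranks)
    n1 = int(in_group.sum())
    w_obs = ranks[in_group].sum()
    total = comb(n, n1)
    le = ge = 0
    eps = 1e-9
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if w <= w_obs + eps:
            le += 1
        if w >= w_obs - eps:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    Returns (z_or_nan, p). Exact enumeration when both groups have <= 8
    observations; otherwise normal approximation with tie correction and a
    0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        in_group = np.zeros(n1 + n2, dtype=bool)
        in_group[:n1] = True
        return np.nan, _ranksum_exact(ranks, in_group)
    w = ranks[:n1].sum()
    z, p = _ranksum_normal(np.array([w]), n1, n2, _tie_term(pooled[None].T))
    return float(z[0]), float(p[0])


def _tie_term(values: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tie groups, per column of ``values``."""
    out = np.zeros(values.shape[1])
    for j in range(values.shape[1]):
        _, counts = np.unique(values[:, j], return_counts=True)
        out[j] = float((counts.astype(float) ** 3 - counts).sum())
    return out


def _ranksum_normal(w: np.ndarray, n1: int, n2: int, ties: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1.0)))
    var = np.maximum(var, 1e-300)
    diff = w - mu
    z = (diff - np.sign(diff) * 0.5) / np.sqrt(var)  # continuity correction
    return z, 2.0 * stats.norm.sf(np.abs(z))


# ---------------------------------------------------------------------------
# one-vs-rest marker table


@dataclass
class MarkerTable:
    """Retained positive markers per cluster (log_fc > threshold)."""

    table: pd.DataFrame  # cluster, gene, log_fc, p_value, adj_p, pct_in, pct_out
    logfc_min: float


@dataclass
class GeneSet:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate genes")


def log_fold_change(expr_in: np.ndarray, expr_out: np.ndarray) -> np.ndarray:
    """ln((mean(expm1 x_in)+1) / (mean(expm1 x_out)+1)), per gene."""
    a = np.expm1(expr_in).mean(axis=0) + 1.0
    b = np.expm1(expr_out).mean(axis=0) + 1.0
    return np.log(a / b)


def rank_markers(expr: ExprMatrix, labels: ClusterLabels | np.ndarray,
                 logfc_min: float = 0.25, positive_only: bool = True,
                 min_cluster_size: int = 3) -> MarkerTable:
    """One-vs-rest Wilcoxon markers for every cluster.

    Rows failing the fold-change floor (or positivity) are dropped before
    Benjamini-Hochberg adjustment, which is applied within each cluster.
    """
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels)
    groups = pd.unique(pd.Series(lab))
    if len(groups) < 2:
        raise ValueError("need >= 2 clusters for one-vs-rest markers")
    X = expr.values
    n = X.shape[0]
    ranks = stats.rankdata(X, axis=0)
    ties = _tie_term(X)
    frames = []
    for g in sorted(groups, key=str):
        in_g = lab == g
        n1 = int(in_g.sum())
        n2 = n - n1
        if n1 < min_cluster_size:
            warnings.warn(f"cluster {g!r} has {n1} < {min_cluster_size} cells; skipped")
            continue
        lfc = log_fold_change(X[in_g], X[~in_g])
        if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
            pvals = np.array([rank_sum_test(X[in_g, j], X[~in_g, j])[1]
                              for j in range(X.shape[1])])
        else:
            w = ranks[in_g].sum(axis=0)
            _, pvals = _ranksum_normal(w, n1, n2, ties)
        keep = lfc > logfc_min if positive_only else np.abs(lfc) > logfc_min
        if not keep.any():
            continue
        adj = multipletests(pvals[keep], method="fdr_bh")[1]
        frames.append(pd.DataFrame({
            "cluster": g,
            "gene": expr.gene_ids[keep],
            "log_fc": lfc[keep],
            "p_value": pvals[keep],
            "adj_p": adj,
            "pct_in": (X[in_g][:, keep] > 0).mean(axis=0),
            "pct_out": (X[~in_g][:, keep] > 0).mean(axis=0),
        }))
    if frames:
        tab = pd.concat(frames, ignore_index=True)
        tab = tab.sort_values(["cluster", "adj_p", "p_value", "log_fc"],
                              ascending=[True, True, True, False],
                              kind="stable").reset_index(drop=True)
    else:
        tab = pd.DataFrame(columns=["cluster", "gene", "log_fc", "p_value",
                                    "adj_p", "pct_in", "pct_out"])
    return MarkerTable(tab, logfc_min)


def top_gene_set(markers: MarkerTable, cluster, k: int = 100,
                 name: str | None = None) -> GeneSet:
    """Top-k marker genes of one cluster, ranked by adj_p then log_fc."""
    sub = markers.table[markers.table["cluster"] == cluster]
    sub = sub.sort_values(["adj_p", "p_value", "log_fc"],
                          ascending=[True, True, False], kind="stable")
    genes = sub["gene"].head(k).tolist()
    return GeneSet(str(cluster) if name is None else name, genes)


# ---------------------------------------------------------------------------
# gene-set scoring


def score_cells(expr: ExprMatrix, gene_set: GeneSet,
                min_cells_in_pool: int = 10, n_bins: int = 25,
                ctrl_size: int = 50, seed: int = 0) -> pd.Series:
    """Control-matched gene-set score per cell.

    Score = mean expression over the set minus mean expression over control
    genes sampled (seeded) from expression-matched bins of the background
    pool. The pool is every gene expressed in more than ``min_cells_in_pool``
    cells, excluding the set genes.
    """
    rng = np.random.default_rng(seed)
    present = [g for g in gene_set.genes if g in expr.gene_ids]
    missing = sorted(set(gene_set.genes) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} set genes missing from matrix "
                      f"(e.g. {missing[:5]}); dropped")
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} in the matrix")
    X = expr.values
    n_expressing = (X > 0).sum(axis=0)
    pool_mask = n_expressing > min_cells_in_pool
    set_idx = expr.gene_index(present)
    pool_mask[set_idx] = False
    pool_idx = np.flatnonzero(pool_mask)
    if len(pool_idx) < len(set_idx):
        raise ValueError(
            f"background pool ({len(pool_idx)} genes) smaller than gene set")
    # expression bins over pool + set genes, by mean expression
    all_idx = np.concatenate([pool_idx, set_idx])
    means = X[:, all_idx].mean(axis=0)
    order = np.argsort(means, kind="stable")
    bin_of = np.empty(len(all_idx), dtype=int)
    for b, chunk in enumerate(np.array_split(order, min(n_bins, len(order)))):
        bin_of[chunk] = b
    bin_lookup = dict(zip(all_idx, bin_of))
    pool_by_bin: dict[int, np.ndarray] = {}
    for b in np.unique(bin_of):
        members = all_idx[(bin_of == b)]
        pool_by_bin[b] = members[np.isin(members, pool_idx)]
    ctrl: set[int] = set()
    for gi in set_idx:
        candidates = pool_by_bin.get(bin_lookup[gi], np.array([], dtype=int))
        if len(candidates) == 0:
            continue
        take = min(ctrl_size, len(candidates))
        ctrl.update(rng.choice(candidates, size=take, replace=False).tolist())
    if not ctrl:
        raise ValueError("no control genes available for scoring")
    ctrl_idx = np.array(sorted(ctrl))
    score = X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=expr.cell_ids, name=gene_set.name)


def score_matrix(expr: ExprMatrix, gene_sets: dict[str, GeneSet],
                 cell_types: pd.Series | None = None,
                 normalize: bool = True, min_cells_in_pool: int = 10,
                 n_bins: int = 25, ctrl_size: int = 50,
                 seed: int = 0) -> pd.DataFrame:
    """Cells x types score matrix, optionally own-type-median normalised.

    With ``normalize`` and ``cell_types`` given, each type's column is
    divided by the median score of that type's own cells, so the median
    own-type score is exactly 1.
    """
    cols = {name: score_cells(expr, gs, min_cells_in_pool, n_bins, ctrl_size,
                              seed=seed + i)
            for i, (name, gs) in enumerate(sorted(gene_sets.items()))}
    mat = pd.DataFrame(cols, index=expr.cell_ids)
    if normalize:
        if cell_types is None:
            raise ValueError("normalisation requires per-cell type labels")
        cell_types = cell_types.reindex(mat.index)
        for name in mat.columns:
            own = mat.loc[cell_types == name, name]
            if own.empty:
                warnings.warn(f"no cells of type {name!r}; column left unnormalised")
                continue
            med = float(own.median())
            if med == 0:
                warnings.warn(f"median own-type score of {name!r} is 0; "
                              "column left unnormalised")
                continue
            mat[name] = mat[name] / med
    return mat


# ---------------------------------------------------------------------------
# list overlap and staging


def overlap_coefficient(set_a: GeneSet | list[str],
                        set_b: GeneSet | list[str]) -> float:
    """|A n B| / min(|A|, |B|)."""
    a = set(set_a.genes if isinstance(set_a, GeneSet) else set_a)
    b = set(set_b.genes if isinstance(set_b, GeneSet) else set_b)
    if not a or not b:
        raise ValueError("overlap coefficient of an empty gene list")
    return len(a & b) / min(len(a), len(b))


def stage_gene_sets(expr: ExprMatrix, stages: pd.Series, k: int = 50,
                    logfc_min: float = 0.25) -> dict[str, list[str]]:
    """Top-k one-stage-vs-rest marker genes for every stage."""
    stages = stages.reindex(expr.cell_ids)
    tab = rank_markers(expr, stages.to_numpy(), logfc_min=logfc_min)
    out = {}
    for s in sorted(stages.dropna().unique(), key=str):
        genes = top_gene_set(tab, s, k=k).genes if \
            (tab.table["cluster"] == s).any() else []
        out[str(s)] = genes
    return out


def stage_correlation(query_profiles: pd.DataFrame,
                      reference_profiles: pd.DataFrame,
                      stage_degs: dict[str, list[str]]) -> pd.DataFrame:
    """Spearman correlation of query groups against reference stages.

    Profiles are mean log expression (rows = groups/stages, columns = genes);
    the gene panel is the union of the per-stage top marker lists.
    """
    panel: list[str] = []
    for genes in stage_degs.values():
        panel.extend(g for g in genes if g not in panel)
    panel = [g for g in panel
             if g in query_profiles.columns and g in reference_profiles.columns]
    if len(panel) < 3:
        raise ValueError(f"stage panel has only {len(panel)} usable genes")
    Q = query_profiles[panel].to_numpy()
    R = reference_profiles[panel].to_numpy()
    rho = np.zeros((Q.shape[0], R.shape[0]))
    for i in range(Q.shape[0]):
        for j in range(R.shape[0]):
            rho[i, j] = stats.spearmanr(Q[i], R[j]).statistic
    return pd.DataFrame(rho, index=query_profiles.index,
                        columns=reference_profiles.index)


def best_stage(correlations: pd.DataFrame) -> pd.Series:
    """Argmax stage per query group; ties broken toward the earlier stage."""
    return pd.Series({q: correlations.columns[int(np.argmax(row.to_numpy()))]
                      for q, row in correlations.iterrows()})
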