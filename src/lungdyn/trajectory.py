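"""Cluster-backbone trajectories, pseudotime, lineage genes and fates.

The backbone is a minimum spanning tree over cluster centroids in PC
space; lineages are the simple root-to-leaf paths, and each cell's
pseudotime is the arc position of its orthogonal projection onto the
piecewise-linear backbone of its best-fitting lineage. Lineage-associated
genes come from a natural-cubic-spline regression F-test of expression on
pseudotime (BH-adjusted within each lineage). Gene modules use Ward
linkage on 1 - Pearson correlation. Cluster-graph connectivity per
gestational vignette is a PAGA-style observed/expected edge ratio, and
fate probabilities come from an absorbing Markov chain on the kNN graph
with a pseudotime-directed (logistic in delta-tau) transition kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.cluster import hierarchy
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform
from scipy.special import expit
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .datatypes import ClusterLabels
from .vignettes import TRAJECTORY_VIGNETTES, assign_vignette

# ---------------------------------------------------------------------------
# natural cubic spline basis


def natural_spline_basis(x: np.ndarray, df: int = 10,
                         knots: np.ndarray | None = None) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Knots (df + 1 of them, boundary included) sit at quantiles of ``x``.
    Uses the truncated-power natural basis: linearity is enforced beyond the
    boundary knots. Duplicate knots (heavily tied x) are collapsed, which
    lowers the effective df.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = np.quantile(x, np.linspace(0, 1, df + 1))
    knots = np.unique(knots)
    K = len(knots)
    if K < 3:
        # too few distinct values for curvature: linear basis only
        return x[:, None] - x.mean()

    def d(k):
        num = (np.maximum(x - knots[k], 0) ** 3
               - np.maximum(x - knots[-1], 0) ** 3)
        return num / (knots[-1] - knots[k])

    dK1 = d(K - 2)
    cols = [x] + [d(k) - dK1 for k in range(K - 2)]
    B = np.column_stack(cols)
    return B - B.mean(axis=0)


# ---------------------------------------------------------------------------
# backbone + pseudotime


@dataclass
class TrajectoryModel:
    centroids: pd.DataFrame          # clusters x PCs
    mst_edges: list[tuple]           # (cluster, cluster)
    root: object
    lineages: list[list]             # ordered root -> leaf cluster paths
    pseudotime: pd.Series            # per cell, arc length from root
    lineage_weights: pd.DataFrame    # cells x lineages, rows sum to 1
    best_lineage: pd.Series          # argmax-weight lineage name per cell
    cell_ids: pd.Index = field(repr=False, default=None)

    def lineage_name(self, path) -> str:
        return str(path[-1])


def _project_polyline(points: np.ndarray, vertices: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Arc position and distance of each point's projection onto a polyline.

    The first and last segments are extended beyond the root/leaf vertices
    so cells outside the centroid span keep a graded arc position (arc may
    then be negative; the caller shifts pseudotime to be non-negative).
    """
    seg_len = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    last = len(vertices) - 2
    best_d = np.full(len(points), np.inf)
    best_arc = np.zeros(len(points))
    for s in range(len(vertices) - 1):
        a, b = vertices[s], vertices[s + 1]
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            t = np.zeros(len(points))
        else:
            lo = -np.inf if s == 0 else 0.0
            hi = np.inf if s == last else 1.0
            t = np.clip((points - a) @ ab / denom, lo, hi)
        proj = a + t[:, None] * ab
        dist = np.linalg.norm(points - proj, axis=1)
        better = dist < best_d
        best_d[better] = dist[better]
        best_arc[better] = cum[s] + t[better] * seg_len[s]
    return best_arc, best_d


def infer_backbone(embedding: np.ndarray, labels: ClusterLabels | np.ndarray,
                   root_cluster, cell_ids: pd.Index | None = None
                   ) -> TrajectoryModel:
    """MST backbone over cluster centroids with per-cell arc pseudotime."""
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels)
    clusters = sorted(pd.unique(pd.Series(lab)), key=str)
    if root_cluster not in clusters:
        raise ValueError(f"root cluster {root_cluster!r} not present in labels")
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters to build a backbone")
    cents = np.vstack([embedding[lab == c].mean(axis=0) for c in clusters])
    D = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=2)
    mst = minimum_spanning_tree(D).toarray()
    G = nx.Graph()
    G.add_nodes_from(range(len(clusters)))
    for i, j in zip(*np.nonzero(mst)):
        G.add_edge(int(i), int(j), weight=float(D[i, j]))
    ridx = clusters.index(root_cluster)
    leaves = [n for n in G.nodes if G.degree[n] == 1 and n != ridx]
    if not leaves:  # two-node tree where root is one of the two leaves
        leaves = [n for n in G.nodes if n != ridx]
    lineages_idx = [nx.shortest_path(G, ridx, leaf) for leaf in leaves]
    lineages = [[clusters[i] for i in path] for path in lineages_idx]

    if cell_ids is None:
        cell_ids = pd.RangeIndex(len(lab))
    arcs = np.zeros((len(lab), len(lineages)))
    dists = np.zeros_like(arcs)
    for li, path in enumerate(lineages_idx):
        arc, dist = _project_polyline(embedding, cents[path])
        arcs[:, li] = arc
        dists[:, li] = dist
    # weights from relative (inverse squared) distance to each backbone
    inv = 1.0 / (dists ** 2 + 1e-12)
    weights = inv / inv.sum(axis=1, keepdims=True)
    best = np.argmin(dists, axis=1)
    tau = arcs[np.arange(len(lab)), best]
    if tau.min() < 0:  # cells upstream of the root centroid: shift to >= 0
        arcs -= tau.min()
        tau = tau - tau.min()
    names = [str(path[-1]) for path in lineages]
    edges = [(clusters[i], clusters[j]) for i, j in zip(*np.nonzero(mst))]
    return TrajectoryModel(
        centroids=pd.DataFrame(cents, index=pd.Index(clusters, name="cluster")),
        mst_edges=edges, root=root_cluster, lineages=lineages,
        pseudotime=pd.Series(tau, index=cell_ids, name="pseudotime"),
        lineage_weights=pd.DataFrame(weights, index=cell_ids, columns=names),
        best_lineage=pd.Series(np.array(names, dtype=object)[best],
                               index=cell_ids, name="lineage"),
        cell_ids=cell_ids)


# ---------------------------------------------------------------------------
# lineage-associated genes


def _spline_ftest(y: np.ndarray, Q: np.ndarray, df1: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised F-test of spline model vs intercept; y is cells x genes."""
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    rss0 = (yc ** 2).sum(axis=0)
    fit = Q.T @ yc
    rss1 = np.maximum(rss0 - (fit ** 2).sum(axis=0), 0.0)
    df_resid = n - df1 - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (rss0 - rss1) / df1 / np.where(rss1 > 0, rss1 / df_resid, np.nan)
    p = np.where(np.isfinite(F), stats.f.sf(F, df1, df_resid), 1.0)
    p = np.where(rss0 == 0, 1.0, p)  # constant genes: no association
    return F, p


def association_test(expr_values: np.ndarray, gene_ids: pd.Index,
                     model: TrajectoryModel, fdr: float = 0.01,
                     df: int = 10, min_cells: int = 30,
                     min_weight: float | None = None
                     ) -> dict[str, pd.DataFrame]:
    """Per-lineage spline F-test of expression on pseudotime.

    A cell contributes to every lineage whose weight exceeds
    ``min_weight`` (default 0.8 / n_lineages) — cells on the shared trunk
    weigh roughly equally on all lineages and are tested on each. BH
    adjustment is applied within each lineage separately and genes with
    adjusted p below ``fdr`` are flagged. Lineages with fewer than
    ``min_cells`` cells are skipped.
    """
    n_lineages = model.lineage_weights.shape[1]
    if min_weight is None:
        min_weight = 0.8 / n_lineages
    out: dict[str, pd.DataFrame] = {}
    for name in model.lineage_weights.columns:
        mask = (model.lineage_weights[name] >= min_weight).to_numpy()
        n = int(mask.sum())
        if n < min_cells:
            warnings.warn(f"lineage {name!r} has {n} < {min_cells} cells; skipped")
            continue
        tau = model.pseudotime.to_numpy()[mask]
        B = natural_spline_basis(tau, df=df)
        Q, _ = np.linalg.qr(B)
        F, p = _spline_ftest(expr_values[mask], Q, B.shape[1])
        adj = multipletests(p, method="fdr_bh")[1]
        out[name] = pd.DataFrame({
            "gene": gene_ids, "F": F, "p_value": p, "adj_p": adj,
            "selected": adj < fdr}).sort_values(
                ["adj_p", "p_value"], kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# gene modules along one lineage


@dataclass
class GeneModules:
    assignment: pd.Series       # gene -> module id (1..n_modules)
    smoothed: pd.DataFrame      # genes x pseudotime grid, spline-smoothed
    linkage: np.ndarray
    tau_grid: np.ndarray


def gene_modules(expr_values: np.ndarray, gene_ids: pd.Index,
                 tau: np.ndarray, n_modules: int, smooth_df: int = 10,
                 grid_size: int = 100) -> GeneModules:
    """Ward clustering of lineage genes on 1 - correlation, with smoothing."""
    if expr_values.shape[1] < 2:
        raise ValueError("need >= 2 lineage genes to form modules")
    order = np.argsort(tau, kind="stable")
    X = expr_values[order]
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant genes removed before "
                      "correlation")
    X = X[:, keep]
    gene_ids = gene_ids[keep]
    corr = np.corrcoef(X.T)
    D = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.ward(squareform(D, checks=False))
    modules = hierarchy.fcluster(Z, t=min(n_modules, X.shape[1]),
                                 criterion="maxclust")
    tau_sorted = tau[order]
    grid = np.linspace(tau_sorted.min(), tau_sorted.max(), grid_size)
    B = natural_spline_basis(tau_sorted, df=smooth_df)
    knots = np.quantile(tau_sorted, np.linspace(0, 1, smooth_df + 1))
    Bg = natural_spline_basis(grid, df=smooth_df, knots=knots)
    A = np.column_stack([np.ones(len(tau_sorted)), B])
    Ag = np.column_stack([np.ones(len(grid)), Bg])
    coef, *_ = np.linalg.lstsq(A, X, rcond=None)
    smoothed = pd.DataFrame((Ag @ coef).T, index=gene_ids, columns=grid)
    return GeneModules(pd.Series(modules, index=gene_ids, name="module"),
                       smoothed, Z, grid)


# ---------------------------------------------------------------------------
# vignette-split cluster-graph connectivity


def _knn_undirected_edges(embedding: np.ndarray, k: int) -> np.ndarray:
    """Unique undirected edges of the symmetrised kNN graph, as (m, 2)."""
    n = embedding.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    idx = nn.kneighbors(return_distance=False)
    src = np.repeat(np.arange(n), k)
    dst = idx.ravel()
    a = np.minimum(src, dst)
    b = np.maximum(src, dst)
    return np.unique(np.column_stack([a, b]), axis=0)


def connectivity_ratio(edges: np.ndarray, labels: np.ndarray
                       ) -> pd.DataFrame:
    """PAGA-style observed/expected inter-cluster edge ratio, capped at 1."""
    clusters = sorted(pd.unique(pd.Series(labels)), key=str)
    code = pd.Categorical(labels, categories=clusters).codes
    K = len(clusters)
    sizes = np.bincount(code, minlength=K).astype(float)
    n = len(labels)
    m = len(edges)
    obs = np.zeros((K, K))
    np.add.at(obs, (code[edges[:, 0]], code[edges[:, 1]]), 1.0)
    obs = obs + obs.T
    np.fill_diagonal(obs, 0.0)
    conn = np.zeros((K, K))
    total_pairs = n * (n - 1) / 2.0
    for i in range(K):
        for j in range(i + 1, K):
            expected = m * sizes[i] * sizes[j] / total_pairs
            r = min(obs[i, j] / expected, 1.0) if expected > 0 else 0.0
            conn[i, j] = conn[j, i] = r
    return pd.DataFrame(conn, index=clusters, columns=clusters)


@dataclass
class VignetteGraph:
    connectivity: dict[str, pd.DataFrame]
    edges: pd.DataFrame  # vignette, from, to, connectivity (from = earlier tau)


def vignette_connectivity(embedding: np.ndarray,
                          labels: ClusterLabels | np.ndarray,
                          gestational_week: np.ndarray,
                          pseudotime: np.ndarray,
                          k_neighbors: int = 30,
                          bounds: dict[str, tuple[int, int]] | None = None
                          ) -> VignetteGraph:
    """Cluster-graph connectivity per gestational vignette, tau-oriented."""
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels)
    bounds = bounds if bounds is not None else TRAJECTORY_VIGNETTES
    vig = assign_vignette(gestational_week, bounds).to_numpy()
    conn: dict[str, pd.DataFrame] = {}
    rows = []
    for name in bounds:
        mask = vig == name
        sub_lab = lab[mask]
        present = pd.unique(pd.Series(sub_lab))
        if len(present) < 2:
            warnings.warn(f"vignette {name!r} has < 2 clusters; empty graph")
            conn[name] = pd.DataFrame()
            continue
        edges = _knn_undirected_edges(embedding[mask], k_neighbors)
        C = connectivity_ratio(edges, sub_lab)
        conn[name] = C
        mean_tau = pd.Series(pseudotime[mask]).groupby(sub_lab).mean()
        for i, ci in enumerate(C.index):
            for cj in C.columns[i + 1:]:
                w = float(C.loc[ci, cj])
                if w <= 0:
                    continue
                src, dst = (ci, cj) if mean_tau.get(ci, np.inf) <= \
                    mean_tau.get(cj, np.inf) else (cj, ci)
                rows.append({"vignette": name, "from": src, "to": dst,
                             "connectivity": w})
    return VignetteGraph(conn, pd.DataFrame(
        rows, columns=["vignette", "from", "to", "connectivity"]))


# ---------------------------------------------------------------------------
# fate probabilities


def fate_probabilities(embedding: np.ndarray, pseudotime: np.ndarray,
                       terminal_clusters: list, labels: ClusterLabels | np.ndarray,
                       k_neighbors: int = 15, kernel_scale: float | None = None,
                       cell_ids: pd.Index | None = None) -> pd.DataFrame:
    """Absorption probabilities of a pseudotime-directed walk on the kNN graph.

    Transition weight to a neighbour is logistic in the pseudotime increment
    (scale = sd of delta-tau over kNN edges by default), rows renormalised;
    cells in terminal clusters are absorbing. Probabilities solve the linear
    absorption system exactly.
    """
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels)
    tau = np.asarray(pseudotime, dtype=float)
    if not np.all(np.isfinite(tau)):
        raise ValueError("pseudotime must be finite for every cell")
    terminals = list(terminal_clusters)
    if not terminals:
        raise ValueError("need >= 1 terminal cluster")
    n = len(tau)
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    idx = nn.kneighbors(return_distance=False)
    dtau = tau[idx] - tau[:, None]
    if kernel_scale is None:
        kernel_scale = float(dtau.std())
        if kernel_scale == 0:
            kernel_scale = 1.0
    W = expit(dtau / kernel_scale)
    W = W / W.sum(axis=1, keepdims=True)

    is_term = np.isin(lab, terminals)
    state_of = {t: s for s, t in enumerate(terminals)}
    n_states = len(terminals)

    # cells with no directed path to an absorbing state make the linear
    # system singular; assign them to the nearest terminal centroid
    reachable = is_term.copy()
    changed = True
    while changed:
        changed = False
        newly = ~reachable & reachable[idx].any(axis=1)
        if newly.any():
            reachable |= newly
            changed = True
    stranded = np.flatnonzero(~reachable)
    forced_state = {}
    if len(stranded):
        warnings.warn(f"{len(stranded)} cells cannot reach a terminal state "
                      "on the kNN graph; assigned to the nearest terminal "
                      "centroid")
        cents = {t: embedding[lab == t].mean(axis=0) for t in terminals}
        for c in stranded:
            d = {t: np.linalg.norm(embedding[c] - cents[t]) for t in terminals}
            forced_state[c] = state_of[min(d, key=d.get)]
    absorbing = is_term | ~reachable

    trans = np.flatnonzero(~absorbing)
    tpos = {c: i for i, c in enumerate(trans)}
    if len(trans):
        Q = sparse.lil_matrix((len(trans), len(trans)))
        R = np.zeros((len(trans), n_states))
        for row, c in enumerate(trans):
            for j, w in zip(idx[c], W[c]):
                if absorbing[j]:
                    s = state_of[lab[j]] if is_term[j] else forced_state[j]
                    R[row, s] += w
                else:
                    Q[row, tpos[j]] += w
        A = sparse.identity(len(trans), format="csc") - Q.tocsc()
        F_trans = sparse.linalg.spsolve(A, R)
        if F_trans.ndim == 1:
            F_trans = F_trans[:, None]
    F = np.zeros((n, n_states))
    for i in range(n):
        if is_term[i]:
            F[i, state_of[lab[i]]] = 1.0
        elif i in forced_state:
            F[i, forced_state[i]] = 1.0
        else:
            F[i] = F_trans[tpos[i]]
    if cell_ids is None:
        cell_ids = pd.RangeIndex(n)
    return pd.DataFrame(F, index=cell_ids,
                        columns=[str(t) for t in terminals])
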