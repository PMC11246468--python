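"""Benchmark a query (stem-cell-derived) dataset against the reference atlas.

The query is normalised with the reference's parameters and projected onto
the reference PCA loadings (a deterministic stand-in for joint-graph
integration), clustered jointly with the reference, filtered to clusters
holding more than 100 query cells, positioned along the reference
trajectory by the mean pseudotime of co-clustered reference cells, and
summarised with normalised cell-type scores and Spearman staging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ClusterLabels, CountMatrix
from .preprocess import TransformModel, cluster_graph

MIN_QUERY_CELLS = 100
JOINT_RESOLUTION = 2.25


@dataclass
class JointEmbedding:
    coords: np.ndarray
    origin: np.ndarray          # "reference" | "query" per row
    cell_ids: pd.Index

    def query_mask(self) -> np.ndarray:
        return self.origin == "query"


def project_query(model: TransformModel, reference_embedding: np.ndarray,
                  reference_ids: pd.Index, query: CountMatrix,
                  min_overlap: float = 0.5) -> JointEmbedding:
    """Project query counts onto the reference PCA axes.

    Genes are matched by id (file order is irrelevant); query HVGs missing
    from the reference panel contribute their reference mean (i.e. zero
    after scaling). Fails if less than ``min_overlap`` of the reference HVG
    panel is present in the query.
    """
    hvg = model.hvg
    present = hvg.isin(query.gene_ids)
    overlap = present.mean()
    if overlap < min_overlap:
        missing = list(hvg[~present][:20])
        raise ValueError(
            f"query covers only {overlap:.0%} of the reference HVG panel "
            f"(need >= {min_overlap:.0%}); missing e.g. {missing}")
    lib = query.counts.sum(axis=1, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    X = np.log1p(query.counts / lib * model.target_sum)
    H = np.tile(model.center, (query.n_cells, 1))
    cols_q = query.gene_ids.get_indexer(hvg[present])
    H[:, np.flatnonzero(present)] = X[:, cols_q]
    Z = np.clip((H - model.center) / model.scale, -model.clip, model.clip)
    coords_q = Z @ model.components.T
    coords = np.vstack([reference_embedding, coords_q])
    origin = np.array(["reference"] * len(reference_ids)
                      + ["query"] * query.n_cells, dtype=object)
    ids = reference_ids.append(query.cell_ids)
    return JointEmbedding(coords, origin, ids)


def joint_clusters(joint: JointEmbedding, resolution: float = JOINT_RESOLUTION,
                   min_query_cells: int = MIN_QUERY_CELLS,
                   k_neighbors: int = 30, seed: int = 0
                   ) -> tuple[ClusterLabels, list[int]]:
    """Cluster the joint embedding; retain clusters with > min query cells."""
    labels = cluster_graph(joint.coords, k_neighbors=k_neighbors,
                           resolution=resolution, seed=seed)
    qmask = joint.query_mask()
    retained = []
    for c in range(labels.n_clusters):
        n_query = int(((labels.labels == c) & qmask).sum())
        if n_query > min_query_cells:  # strictly greater
            retained.append(c)
    if not retained:
        warnings.warn("no joint cluster holds enough query cells; empty report")
    return labels, retained


def position_clusters(labels: ClusterLabels, joint: JointEmbedding,
                      reference_pseudotime: pd.Series,
                      retained: list[int]) -> pd.DataFrame:
    """Order retained clusters by mean reference pseudotime.

    Ties are broken by cluster id; retained clusters with no reference cells
    carrying pseudotime are excluded with a warning.
    """
    qmask = joint.query_mask()
    rows = []
    for c in retained:
        in_c = labels.labels == c
        ref_ids = joint.cell_ids[in_c & ~qmask]
        tau = reference_pseudotime.reindex(ref_ids).dropna()
        if tau.empty:
            warnings.warn(f"joint cluster {c} has no reference pseudotime; "
                          "excluded from positioning")
            continue
        rows.append({"cluster": c,
                     "n_query_cells": int((in_c & qmask).sum()),
                     "n_reference_cells": len(tau),
                     "mean_pseudotime": float(tau.mean())})
    pos = pd.DataFrame(rows, columns=["cluster", "n_query_cells",
                                      "n_reference_cells", "mean_pseudotime"])
    pos = pos.sort_values(["mean_pseudotime", "cluster"],
                          kind="stable").reset_index(drop=True)
    pos["position"] = np.arange(len(pos))
    return pos


def benchmark_report(labels: ClusterLabels, joint: JointEmbedding,
                     positions: pd.DataFrame,
                     query_scores: pd.DataFrame | None = None,
                     query_staging: pd.DataFrame | None = None
                     ) -> pd.DataFrame:
    """Join positions, per-cluster query score medians, and staging rows.

    ``query_scores`` is a cells x reference-type normalised score matrix for
    the query cells; ``query_staging`` is a clusters x stage Spearman matrix
    indexed by joint cluster id.
    """
    report = positions.copy()
    if report.empty:
        return report
    qmask = joint.query_mask()
    if query_scores is not None:
        med_rows = []
        for c in report["cluster"]:
            ids = joint.cell_ids[(labels.labels == c) & qmask]
            missing = ids.difference(query_scores.index)
            if len(missing):
                raise KeyError(f"cluster {c}: query cells missing from the "
                               f"score matrix (e.g. {list(missing[:5])})")
            med_rows.append(query_scores.loc[ids].median(axis=0)
                            .rename(lambda t: f"score_{t}"))
        report = pd.concat(
            [report.reset_index(drop=True),
             pd.DataFrame(med_rows).reset_index(drop=True)], axis=1)
    if query_staging is not None:
        missing = [c for c in report["cluster"] if c not in query_staging.index]
        if missing:
            raise KeyError(f"clusters missing from staging matrix: {missing}")
        stag = query_staging.loc[report["cluster"]].reset_index(drop=True)
        stag.columns = [f"rho_stage_{s}" for s in stag.columns]
        report = pd.concat([report, stag], axis=1)
    return report
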