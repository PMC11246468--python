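"""End-to-end pipeline driver over the synthetic atlas.

Stages: simulate -> preprocess -> markers -> composition -> trajectory ->
spatial -> signaling -> benchmark. Each stage writes CSV/TSV outputs under
its own subdirectory plus a JSON manifest of every parameter and seed, and
the whole run is deterministic given the configuration.

Cluster annotation note: the emulated study annotated clusters manually
from marker genes. Here clusters are annotated by the majority planted
type of their cells — the synthetic ground truth stands in for the manual
step — and the annotated labels drive the downstream stages.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import (benchmark as bm, composition, io, markers, preprocess,
               signaling, spatial, synthetic, trajectory)
from .datatypes import ConfigError
from .vignettes import SIGNALING_VIGNETTES, TRAJECTORY_VIGNETTES

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "markers", "composition", "trajectory",
          "spatial", "signaling", "benchmark")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_samples": 19, "n_cells_per_sample": 300, "n_genes": 600,
        "marker_effect": 1.5, "dispersion": 10.0,
    },
    "qc": {"min_features": 200, "max_mito_frac": 0.15, "min_cells_per_gene": 3},
    "transform": {"n_hvg": 3000, "n_pcs": 30, "target_sum": "median"},
    "cluster": {"k_neighbors": 30, "resolutions": [0.1, 0.5, 1.0],
                "in_prop_threshold": 0.1},
    "markers": {"logfc_min": 0.25, "top_k": 100, "score_bins": 25,
                "min_cells_in_pool": 10},
    "composition": {"prior_sd": 2.5, "margin": 0.5},
    "trajectory": {"fdr": 0.01, "spline_df": 10, "n_modules": 4,
                   "k_neighbors": 30, "fate_k_neighbors": 15},
    "spatial": {"radius": 75.0, "cooccurrence_radii": [25, 50, 75, 100, 150],
                "n_perms": 500, "focal_type": "progenitor"},
    "signaling": {"n_perms": 100, "temporal_n_perms": 20000, "alpha": 0.01,
                  "hill_k": 0.5, "receiver": "progenitor"},
    "benchmark": {"resolution": 2.25, "min_query_cells": 100,
                  "k_neighbors": 30, "stage_top_k": 50,
                  "query_gw": 12, "query_n_cells": 800},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config field: {where}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config field {where} must be a mapping")
            out[key] = _merge(base[key], val, where)
        else:
            out[key] = val
    return out


def make_config(overrides: dict | None = None) -> dict:
    """Full pipeline configuration: defaults deep-merged with overrides."""
    return _merge(DEFAULT_CONFIG, overrides or {})


def demo_config() -> dict:
    """Small configuration exercising every stage in well under a minute."""
    return make_config({
        "simulate": {"n_samples": 10, "n_cells_per_sample": 200,
                     "n_genes": 400},
        "transform": {"n_hvg": 300},
        "spatial": {"n_perms": 200},
        "benchmark": {"query_n_cells": 600},
    })


def run_pipeline(config: dict | None = None, outdir: str | Path = "results",
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run the pipeline and write per-stage outputs plus a manifest.

    ``stages`` selects which stages' outputs are written; computation always
    proceeds in order up to the last requested stage, since later stages
    consume earlier results in memory. Returns a dict of key in-memory
    artifacts for programmatic use.
    """
    cfg = make_config(config) if not _is_full(config) else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    last = max(STAGES.index(s) for s in stages)
    want = set(stages)
    art: dict = {"config": cfg}

    # --- simulate ---------------------------------------------------------
    sim = synthetic.SimConfig(seed=cfg["seed"], **cfg["simulate"])
    atlas = synthetic.make_atlas(sim)
    art["atlas"] = atlas
    if "simulate" in want:
        d = outdir / "simulate"
        io.write_counts(atlas.counts, d / "counts")
        io.write_spatial(atlas.spatial, d / "spatial_cells.csv")
        io.write_spot_weights(atlas.spot_weights, d / "spot_weights.csv")
        io.write_table(atlas.lr_database, d / "lr_database.csv")
        io.write_table(atlas.lr_truth, d / "lr_truth.csv")
        truth_markers = pd.DataFrame(
            [(t, g) for t, gs in atlas.truth_markers.items() for g in gs],
            columns=["set_name", "gene"])
        io.write_table(truth_markers, d / "truth_markers.tsv")
    if STAGES.index("simulate") == last:
        _finish(cfg, outdir)
        return art

    # --- preprocess -------------------------------------------------------
    pc = cfg["qc"]
    qc = preprocess.qc_filter(atlas.counts, **pc)
    expr, embedding, model = preprocess.transform(qc, **cfg["transform"])
    cl = cfg["cluster"]
    labelings = [preprocess.cluster_graph(embedding, cl["k_neighbors"], r,
                                          seed=cfg["seed"])
                 for r in cl["resolutions"]]
    stability = preprocess.resolution_stability(labelings,
                                                cl["in_prop_threshold"])
    chosen = labelings[-1]
    for lab in labelings:
        if lab.resolution == stability.recommended_resolution:
            chosen = lab
    # annotate clusters by majority planted type (stands in for manual
    # annotation); annotated labels drive the downstream stages
    truth = qc.cell_meta["true_type"]
    ann = {c: truth[chosen.labels == c].mode().iloc[0]
           for c in range(chosen.n_clusters)}
    cell_type = pd.Series([ann[c] for c in chosen.labels], index=qc.cell_ids,
                          name="cell_type")
    art.update(qc=qc, expr=expr, embedding=embedding, model=model,
               labels=chosen, cell_type=cell_type, stability=stability)
    if "preprocess" in want:
        d = outdir / "preprocess"
        lab_tab = pd.DataFrame({"cell_id": qc.cell_ids,
                                **{f"res_{l.resolution}": l.labels
                                   for l in labelings},
                                "cell_type": cell_type.to_numpy()})
        io.write_table(lab_tab, d / "cluster_labels.csv")
        io.write_table(stability.edges, d / "stability_edges.csv")
        emb = pd.DataFrame(embedding, index=qc.cell_ids,
                           columns=[f"PC{i+1}" for i in range(embedding.shape[1])])
        io.write_table(emb.reset_index(), d / "embedding.csv")
    if STAGES.index("preprocess") == last:
        _finish(cfg, outdir)
        return art

    # --- markers ----------------------------------------------------------
    mk = cfg["markers"]
    marker_tab = markers.rank_markers(expr, cell_type.to_numpy(),
                                      logfc_min=mk["logfc_min"])
    gene_sets = {t: markers.top_gene_set(marker_tab, t, k=mk["top_k"])
                 for t in sorted(cell_type.unique())
                 if (marker_tab.table["cluster"] == t).any()}
    scores = markers.score_matrix(expr, gene_sets, cell_types=cell_type,
                                  min_cells_in_pool=mk["min_cells_in_pool"],
                                  n_bins=mk["score_bins"], seed=cfg["seed"])
    art.update(marker_table=marker_tab, gene_sets=gene_sets, scores=scores)
    if "markers" in want:
        d = outdir / "markers"
        io.write_table(marker_tab.table, d / "marker_table.csv")
        sets_tab = pd.DataFrame([(n, g) for n, gs in gene_sets.items()
                                 for g in gs.genes],
                                columns=["set_name", "gene"])
        io.write_table(sets_tab, d / "gene_sets.tsv")
        io.write_table(scores.reset_index(), d / "scores.csv")
    if STAGES.index("markers") == last:
        _finish(cfg, outdir)
        return art

    # --- composition ------------------------------------------------------
    comp_tab = (qc.cell_meta.assign(type=cell_type)
                .groupby(["sample_id", "gestational_week", "type"],
                         observed=True).size().rename("count").reset_index())
    totals = comp_tab.groupby("sample_id")["count"].sum().rename("total")
    comp_tab = comp_tab.merge(totals, on="sample_id")
    comp_fits = composition.fit_all_types(comp_tab, **cfg["composition"])
    art["composition"] = comp_fits
    if "composition" in want:
        d = outdir / "composition"
        io.write_table(comp_tab, d / "counts_by_sample.csv")
        io.write_table(comp_fits, d / "model_selection.csv")
    if STAGES.index("composition") == last:
        _finish(cfg, outdir)
        return art

    # --- trajectory -------------------------------------------------------
    tj = cfg["trajectory"]
    spec = atlas.config.trajectory_spec
    traj_types = sorted({t for p in spec.paths for t in p})
    on_traj = cell_type.isin(traj_types).to_numpy()
    root = spec.paths[0][0]
    traj_labels = cell_type[on_traj].to_numpy()
    traj_emb = embedding[on_traj]
    tmodel = trajectory.infer_backbone(traj_emb, traj_labels, root,
                                       cell_ids=qc.cell_ids[on_traj])
    assoc = trajectory.association_test(expr.values[on_traj], expr.gene_ids,
                                        tmodel, fdr=tj["fdr"],
                                        df=tj["spline_df"])
    lineage0 = next(iter(assoc)) if assoc else None
    modules = None
    if lineage0 is not None:
        sel = assoc[lineage0][assoc[lineage0]["selected"]]["gene"]
        if len(sel) >= 2:
            on_l = (tmodel.best_lineage == lineage0).to_numpy()
            cols = expr.gene_index(sel)
            modules = trajectory.gene_modules(
                expr.values[on_traj][on_l][:, cols], pd.Index(sel),
                tmodel.pseudotime.to_numpy()[on_l], tj["n_modules"],
                smooth_df=tj["spline_df"])
    vgraph = trajectory.vignette_connectivity(
        traj_emb, traj_labels,
        qc.cell_meta["gestational_week"].to_numpy()[on_traj],
        tmodel.pseudotime.to_numpy(), k_neighbors=tj["k_neighbors"],
        bounds=TRAJECTORY_VIGNETTES)
    terminals = [p[-1] for p in spec.paths if p[-1] in set(traj_labels)]
    fates = trajectory.fate_probabilities(
        traj_emb, tmodel.pseudotime.to_numpy(), terminals, traj_labels,
        k_neighbors=tj["fate_k_neighbors"], cell_ids=qc.cell_ids[on_traj])
    art.update(trajectory=tmodel, association=assoc, modules=modules,
               vignette_graph=vgraph, fates=fates)
    if "trajectory" in want:
        d = outdir / "trajectory"
        io.write_table(pd.DataFrame({
            "cell_id": tmodel.pseudotime.index,
            "pseudotime": tmodel.pseudotime.to_numpy(),
            "lineage": tmodel.best_lineage.to_numpy()}), d / "pseudotime.csv")
        for name, tab in assoc.items():
            io.write_table(tab, d / f"lineage_genes_{name}.tsv")
        if modules is not None:
            io.write_table(modules.assignment.rename("module").reset_index()
                           .rename(columns={"index": "gene"}),
                           d / "gene_modules.csv")
        io.write_table(vgraph.edges, d / "vignette_edges.csv")
        io.write_table(fates.reset_index(), d / "fate_probabilities.csv")
    if STAGES.index("trajectory") == last:
        _finish(cfg, outdir)
        return art

    # --- spatial ----------------------------------------------------------
    sp = cfg["spatial"]
    cooc = spatial.cooccurrence_profile(atlas.spatial, sp["focal_type"],
                                        sp["cooccurrence_radii"])
    enrich = spatial.neighborhood_enrichment(atlas.spatial, sp["radius"],
                                             n_perms=sp["n_perms"],
                                             seed=cfg["seed"])
    coloc = spatial.weight_colocalization(atlas.spot_weights)
    prox = spatial.proximal_types(enrich, sp["focal_type"])
    art.update(cooccurrence=cooc, enrichment=enrich, colocalization=coloc,
               proximal=prox)
    if "spatial" in want:
        d = outdir / "spatial"
        io.write_table(cooc.reset_index(), d / "cooccurrence.csv")
        io.write_table(enrich.rename_axis("type").reset_index(),
                       d / "enrichment_z.csv")
        io.write_table(coloc.correlation.rename_axis("type").reset_index(),
                       d / "weight_correlation.csv")
        io.write_table(pd.DataFrame({"proximal_type": sorted(prox)}),
                       d / "proximal_types.csv")
    if STAGES.index("spatial") == last:
        _finish(cfg, outdir)
        return art

    # --- signaling --------------------------------------------------------
    sg = cfg["signaling"]
    lr_db = atlas.lr_database
    tables = signaling.vignette_tables(
        expr, cell_type, lr_db, bounds=SIGNALING_VIGNETTES,
        n_perms=sg["n_perms"], alpha=sg["alpha"], hill_k=sg["hill_k"],
        seed=cfg["seed"])
    restrict = spatial.proximal_types(enrich, sg["receiver"])
    calls = signaling.temporal_compare(
        expr, cell_type, lr_db, tables, restrict_senders=restrict,
        bounds=SIGNALING_VIGNETTES, n_perms=sg["temporal_n_perms"],
        alpha=sg["alpha"], hill_k=sg["hill_k"], seed=cfg["seed"])
    flows, flow_tests = signaling.information_flow(tables)
    art.update(interaction_tables=tables, temporal_calls=calls,
               information_flow=flows, flow_tests=flow_tests)
    if "signaling" in want:
        d = outdir / "signaling"
        for name, tab in tables.items():
            io.write_table(tab, d / f"interactions_{name}.csv")
        io.write_table(calls, d / "temporal_calls.csv")
        io.write_table(flows.reset_index(), d / "information_flow.csv")
        io.write_table(flow_tests, d / "flow_tests.csv")
    if STAGES.index("signaling") == last:
        _finish(cfg, outdir)
        return art

    # --- benchmark --------------------------------------------------------
    bk = cfg["benchmark"]
    query = synthetic.make_query(atlas.config, bk["query_n_cells"],
                                 gw=bk["query_gw"], seed=cfg["seed"])
    joint = bm.project_query(model, embedding, qc.cell_ids, query)
    jlabels, retained = bm.joint_clusters(
        joint, resolution=bk["resolution"],
        min_query_cells=bk["min_query_cells"],
        k_neighbors=bk["k_neighbors"], seed=cfg["seed"])
    # reference pseudotime only exists on the trajectory subset
    positions = bm.position_clusters(jlabels, joint, tmodel.pseudotime,
                                     retained)
    # staging: per-GW reference pseudobulk vs per-cluster query pseudobulk
    stage_series = qc.cell_meta["gestational_week"].astype(str)
    stage_sets = markers.stage_gene_sets(expr, stage_series,
                                         k=bk["stage_top_k"])
    ref_prof = pd.DataFrame(expr.values, index=expr.cell_ids,
                            columns=expr.gene_ids).groupby(stage_series).mean()
    qlib = query.counts.sum(axis=1, keepdims=True).astype(float)
    qlog = pd.DataFrame(np.log1p(query.counts / np.maximum(qlib, 1)
                                 * model.target_sum),
                        index=query.cell_ids, columns=query.gene_ids)
    qmask = joint.query_mask()
    qcluster = pd.Series(jlabels.labels[qmask],
                         index=joint.cell_ids[qmask])
    prof_rows = {c: qlog.loc[qcluster[qcluster == c].index].mean()
                 for c in retained}
    staging = None
    if prof_rows:
        qprof = pd.DataFrame(prof_rows).T
        staging = markers.stage_correlation(qprof, ref_prof, stage_sets)
    report = bm.benchmark_report(jlabels, joint, positions,
                                 query_staging=staging)
    art.update(query=query, joint=joint, joint_labels=jlabels,
               retained=retained, positions=positions, report=report,
               staging=staging)
    if "benchmark" in want:
        d = outdir / "benchmark"
        io.write_table(positions, d / "positions.csv")
        io.write_table(report, d / "report.csv")
        if staging is not None:
            io.write_table(staging.rename_axis("cluster").reset_index(),
                           d / "staging.csv")
    _finish(cfg, outdir)
    return art


def _is_full(config) -> bool:
    return isinstance(config, dict) and set(config) == set(DEFAULT_CONFIG)


def _finish(cfg: dict, outdir: Path) -> None:
    io.write_manifest({"config": cfg, "stages": list(STAGES)},
                      outdir / "manifest.json")
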