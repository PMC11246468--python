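"""Generate the synthetic developing-lung atlas and write it to disk.

Emits the cells x genes count matrix (MatrixMarket + TSV sidecars), the
spatial centroid map, grid-spot deconvolution weights, the ligand-receptor
database, and the planted ground truth used by the later analyses.
"""

from lungdyn import pipeline

art = pipeline.run_pipeline(pipeline.make_config(), "results/pipeline",
                            stages=("simulate",))
atlas = art["atlas"]
meta = atlas.counts.cell_meta

print(f"atlas: {atlas.counts.n_cells} cells x {atlas.counts.n_genes} genes "
      f"over {meta['sample_id'].nunique()} samples "
      f"(GW {meta['gestational_week'].min()}-{meta['gestational_week'].max()})")
print("cells per type:")
print(meta["true_type"].value_counts().to_string())
print(f"spatial map: {len(atlas.spatial.table)} cells, "
      f"{len(atlas.spot_weights.weights)} occupied spots")
print(f"ligand-receptor database: {len(atlas.lr_database)} pairs "
      f"({len(atlas.lr_truth)} planted, rest decoys)")
print("outputs under results/pipeline/simulate/")
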