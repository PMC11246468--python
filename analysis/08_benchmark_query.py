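"""Benchmark a synthetic stem-cell-derived query against the atlas.

Draws a query dataset from the reference generative model, projects it
onto the reference PCA axes, clusters the joint embedding at resolution
2.25, keeps clusters with more than 100 query cells, positions them by
mean reference pseudotime, and stages each cluster by Spearman
correlation against per-week reference profiles over the top-50
week-discriminating genes.
"""

from lungdyn import pipeline

art = pipeline.run_pipeline(pipeline.make_config(), "results/pipeline",
                            stages=("benchmark",))

print(f"query: {art['query'].n_cells} cells at GW "
      f"{art['query'].cell_meta['gestational_week'].iloc[0]}")
print(f"joint clustering: {art['joint_labels'].n_clusters} clusters, "
      f"{len(art['retained'])} retained (> 100 query cells)")
print("\npositions along the reference trajectory:")
print(art["positions"].to_string(index=False))
if art["staging"] is not None:
    from lungdyn import markers

    best = markers.best_stage(art["staging"])
    print("\nbest-matching gestational week per retained cluster:")
    print(best.to_string())
print("outputs under results/pipeline/benchmark/")
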