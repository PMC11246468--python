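"""Spatial organisation: co-occurrence, neighbourhood enrichment,
spot-weight colocalization, and the spatially-close sender set.

Co-occurrence profiles give the type composition within growing radii of
the progenitor (focal) cells; enrichment z-scores come from a
label-permutation test on the radius-75 neighbour graph; deconvolution
weight correlations show which types share spots.
"""

from lungdyn import pipeline

art = pipeline.run_pipeline(pipeline.make_config(), "results/pipeline",
                            stages=("spatial",))

print("co-occurrence around progenitor cells (rows = radius):")
print(art["cooccurrence"].round(3).to_string())
print("\nneighbourhood enrichment z (radius 75):")
print(art["enrichment"].round(1).to_string())
print("\nweight-colocalization dendrogram order:",
      art["colocalization"].order)
print("types spatially close to progenitor (z > 0):",
      sorted(art["proximal"]))
print("outputs under results/pipeline/spatial/")
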