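"""Marker genes and cell-type scores for the annotated clusters.

One-vs-rest Wilcoxon markers (natural-log fold change > 0.25, positive
only, BH within cluster), top-100 gene sets, and control-matched
cell-type scores normalised so each type's own-cell median is 1. Reports
how many planted marker genes land in their own type's gene set.
"""

from lungdyn import pipeline

art = pipeline.run_pipeline(pipeline.make_config(), "results/pipeline",
                            stages=("markers",))
atlas, gene_sets, scores = art["atlas"], art["gene_sets"], art["scores"]

print(f"marker table: {len(art['marker_table'].table)} retained rows over "
      f"{art['marker_table'].table['cluster'].nunique()} types")
for t, truth_genes in atlas.truth_markers.items():
    if t in gene_sets:
        recall = len(set(truth_genes) & set(gene_sets[t].genes)) / len(truth_genes)
        print(f"  {t}: planted-marker recall in top-100 set = {recall:.2f}")
truth = art["qc"].cell_meta["true_type"]
for t in scores.columns:
    med = scores.loc[(truth == t).to_numpy(), t].median()
    print(f"  {t}: median own-type score = {med:.3f}")
print("outputs under results/pipeline/markers/")
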