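# Methods

`lungdyn` implements the quantitative backbone of a developing-human-lung
single-cell atlas analysis — temporal cell-type composition modelling,
trajectory and pseudotime dynamics, spatial neighbourhood statistics,
gestational-vignette ligand–receptor analysis, and organoid-to-atlas
benchmarking — and exercises it end-to-end on a synthetic atlas generator
with planted ground truth. This note records the models, their
assumptions, the defaults that matter, and what the synthetic test-bed
does and does not establish about real data.

## The synthetic atlas generator

The generator (`lungdyn.synthetic`) emulates a cross-sectional fetal-lung
design: 19 samples, one integer gestational week (GW) each, spanning
GW 10–19; 300 cells per sample and 600 genes by default. It produces
counts, spatial centroids, spot-level deconvolution weights, a
ligand–receptor database, and complete ground truth (type, pseudotime,
branch, trend coefficients, planted interactions).

**Counts.** Negative binomial with gene-specific means, dispersion
(size) 10, and a per-sample lognormal depth factor (sd 0.15). Background
genes have a lognormal baseline around 0.6 counts/cell — enough that the
median cell clears the 200-detected-gene QC floor with margin, so QC
removes a tail of cells rather than whole unlucky samples.

**Cell types and composition.** Five types (progenitor, transitional,
ciliated, neuroendocrine, stromal). Each type's expected proportion
follows a constant, linear, or quadratic trend in centred GW on the logit
scale; the inverse-logit values are renormalised across types, so a
type's *realised* proportion also inherits curvature from its
neighbours' trends. Defaults: progenitor declines (slope −0.35/week on
the logit scale), ciliated rises (+0.35), neuroendocrine peaks mid-window
(curvature −0.08), transitional and stromal are constant. Magnitudes were
chosen for testability — the emulated study does not report effect sizes.

**Markers.** Ten disjoint marker genes per type, baseline ≈3 counts/cell,
elevated by `marker_effect` (default 1.5, natural-log scale) in the own
type. Markers of types that sit on the trajectory ramp on and off
*smoothly in pseudotime* (logistic edges of width 0.02) rather than
switching at the discretised type boundaries: differentiation is a
continuum, and hard switches would disconnect adjacent types in
expression space (with visible consequences: a k-nearest-neighbour graph
with no edges between consecutive stages, and an absorbing-chain fate
system with no path to absorption).

**Trajectory.** A branching path
progenitor → transitional → {ciliated, neuroendocrine}. Each type on a
path occupies an equal slice of latent pseudotime τ ∈ [0, 1]; cells draw
τ uniformly within their slice. Sixty pseudotime genes follow logistic
activations a·σ(±(τ−m)/0.08) with amplitude 2 and midpoints spread over
[0.15, 0.85]; genes with midpoints past the bifurcation are
branch-specific (and also active in the trunk, where their activation is
naturally near zero), so the two branches diverge in expression and the
centroid tree is a genuine Y.

**Gestational maturation.** Forty genes vary log-linearly with
standardised GW (alternating signs, swings 0.25–0.75). These model the
week-level maturation programs that make gestational stages
distinguishable; without them, central weeks would have no discriminating
genes and week-resolution staging would be unidentifiable.

**Space.** Cells are placed on a [0, 1000]² plane (so the reference
75-unit radius is meaningful at default density): two niches of radius
220 with distinct type mixtures plus a uniform background. Spot weights
are local type proportions on a 100-unit grid (rows sum to 1).

**Signalling.** A small ligand–receptor–pathway database mixes planted
pairs — ligand elevated (log-effect 2) in the sender type, optionally
only in one gestational vignette; receptor constitutively elevated in the
receiver — with flat "decoy" pairs expressed everywhere. Ligand baselines
are ≈0.8 counts/cell so that a vignette-specific elevation shifts the
sender library by ~1%; library-size closure (one gene up ⇒ all other
normalised values slightly down) is therefore kept below between-sample
noise rather than pretending it does not exist.

**What the generator does not model:** ambient RNA, doublets, batch
effects beyond depth scaling, spatially varying expression within a type,
cell-cycle structure, or any feedback between signalling and expression.
Passing recovery tests on this test-bed demonstrates the estimators'
correctness and calibration under the assumed generative structure — not
robustness to the full messiness of real tissue.

## Preprocessing

QC removes cells with <200 detected genes or >15% mitochondrial counts
(computed on the raw matrix), then genes detected in <3 surviving cells;
cell filters run once, before the gene filter. Normalisation scales each
cell to the median library and applies log(1+x). Highly variable genes
are ranked by the dispersion (variance/mean of normalised counts)
z-scored within 20 equal-frequency mean bins; the top 3000 (or all, if
fewer) are z-scaled, clipped at ±10, and reduced to 30 principal
components by exact SVD with a deterministic sign convention. Clustering
is Leiden modularity (RBConfiguration, seeded, via `leidenalg`) on a
shared-nearest-neighbour graph (k=30, Jaccard weights, pruned below
1/15). The cluster-tree stability diagnostic computes, for each cluster
at one resolution, the fraction of its cells contributed by each cluster
at the previous resolution; a resolution is flagged over-clustered when
any cluster draws ≥ the threshold (default 0.1) from two or more parents,
and the largest unflagged resolution is recommended. Note the diagnostic
flags *merges from multiple parents*, not pure splits: resolutions that
cleanly split a type into age substructure are not flagged.

## Marker statistics

One-vs-rest Wilcoxon rank-sum per gene per cluster; exact (tie-aware
enumeration over group assignments) when both groups have ≤8 cells,
normal approximation with tie and continuity corrections otherwise. Fold
change is ln((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1)); rows at or
below 0.25 (or non-positive) are dropped *before* Benjamini–Hochberg
adjustment, which is applied within each cluster. Gene-set scores follow
the control-matched scheme: score = mean expression over the set minus
mean over controls sampled (seeded, 50 per set gene) from
expression-matched bins (25) of the background pool, the pool being genes
expressed in more than 10 cells. Normalised score matrices divide each
type's column by the median score of its own cells, making that median
exactly 1. Staging computes one-stage-vs-rest markers per gestational
week (top 50), takes the union as a panel, and reports Spearman
correlations of query mean profiles against per-week reference profiles;
group means (not per-cell profiles) are used.

## Composition trends

Per-sample counts of a focal type out of all QC-passing cells are
binomial with a logit link and constant/linear/quadratic dependence on
GW. The week covariate is centred and scaled to unit sd; all coefficients
carry N(0, 2.5²) priors. Fits are MAP via damped Newton iterations; 95%
intervals come from the Laplace approximation at the MAP, propagated
through the inverse logit. The reference analysis fits these models by
MCMC with an approximate LOO criterion; this package deliberately
substitutes MAP + Laplace + *exact* refit-LOO (each sample held out, the
model refit, the held-out binomial log density summed), which is
deterministic and cheap at n = 19 samples.

Family selection picks the *simplest* family whose LOO score is within a
parsimony margin (default 0.5 nats) of the best score. A plain argmax
over LOO scores prefers a quadratic over a true constant ≈13–14% of the
time (LOO behaves like AIC: P(χ²₂ > 2·k_extra)); the margin is the
standard one-standard-error-style correction and brings that overselection
to ≈6–8% while leaving strong trends (ΔLOO ≫ 0.5) untouched. Intervals
are reported for the selected family only, conditional on selection.

## Trajectories

The backbone is the minimum spanning tree over cluster centroids in PC
space; lineages are the root-to-leaf paths. A cell's pseudotime is the
arc position of its orthogonal projection onto the piecewise-linear
backbone of its best lineage; the first and last segments extend beyond
the terminal centroids (otherwise all cells outside the centroid span
collapse onto the endpoints), and pseudotime is shifted to be
non-negative. This replaces the principal-curves smoothing stage of
curve-based trajectory tools with a simpler deterministic construction.
Lineage weights are normalised inverse squared distances to each
lineage's backbone; cells on the shared trunk weigh ≈ equally on all
lineages.

Lineage-associated genes: natural cubic spline regression of expression
on pseudotime (df = 10, knots at quantiles — the "general additive model
with 10 splines" convention) against an intercept-only null, F-tested
per gene, BH-adjusted within each lineage separately, selected at
adjusted p < 0.01. A cell contributes to every lineage with weight
≥ 0.8/n_lineages, so trunk cells are tested on all lineages. Gene
modules: Ward linkage on 1 − Pearson correlation across τ-ordered cells,
cut at a requested module count; heatmap rows are spline-smoothed
(df 10) on a τ grid.

Vignette-split cluster graphs: within each gestational vignette
(early GW 10–13, mid 14–16, late 17–19 for trajectory work), connectivity
between two clusters is the observed number of symmetrised-kNN edges
joining them divided by the expectation under random edge placement given
cluster sizes, capped at 1; edges are oriented from the cluster with
lower mean pseudotime. Under strong type separation these ratios are
small (a handful of contact edges against a large random expectation) —
the magnitudes are comparable across pairs, not absolute probabilities.

Fate probabilities: on the kNN graph, the transition weight to a
neighbour is logistic in the pseudotime increment,
σ(Δτ/scale) with scale defaulting to the sd of Δτ over edges, rows
renormalised; cells of terminal clusters are absorbing, and absorption
probabilities solve the linear system exactly. Transient cells with no
directed path to any absorbing state (possible on disconnected graphs)
are assigned to the nearest terminal centroid with a warning instead of
producing a silently singular solve.

## Spatial statistics

Co-occurrence: for each radius, every non-focal cell within a closed
Euclidean ball of any focal cell joins a pool (once); the profile is the
type composition of the pool. Pooling over focal cells (rather than
averaging per-cell profiles) was chosen and is exposed; an empty pool
yields missing values, not zeros. Neighbourhood enrichment counts
radius-graph edges (default radius 75) between each unordered type pair
and compares against seeded label permutations; z = (obs − mean)/sd.
Spot-weight colocalization is the Pearson correlation of deconvolution
weight columns across spots, ordered by average-linkage clustering on
1 − r. "Spatially close" types for signalling default to enrichment
z > 0 with the focal type — the quantitative rule behind the reference
analysis' proximity subset is unstated, so the default here is explicit
and configurable.

## Ligand–receptor signalling

Interaction probability is a minimal mass-action Hill form: with L the
25%-trimmed mean of ligand expression in the sender and R the geometric
mean over receptor subunits of their trimmed means in the receiver,
p = LR/(0.5 + LR). This deliberately omits the cofactor/agonist
machinery of full communication frameworks; the *significance* scheme is
the one that matters downstream: cell-type labels are permuted (seeded,
default 100 draws), p = (1 + #{null ≥ obs})/(1 + n), significant at
p < 0.01. Because library-size closure induces real (if small)
differences in normalised expression between types, broadly expressed
pairs can be genuinely "significant" without any planted biology — the
temporal contrast below, not raw significance, is the discovery
statistic.

Temporal contrasts are made only for interactions that are significant in
at least one vignette and whose sender is spatially close to the
receiver (vignettes: early GW 10–13, mid 14–16, late 18–19 here; GW 17
falls in no bin). The statistic aggregates hierarchically: per-sample
trimmed means of ligand and receptor, averaged over the samples of each
vignette, multiplied, and mapped to the log scale (the logit of the Hill
probability), where strong switches are not compressed by saturation.
The contrast is Δ = log-intensity(early) − max over mid/late; the null
permutes the *sample-to-vignette assignment*. Samples — not cells — are
the exchangeable unit: the vignette is a sample-level covariate, and a
cell-level shuffle understates the null variance badly enough to flag
1–2% library-closure shifts as discoveries. One-sided p-values for both
directions are Holm-adjusted across the whole candidate family and
called at adjusted p < 0.01, so the familywise false-call rate is
controlled at 1% per run; the default 20 000 vectorised permutations keep
the attainable p floor below the Holm threshold for ~100 candidates.
Calls in the "late-up" direction are intrinsically lower-powered under
this contrast: the max over two bins is easily mimicked by null
arrangements that concentrate the elevated samples in either bin.

Information flow is the sum of significant interaction probabilities per
pathway per vignette; vignette pairs are compared by a paired Wilcoxon
signed-rank test across pathways, computed exactly (dynamic programming
over the signed-rank distribution on doubled midranks; tie-aware; zero
differences dropped; p = 1 if none remain) for up to 25 pathways.

## Benchmarking a query dataset

Query counts are normalised with the reference's parameters (target sum,
HVG panel, per-gene centring and scale, clip) and projected onto the
reference PCA loadings; genes are matched by identifier and missing panel
genes contribute the reference mean (zero after scaling). This
deterministic reference-projection replaces graph-based batch
integration; it is sufficient for the positioning contract and exactly
reproducible. The joint embedding is clustered at resolution 2.25;
clusters with strictly more than 100 query cells are retained, positioned
by the mean reference pseudotime of their reference cells (ties by
cluster id), and summarised together with normalised cell-type score
medians and per-week Spearman staging. Retained clusters whose reference
cells carry no pseudotime (e.g. off-trajectory types) are excluded from
positioning with a warning.

## Pipeline, determinism and problem sizes

`lungdyn.pipeline.run_pipeline` chains all stages on the synthetic atlas,
writing CSV/TSV/MatrixMarket outputs and a JSON manifest of every
parameter and seed; reruns are byte-identical. Clusters are annotated by
their majority planted type — the ground truth stands in for the
reference study's manual marker-based annotation step. Default problem
sizes (19 × 300 cells, 600 genes; 2 000-cell spatial maps; 100–20 000
permutations depending on the statistic; 20-replicate benchmark runs and
100-replicate composition recoveries) were chosen so the complete test
suite and the acceptance script each run in a couple of minutes on one
CPU while keeping every recovery check well-powered.

## Known limitations

* The backbone is piecewise-linear; strongly curved manifolds would bias
  arc pseudotime where a principal curve would not.
* The composition model treats types marginally; a joint multinomial
  model would propagate the renormalisation constraint that makes a
  "constant" type's realised proportion drift when its neighbours trend.
* Temporal signalling calls inherit the coarse resolution of the
  sample-level permutation group; designs with few samples per vignette
  (≲4 total) cannot reach p < 0.01.
* The Hill interaction model ignores cofactors, antagonists and
  spatially resolved signalling; spatial data only restricts sender sets.
* The permutation significance of interactions is liberal for broadly
  expressed genes because library closure is a real effect; treat the
  vignette contrast, not raw significance, as the discovery statistic.
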