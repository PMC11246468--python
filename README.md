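# lungdyn

Temporal, spatial and signalling dynamics of a developing-lung
single-cell atlas — as a tested, reusable pipeline exercised end-to-end
on a fully synthetic test-bed with planted ground truth.

Studies of human fetal lung development profile tens of thousands of
cells across gestational weeks (GW), asking how cell-type composition
shifts with age, which differentiation trajectories connect progenitors
to specialised epithelial types, how cell types organise in space, and
which ligand–receptor signals switch between early and late gestation.
`lungdyn` implements the statistical machinery those questions need:

* **Composition trends** — per-type binomial models with logit link and
  constant/linear/quadratic dependence on GW, N(0, 2.5²) coefficient
  priors on the standardised covariate, MAP fits with Laplace 95%
  intervals, and family selection by exact leave-one-out
  cross-validation (sum of held-out log predictive densities) with a
  parsimony margin.
* **Trajectories** — minimum-spanning-tree backbones over cluster
  centroids in 30-PC space, arc-length pseudotime τ, lineage-gene
  detection by natural-spline (df = 10) F-tests at FDR < 0.01 per
  lineage, Ward modules on 1 − correlation, vignette-split cluster-graph
  connectivity, and fate probabilities from an absorbing Markov chain
  with a pseudotime-directed kernel p(i→j) ∝ σ(Δτ/scale).
* **Spatial statistics** — co-occurrence profiles around a focal type,
  permutation neighbourhood-enrichment z-scores at radius 75, and
  deconvolution-weight colocalization with hierarchical ordering.
* **Signalling** — Hill interaction probabilities LR/(0.5 + LR) from
  trimmed-mean ligand/receptor expression, cell-label permutation
  significance (p < 0.01), spatially restricted early/mid/late vignette
  contrasts with a sample-permutation null and Holm control, and
  pathway information flow compared by exact paired signed-rank tests.
* **Benchmarking** — projection of a query (e.g. stem-cell-derived)
  dataset onto the reference PCA, joint clustering at resolution 2.25
  with a strict >100-query-cell filter, positioning by mean reference
  pseudotime, marker overlap coefficients |A∩B|/min(|A|,|B|), and
  Spearman staging on top-50 per-week genes.
* **A synthetic atlas generator** — seeded, with planted markers,
  composition trends, a branching pseudotime trajectory, maturation
  genes, spatial niches and vignette-switched ligand–receptor pairs, so
  every estimator above can be validated against known truth without
  downloading any data.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
synthetic atlas and write tables under `results/pipeline/`:

```bash
python analysis/01_simulate_atlas.py
python analysis/04_composition_trends.py
python analysis/07_signaling.py
```

`04_composition_trends.py` prints (abridged):

```
type             selected   configured  loo(const/lin/quad)
ciliated         quadratic  linear      -387.9/-61.1/-60.2
neuroendocrine   quadratic  quadratic   -118.4/-128.8/-58.4
progenitor       quadratic  linear      -374.6/-64.7/-63.4
stromal          linear     constant    -67.2/-66.6/-67.2
transitional     linear     constant    -60.5/-59.8/-60.3
```

Each row shows the LOO score of the three trend families and the
selected one. The neuroendocrine type, planted with a mid-gestation
peak, is decisively quadratic (ΔLOO ≈ 60 nats over linear). Types
configured "constant" are read as weakly linear because proportions are
renormalised across types — when progenitors decline, everyone else's
realised share drifts up — which is the correct reading of the realised
data, not a selection error.

`07_signaling.py` prints (abridged):

```
temporal calls (30 candidates tested):
 sender       receiver        pair    delta  adj_p_early  adj_p_late  early_up
stromal     progenitor FGF7->FGFR2 1.652940        0.006         1.0      True
stromal   transitional FGF7->FGFR2 1.707490        0.006         1.0      True
```

The planted early-gestation FGF7 ligand in stromal senders is called
early-up (Δ is the log interaction-intensity contrast of early versus
the best of mid/late; adjusted p from 20 000 sample permutations with
Holm control), and none of the flat decoy pairs is called in either
direction.

The same pipeline is available as a CLI (`lungdyn all --demo -o out/`)
or stage by stage (`lungdyn simulate|qc|markers|... -c config.yaml`).

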