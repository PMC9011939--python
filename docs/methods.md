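# Methods

## The multiview model

For a sample with `L` spatial units (cells or spots) and `k` markers,
polyview models each marker's expression vector `Y_i` as a late fusion of
view-specific machine-learning models:

    Y_i = a_I + a_0 F_0(Y~) + sum_v a_v F_v(G_v(X, Y~, T))

where `Y~` is the expression of all markers except the target, `X` the
coordinate matrix, and `T` optional annotations (cell types). `F_0` is
the **intraview** model — target expression as a function of the other
markers in the same unit — and each `G_v` derives a spatially
contextualized feature matrix:

* **juxtaview** — per-marker sums over a unit's direct neighbors in a
  cell graph (2D Delaunay triangulation pruned at a cutoff length; the
  cutoff is a quantile either of all pairwise distances, default q=0.25,
  or of first-neighbor edge lengths, q=0.75, pooled over the cohort);
* **paraview** — distance-weighted sums over all other units, with weight
  family `gaussian exp(-d^2/l^2)`, `exponential exp(-d/l)`,
  `linear max(1-d/l, 0)` or `constant 1(d<=l)`, an outer scale `l` (the
  radius of significance) and an inner zone of indifference `z` below
  which units contribute nothing. Setting `z` to the juxta cutoff makes
  the two spatial views carry disjoint information.

Design choices worth stating explicitly:

* The paraview always excludes the unit's own row (d = 0), even at
  `z = 0`; the unit's own expression belongs to the intraview.
* Expression-derived views drop the target marker's own column at
  modeling time (the `Y~` convention). Neighbor-*count* views (cell-type
  workflow) keep every column — counting a unit's own type among its
  neighbors is precisely how self-preference is detected.
* The linear weight family is clamped at zero; negative weights are
  meaningless for aggregation.
* Degenerate triangulation input (under 3 points, collinear points)
  falls back to a plain distance-threshold graph with a warning.

## Two-step training

Each view model is a bagged forest of 100 full, unpruned regression
trees with `round(sqrt(m))` candidate features per split, grown on
bootstrap bags. The fusion coefficients are then estimated by ridge
regression of the target on the views' **out-of-bag** predictions (a
unit's prediction uses only trees whose bag excluded it), with the
penalty chosen by leave-one-out generalized cross-validation over 50
log-spaced values in [1e-6, 1e3] on standardized predictions. With 100
trees, a unit is in every bag with probability ~1e-40; if it happens the
full-ensemble mean is substituted and logged.

Performance is the cross-validated fraction of variance explained
(10-fold by default, folds assigned by a seeded shuffle and reduced to
`L` when `L` is small; within each fold the penalty is re-selected and
the baseline is the training-fold mean). `multi_r2` uses all views,
`intra_r2` a meta-model restricted to the intraview prediction, and the
**gain** is their difference in percentage points. Held-out variance
explained may be negative and is reported unclipped. Per-view p-values
come from a two-sided t-test on an unpenalized least-squares refit,
because penalized coefficients have no finite-sample t distribution.
Contributions are the ridge coefficients clamped at zero and normalized
to sum to one over the views (the intercept is excluded); when every
coefficient is non-positive the contributions fall back to uniform, and
a constant target yields an all-zero degenerate result rather than an
error so cohort runs survive dead markers.

When a workflow bypasses the intraview (identity and marker workflows on
the structural tissues), the intraview model is skipped, `intra_r2 := 0`,
and the baseline is an intercept-only model.

The paraview scale `l` is chosen per marker by maximizing the gain over
a grid (IMC-like default {25, 50, 100, 200, 400}; spot-resolution
default {2, 5, 10}), ties broken toward smaller `l` to prefer local
explanations.

## Importances, weighting and aggregation

Raw importances are total impurity (variance) reductions per feature
summed over the trees of a view's forest. Per target and view they are
standardized over predictors — centered by the mean and divided by the
sample standard deviation (`(2,4,6) -> (-1,0,1)`); a configuration
switch `eq3_denominator="var"` divides by the variance instead — and
multiplied by `(1 - p)` of the view's fusion coefficient, so views that
contribute nothing to the meta-model are silenced. Constant or
single-entry importance vectors map to zeros.

Weighted importances are averaged element-wise across samples (weight
per sample first, then average; the reverse order is a different
operation and a regression test pins the implemented one). Entries a
predictor never competes for (a target's own intraview column) are NaN
and are averaged over the samples where they exist; cutoff-based
operations treat NaN and negative values as "not important".

Cohort summaries: the **R² signature** of a sample concatenates
(intra R², multi R², gain) over markers whose *cohort-mean* gain reaches
the threshold (default 2 percentage points; cohort-level filtering keeps
every sample's vector the same length — 26 unfiltered markers give 78
entries, 9 retained give 27); the **importance signature** concatenates
weighted importances over (retained targets × all predictors × views)
(26 markers and 3 views give 2028 entries, 9 retained targets 702), with
undefined cells contributing 0. Interaction counting applies
`importance >= cutoff` (default 0.5, boundary included); view and group
contrasts are set differences of the important-pair sets. Communities
are extracted by Louvain modularity maximization (seeded, default 42) on
`A + A^T` with negative weights clamped and zero-degree nodes dropped.

The coordinate-permutation null re-runs the identical pipeline on
replicates whose position rows are shuffled within each sample
(expression untouched, so per-marker marginals are exactly preserved);
original-versus-permuted gains and contributions are compared by
one-sided Wilcoxon rank-sum tests.

Per-(sample, target, view) forest seeds are derived from the master seed
and the names involved by CRC-32 hashing, so cohort results are
bit-reproducible and independent of execution order.

## Structural tissue generator

Positions are a jittered grid (spacing 1, jitter ±0.25) with `L` sites
drawn without replacement; four cell types start balanced and random.
For the `self` and `mutual` patterns, labels are refined by seeded
greedy label swaps on the Delaunay graph: a swap is accepted if it
increases the count of focal neighbor pairs (ct1–ct1, or ct1–ct3) and
does not decrease a compound objective that penalizes non-focal
same-type adjacency — the penalty vetoes gains that would crowd the
bystander types together, keeping them near their null adjacency rates.
Refinement stops when the focal pair count reaches `strength` times its
expectation under random labels (default strength 2.0), so the planted
enrichment — the very quantity the juxtaview must detect — is
controlled directly. In the mutual pattern the enrichment is carved
mostly out of the focal types' self-adjacency, which drops below null;
that is the intended signature of a mutual (rather than self)
preference.

Expression is multivariate normal per cell type with diagonal
covariance and common spread 1.0. Of 100 markers, 75 are informative:
per marker, the four type means sit on a ladder with rung size drawn
uniformly from [4, 8] spread units (random type order and sign), so any
two types are at least 4 standard deviations apart and a midway
threshold classifies two types with accuracy ≥ Φ(2) ≈ 0.977.
Uninformative markers share one mean across types.

What this generator does *not* emulate: spatial expression gradients
within a type, cell-size or segmentation artifacts, marker count noise,
and any intercellular regulation beyond type co-location. Passing the
structural benchmarks therefore shows that neighborhood composition is
recovered when it is the only signal, not that real IMC noise is
handled.

The two validation workflows both bypass the intraview and use a
deliberately loose juxta cutoff (75th percentile of first-neighbor
distances, emulating threshold mis-estimation on real data): the
identity workflow models one-hot cell types from neighbor type counts;
the marker workflow models gene expression from summed neighbor
expression, with each type represented by its top-10 markers ranked by
the absolute difference between within-type and outside-type means.

## Mechanistic simulator

A cellular-automata reaction-diffusion model on a square grid (default
100×100; the shipped benchmark uses 50×50), sites empty or occupied by
one of four cell types (default occupancy 50%), with 29 species: 5
diffusing ligands, 5 receptors, 19 intracellular proteins. Cell growth,
division, motility and death are neglected. Each species field obeys

    dc_s/dt = d_s * Lap(c_s) + P_s - gamma_s * c_s

integrated by explicit finite differences (5-point Laplacian, grid step
h = 1, zero-flux boundaries, dt = 0.2 against the stability bound
dt <= h²/(4 d)). Only ligands diffuse (d = 1). All production is linear:
ligand production `alpha * producer activity` in producing cell types,
receptor activation `beta * local ligand concentration` in expressing
types, protein activation `beta * upstream activity`. Ligands are
specific (Li activates only Ri).

The wiring gives each receptor one cascade of depth 3 shared by every
type expressing it, so a node means the same thing wherever it is
active; the cascade's deeper tiers secrete the matching ligand (an
autocrine/paracrine relay — X14 produces L1), and each tier also mixes
in a basal input from one of four reserved root nodes, staggered per
cell type. The roots have no upstream edges; they decay slowly
(gamma 0.05 versus 0.5 for other proteins), so their randomized initial
per-cell activity is the persistent heterogeneity the whole tissue rides
on, and the finite horizon (T = 25) leaves the system in a transient
regime. Rates were chosen to put the inference problem in the
interesting regime: the ligand decay length sqrt(d/gamma_L) ≈ 3 grid
units sits inside the paraview radius of 10; small ligand production
(alpha = 0.002) keeps receptor activity a minor component of first-tier
cascade nodes, whose root-driven part is amplified (mix_boost = 4), so
reconstructing a receptor from its own cell's downstream nodes is an
ill-conditioned subtraction while the neighborhood's secreted-ligand
proxies remain informative — receptors are where the tissue view should
help, and in the shipped benchmark they are. Per-edge interaction
strengths vary deterministically in [0.6, 1.5] (keyed by edge identity)
so multi-parent nodes are distinct mixtures.

Measurements are the 24 non-ligand species at occupied sites (ligands
are excluded as hard to assay), with a detection floor of 1e-4:
concentrations below it — in practice only the exponentially decayed
initial values of species a cell type's wiring never touches — read as
exactly zero. Without the floor those round-off-scale residues behave as
pure-noise targets, and a linear meta-model can convert the systematic
anti-correlation of out-of-bag predictions on unpredictable targets into
spurious cross-validated R²; the floor turns them into constant targets
handled by the degenerate path.

Ground truth: intracellular truth per cell type is its direct wiring
edges among measured species; intercellular truth links each ligand's
producer nodes (pooled over all types — any neighbor may secrete) to the
receptor it activates, for receptors the type expresses. Matrices are
compared on their undirected projection sgn(A + Aᵀ) over the
24·23 = 552 ordered off-diagonal pairs; per type this yields 34 ordered
intracellular and 12 ordered intercellular true pairs. AUROC is the
tie-aware rank (Mann-Whitney) statistic and AUPRC the step-wise area
under precision-recall, both via scikit-learn, with absent importances
scored 0.

## Problem sizes and numerical choices

The shipped validation suite uses: structural recovery at L = 2000,
100 markers, 5 seeds; the mechanistic benchmark on a 50×50 grid with
2 samples (intra + gaussian paraview at l = 10); and the permutation
null on one 30×30 mechanistic sample with 10 coordinate permutations
(views intra + juxta at the neighbor-quantile cutoff + paraview with the
zone set to that cutoff). `scripts/acceptance.py` re-runs the same
designs with one structural seed. Paraview weights below 1e-12 are
truncated to exactly zero; results are serialized with 12 significant
digits so a write/read round trip is the identity at that precision.

## Known limitations

* Importance-based relations are not causal and not directional;
  indirect and confounded paths produce false positives, most visibly
  among intercellular pairs (few true positives among 552 candidates).
* The linear meta-model can exploit anti-correlated view predictions on
  near-noise targets (see the detection floor above); targets with tiny
  gains should not be over-read.
* The choice between standard-deviation and variance denominators in
  importance weighting changes the scale that the 0.5 interaction cutoff
  is applied to; the default (sd) makes weighted importances comparable
  across samples, and the variance form is available for comparison.
* Only 2D geometries are supported; 3D triangulation is out of scope.
* The mechanistic simulator is deterministic given its seed and uses
  linear (non-saturating) kinetics; it probes network recovery, not
  stochastic reaction noise.
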