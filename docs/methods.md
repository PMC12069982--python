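# Methods

This note records the modelling assumptions, numerical choices and known
limitations behind each stage of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Label model

Six mutually exclusive classes are derived from three growth-standard
z-scores: severe wasting (z_WFH < −3), wasting (z_WFH < −2), underweight
(z_WFA < −2), stunting (z_HFA < −2), overweight (z_WFH > +2) and a
residual `adequate` class. Two choices are deliberate:

* **WHO convention for wasting.** Wasting is defined as z_WFH below −2.
  Descriptions of wasting as a band "within ±2 SD" describe the *normal*
  range; the deficit convention is the one consistent with the severe
  wasting and stunting definitions and is used throughout.
* **Severity-first priority.** A child can satisfy several conditions at
  once (e.g. wasted *and* stunted). Classes are made exclusive by the
  fixed order severe_wasting > wasting > underweight > stunting >
  overweight, most severe first. The `adequate` class exists because the
  five malnutrition classes are not exhaustive for healthy children; a
  five-class mode is available by passing a mixture without `adequate`.

## Synthetic data

The **child cohort generator** samples a label from a configurable
mixture (default uniform over the six classes), then draws the three
z-scores from class-conditional Gaussians truncated to the label's own
region (e.g. severe wasting: z_WFH ~ N(−3.6, σ) truncated below −3, with
σ = `noise_sd`, default 0.3 — wide enough that neighbouring classes
nearly touch at their shared thresholds, the realistic hard case, without
overlapping). Height and weight are back-computed from z_HFA / z_WFA
against an internal growth-reference table (quadratic, monotone in age,
sex-offset); it is a plausible stand-in curve, *not* the WHO reference,
and only its monotonicity matters downstream. MUAC tracks z_WFH around
13.5 cm. Age, sex, residence and income are independent covariates.

What this emulates: the schema and label logic of UNICEF-style child
anthropometry. What it does not: real marginal distributions, missing
data, measurement error correlated with covariates, or realistic
label-covariate confounding. Passing recovery tests therefore shows the
algorithms work when the generative assumptions hold, not that the
pipeline's headline numbers transfer to field data.

The **prevalence-table generator** draws countries from `n_clusters`
Gaussian blobs in the 6-D (income, wasting, severe wasting, overweight,
stunting, underweight) space. Blob centres are rejection-sampled at
least `separation` within-blob SDs apart (per-column SDs: 0.03 income,
1.5 percentage points otherwise), kept 4 SD inside the physical bounds,
with the severe-wasting centre forced well below the wasting centre;
row-level severe ≤ wasting is enforced by a final clip. The true blob id
is retained for recovery tests.

## Fire Hawk Optimizer

Free parameters the source description leaves open were fixed as follows
and are configurable:

* **Hawk count**: s = clamp(round(|g|·n·cap), 1, n/2), g ~ N(0,1).
  The cap defaults to 0.05: pre-build calibration on the 5-D sphere
  benchmark showed that a small elite (1–3 hawks for n = 50) exploits
  the global best far more effectively than mid-range caps, which stall
  around 10⁻³; with cap 0.05 the median-of-10-seeds final fitness is
  below 10⁻⁵ at 300 iterations.
* **Territories**: hawks claim, in ascending fitness order, their
  ⌈q/s⌉ nearest unclaimed prey (Euclidean); ties break to the lower prey
  index.
* **Prey rule choice**: each prey takes the within-territory move or the
  outside move on a fair coin, with fresh uniform coefficients each time.
* **Safe places**: the within-territory safe place is the mean of that
  territory's prey (owner hawk position if the territory is empty); the
  global safe place is the mean over all prey (archived best if none).
* **Acceptance**: new positions replace old unconditionally; elitism
  lives only in the archived global best, which makes the history
  monotone by construction.
* **Bounds**: hard clamping; degenerate (zero-width) boxes are rejected.

All randomness flows from a single `numpy` Generator seeded by the
config, so runs are bit-reproducible.

## FHO-k-means

A candidate is the flattened K×d centroid matrix; the fitness is the
WCSS after nearest-centroid assignment. Empty clusters are repaired
before every fitness evaluation by moving the empty centroid onto the
point farthest from its assigned centroid (this strictly lowers WCSS).
The hybrid finishes by refining the best centroid set with classical
Lloyd iterations (assignment / mean update) to a 10⁻¹⁰ movement
tolerance — the metaheuristic handles basin selection, the local
iterations the final polish, which is also how the hybrid is described:
centres are updated and points reassigned to the nearest cluster until
convergence.

**Cluster-number selection** scores each K by the mean silhouette of the
fitted model, ties to the smallest K. Raw WCSS is monotone decreasing in
K and cannot produce an interior optimum, so it cannot serve as a
K-selection score; the silhouette is the stand-in used for the "fitness
vs K" curve. Undefined silhouettes (single cluster, singleton clusters,
zero spread) score 0. Silhouette computation is O(n²) and intended for
country-scale tables (hundreds of rows), not large cohorts.

## EGBF

* **Multi-class handling**: softmax cross-entropy with one tree per class
  per round; p = π − onehot, q = π(1−π) floored at 10⁻¹⁶. The base score
  is the log class prior, so a 0-round model predicts the priors.
* **Leaf weight / structure score**: the default pair u* = −P/(Q+β) and
  −½ΣP²/(Q+β) + αH is the internally consistent second-order derivation
  (α the per-leaf penalty from the regularizer Ω = αH + ½βu²).
  `leaf_denominator="as_printed"` switches to u* = −P/(2Q+β), a variant
  kept for fidelity experiments; it is inconsistent with the structure
  score and slightly under-shoots each leaf, acting like an extra
  shrinkage.
* **Fuzzification**: per feature, triangular low/(min,min,median),
  medium/(min,median,max), high/(median,max,max) terms — a partition of
  unity on [min,max]. Features with two distinct values fall back to a
  two-term ramp; constant features get one always-on term and produce no
  splits; a median equal to an extremum is nudged to the range midpoint.
* **Split candidates**: the crisp threshold of a term is its
  0.5-membership crossing — (min+median)/2 for low, (median+max)/2 for
  high. Medium has two crossings; the falling one is used, which
  coincides with high's threshold, so each feature contributes two
  distinct thresholds. Trees route crisply at predict time; memberships
  enter only the split scoring.
* **Fuzzy gain**: per feature, the entropy drop of the class-mass
  partition induced by its membership functions (masses are summed
  membership degrees; the partition of unity makes them additive, so the
  three branch masses reconstruct the node's crisp class counts). All
  term-candidates of one feature share the feature's fuzzy gain and
  differ in structural gain. `entropy_sign="as_printed"` flips the
  entropy sign (which ranks splits backwards and is kept only for
  fidelity experiments).
* **Candidate ranking**: within a node, structural gains and fuzzy gains
  are min-max rescaled to [0,1] over the *valid* candidates (raw
  structural gain > 0, both children's Σq ≥ `min_child_hessian`,
  default 10⁻³) and combined as (1−λ)·ĝ + λ·M̂ with λ = 0.5 by default.
  Rescaling is monotone, so λ = 0 reproduces the exhaustive
  maximum-structural-gain split exactly — the anchor the oracle tests
  check. Ties take the first candidate in (feature, term) order.
* **Defaults**: 100 rounds, learning rate 0.3, depth 3, β = 1, α = 0.
  Rounds and rate are not fixed by the source description; these are
  ordinary boosting defaults at this data scale.

Known limitation: thresholds are anchored at *global* training
min/median/max, giving at most two cut points per feature. Classes
separated at other quantiles (wasting vs severe wasting at z_WFH = −3)
are resolved only through depth and feature combinations, which caps
their one-vs-rest sensitivity below that of the other classes. This is
inherent to the fuzzified split design, not a tuning artefact.

## Evaluation

One-vs-rest counts per class; "overall" metrics are unweighted macro
means (the aggregation is otherwise undefined for these metrics).
F1 uses the standard 2PR/(P+R). MSE is computed between predicted
probability vectors and one-hot truth, averaged over samples *and*
classes, the only well-defined reading for categorical outcomes.
Zero-denominator metrics return 0 with a `RuntimeWarning`.

## Pipeline

Stage order: simulate/load → min-max normalize (fit on the full table
before clustering, matching the workflow being reproduced) → FHO-k-means
→ append the cluster id as a one-hot feature block (the mechanism by
which clustering "structures" the classifier's input) → stratified split
(default 30% test; 20% also supported since both appear in the source
workflow) → EGBF → metrics. Stage seeds are SHA-256 hashes of
`"<global_seed>:<stage_name>"` truncated to 31 bits, so adding a stage
never perturbs earlier ones and any stage can be replayed in isolation.

## Problem sizes

The test suite and acceptance script use cohorts of 400–2000 children,
prevalence tables of 152–400 countries, FHO populations of 15–50 with
15–300 iterations, and 4–100 boosting rounds — the scale of the study
design being emulated (152 countries; K sweep 2–8 peaking at 4) and
comfortably convergent for these algorithms.
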