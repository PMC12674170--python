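# Methods

## Edge vectors

A subject's connectome is the matrix of pairwise Pearson correlations
between ROI-averaged BOLD time series, Fisher-transformed
(`z = atanh r`) and averaged element-wise across runs on the z scale.
Inputs are assumed already preprocessed (registration, denoising,
band-pass filtering and nuisance regression are upstream and out of
scope). The strictly-lower triangle is unrolled **row-major over node
pairs (i, j), i > j, 0-based** — `numpy.tril_indices(R, -1)` order — a
convention fixed here and shared by every module, since nothing
downstream depends on the particular ordering so long as it is uniform.
The diagonal is stored as 0 and never consumed. Correlations of exactly
±1 are clamped to ±(1 − 1e-12) before `atanh` (warning); a zero-variance
ROI is an error naming the node. Averaging accepts 1–4 runs (warning
below the standard 4) so toy data work.

## Behavioural leg

Raw G-scores are residualised on an intercept, age and a binary gender
indicator by OLS; a single-level gender column is dropped with a warning
rather than making the design singular. Derivation of G itself from task
batteries (factor modelling) is out of scope: `g_raw` is an input.

Twin-pair correlations are Pearson correlations across pairs between
member-1 and member-2 adjusted scores. Because member order within a
pair is arbitrary, a **double-entry** variant — the correlation over the
doubled pairing {(a,b), (b,a)}, invariant to order — is provided and
used by the pipeline. Falconer's h² = 2(r_MZ − r_DZ) is reported
unclipped, with a warning outside [0, 1].

## Cross-twin prediction engine

Each bootstrap iteration splits every pair by a fair coin (one member
trains, the co-twin tests; never both in one group — asserted
structurally every iteration). Within an iteration **both fold
directions** are fitted and the iteration's r is their mean, matching
the reading of the two-fold leave-one-group-out scheme; each direction's
selected edge set is kept for the consensus stage.

* **Screening.** Per edge, the univariate F statistic
  `F = r²(n−2)/(1−r²)` on (1, n−2) df, keep `p < 0.05`. Computed from
  the correlation directly with r² clipped below 1 − 1e-14, because the
  textbook sum-of-squares route suffers catastrophic cancellation at
  |r| → 1 (a perfectly collinear column must yield a huge F, not a
  negative one). Constant edges get F = 0 and are never selected.
  Screening is recomputed inside every bootstrap iteration and every
  permutation — never on the full cohort — to avoid leakage.
* **PLSR.** scikit-learn's `PLSRegression` (NIPALS, standardised X and
  y). The component count is chosen on the training group by inner
  k-fold CV (5 folds by default) maximising the mean Pearson r between
  held-out predictions and observations; ties go to the fewest
  components. PLS1 components are nested, so the grid is evaluated by
  fitting once per inner fold at the grid maximum and truncating the
  rotation/loading matrices — verified exactly equal to separate fits
  per component count. The grid upper bound (default 100) is clipped to
  what the fold sizes and feature count support, with a warning. An
  empty selection degenerates to predicting the training mean, which
  scores r = 0 by convention (warning).
* **Permutation null.** Training G-scores are shuffled and the *entire*
  pipeline (screening + grid search + fit) is rerun, `perms_per_model`
  times per iteration, pooling B × perms draws. Shuffling only the
  predicted–observed pairing would inherit the real model's feature
  selection and produce an optimistic null. The reported
  `p = (1 + #{null ≥ observed}) / (1 + N)` (add-one convention).
* **Reproducibility.** Iteration `it` draws from its own
  `default_rng([seed, it])` stream, so results are bit-identical for a
  given seed and independent of execution order.

One caveat documented deliberately: the observed statistic is the mean
of B per-iteration r's while the null draws are single-model values, so
for B > 1 the test is conservative under the null (the observed mean
concentrates while null draws spread). The calibration tests therefore
run at B = 1, where observed and null are exchangeable and the p-value
is exactly uniform under the null.

## Consensus, strengths, networks

An edge counts toward one iteration's consensus only if selected in
**both** fold directions; edges in strictly more than `fraction · B`
models (default 0.5 — a count of exactly 500/1000 is excluded, reading
"more than 50%" literally) form the consensus set. Node connectivity
strength is the count (or absolute-weight sum) of retained edges
incident to a node; top-k tables break ties by ascending node id for
determinism. Network tallies are upper-triangular 10 × 10 tables in
canonical network order and conserve the retained-edge total.

## Fingerprinting

For each individual, Pearson correlations between (optionally masked)
edge vectors against every other individual of the same zygosity cohort;
the argmax is the predicted co-twin, ties resolving to the lowest
subject id, zero-variance candidates excluded with a warning. Both
members of every pair attempt identification and each attempt counts
once. Accuracy is 100 × correct/attempted; chance is 100/(n−1) for a
pool of n individuals.

## Difference models

Per pair, the scalar |G_a − G_b| and the per-edge vector |x_a − x_b|
(the per-edge reading of the "absolute numerical difference" of the
vectorized profiles — the differences are needed edge-wise as
features). Ten-fold CV by default: edges ranked by the training-fold F
statistic, top 400 retained (the cap is inactive when a network has
fewer intra-network edges), PLSR as above, and **pooled out-of-fold
predictions** correlated with the observed differences — one r per
cohort, matching how a single correlation per analysis is reported;
per-fold means would be the alternative reading. Permutations shuffle
the differences and refit everything on the same folds. Network-specific
models restrict the feature columns to one network's intra-network edge
indices.

## Statistics for two independent correlations

Fisher z test with standard error `sqrt(1/(n1−3) + 1/(n2−3))`, Cohen's
q = atanh r₁ − atanh r₂, Zou's (2007) interval built from the two
back-transformed per-correlation intervals, and normal-approximation
power Φ(z_eff − z_{α/2}) + Φ(−z_eff − z_{α/2}). **Sample sizes are
always explicit arguments**: correlations computed across individuals
take per-individual counts (e.g. 178 vs 100), correlations computed
across pairs (difference models) take per-pair counts (e.g. 89 vs 50).
Both conventions reproduce the corresponding published worked values,
which is how the convention per analysis was pinned down.

## Synthetic twin cohorts

Generated at the edge level (the pipeline consumes edge vectors, and
edge-level generation makes the within-pair correlation exact): pair
latent `g_p ~ N(0, I)`, member `x_i = sqrt(ρ) g_p + sqrt(1−ρ) e_i`, so
each edge has unit variance and within-pair correlation ρ; G-score
`G_i = β Σ_j w_j x_ij + s_p + σ ε_i` with k causal edges, fixed
equal-magnitude unit-norm weights, pair-shared environment
`s_p ~ N(0, c)` and individual noise. Model-implied co-twin G
correlation: `(β²ρ + c)/(β² + σ² + c)`; Var(G) = β² + σ² + c. Twins
share age (uniform 22–36) and gender (same-sex pairs); optional small
age/gender effects on raw G default to zero.

Default condition (frozen before the acceptance properties were run, and
not revisited): 89 MZ-like/50 DZ-like pairs, ρ_MZ = 0.8, ρ_DZ = 0.2,
β = 0.4, k = 40, c = 0.3, σ = 0.735 (Var G ≈ 1). β anchors the ideal
connectome-to-G correlation at 0.4, the magnitude of reported
FC–intelligence associations, and spreading it over 40 edges puts
single-edge correlations in the realistic 0.05–0.15 band — weak enough
that honest out-of-sample learning from ~80 training subjects is
marginal, so the cross-twin r is driven mainly by profile similarity
(rising with ρ), which is the regime the study design probes. c supplies
pair-shared G variance not mediated by the modelled edges.

Two modelled consequences worth knowing:

* With c > 0, a cohort with β = 0 is *not* a null for cross-twin
  prediction: an overfit model memorises the training twins' G via their
  edge profiles, and co-twins resemble both — a family-resemblance
  channel that produces genuine positive prediction. Null-calibration
  tests therefore set β = 0 **and** c = 0.
* Difference models see more signal at low ρ (larger within-pair
  differences against fixed individual noise), so the planted-network
  recovery condition uses ρ = 0.2, all k = 6 causal edges concentrated
  in the DMN of a balanced 10 × 4-node atlas, β = 1.2, σ = 0.1,
  150 pairs.

What the generator does **not** emulate: a population-common FC
component (real connectomes are all grossly similar, which is why real
whole-brain fingerprinting is far from the ceiling our independent-edge
model hits at high ρ), spatial autocorrelation between edges,
haemodynamics or motion artefacts, and distributional asymmetries of
real Fisher-z values. Passing tests therefore demonstrate the
correctness and calibration of the *machinery*, not effect sizes to be
expected on real cohorts. A time-series emitter (`emit_time_series`,
Gaussian draws from a PSD-repaired target correlation matrix) exists
only to exercise the matrix-construction I/O path.

## Problem sizes and numerical choices

Desk-scale runs used throughout the tests and examples — 40-node
parcellations (780 edges), 30–150 pairs, 25–50 bootstrap iterations,
component grids up to 20 with 3–5 inner folds — were chosen so each
property check completes in seconds to a few minutes while keeping every
statistic in its asymptotically meaningful regime; full-scale settings
(268 nodes, B = 1000, 100 permutations per model, grid to 100) are the
defaults of the public functions. Tolerances in Monte-Carlo assertions
are 3–4 standard errors of the quantity under test. Degenerate inputs
are conventions, not crashes: constant predictions score r = 0, constant
edges get F = 0, empty selections fall back to the training mean.

## Known limitations

Alternative learners (SVM, trees, logistic) are accommodated only
through the pluggable-regressor hook, not implemented. The two-sample
t-test across bootstrap distributions reported in this literature
compares resampled, non-independent values; it is deliberately omitted
as inferentially misleading — the independent-correlation comparison
(Fisher z, Zou CI) is the supported route. Voxel-level processing,
atlas construction and factor modelling of G are out of scope.
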