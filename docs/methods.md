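# Methods

`trajdiff` compares single-cell differentiation trajectories across
experimental conditions.  This note records the statistical model, the
numerical choices, and the places where the design was genuinely open,
together with what the bundled simulator does and does not emulate.

## Data model

The input is a gene-by-cell count matrix **Y** (J × n), a condition label
c(i) ∈ {1, …, C} per cell, cluster labels, and a reduced-dimensional
embedding **X** (n × d, typically PCA or UMAP computed upstream).  A
trajectory for condition c is a tree 𝒯_c over cell states; its root-to-leaf
paths are the L lineages.  Each cell carries a pseudotime vector
**T**_i ~ G_c(i) (one entry per lineage, arc-length units of the embedding)
and a lineage-weight vector **W**_i ~ H_c(i) with ‖**W**_i‖₁ = 1.  The three
trajectory-level questions — common topology? equal progression? equal fate
selection? — are hypotheses about 𝒯_c, G_c and H_c respectively; gene-level
differences are modelled with condition-specific smoothers (below).

## Skeleton trajectories and projection

Trajectories are fitted TSCAN-style: cluster centroids in the embedding are
joined by a Euclidean minimum spanning tree (Kruskal; equal-length edges
broken by lexicographic node order), rooted at a user-chosen cluster.
Principal curves are deliberately not fitted — the permutation topology test
requires refitting hundreds of trajectories on a *fixed* skeleton, and the
centroid-polyline variant is deterministic and cheap.  Externally computed
pseudotime/weight matrices can be supplied to every downstream test, so any
trajectory-inference method can drive steps 2–3.

Cells are projected orthogonally onto each lineage's centroid polyline;
pseudotime is the root-to-projection arc length.  Projections clamp to
segment ends except at the far end of the terminal segment, which is treated
as a ray.  This mirrors the curve extension used by principal-curve methods
and matters statistically: without it, all cells beyond the last centroid
collapse onto a single condition-specific atom at the lineage's total arc
length, and the permutation null of the topology test (a per-cell *average*
over refits) smears that atom, producing ~90% false rejections on null data.
With the extension the test is calibrated.  Consequently pseudotime is
bounded by the data's projected extent rather than by the centroid
polyline's length; cells on the polyline still recover their exact arc
length.

Distances d_il from cell i to lineage l become weights via a Gaussian kernel
w_il ∝ exp(−d_il²/σ²), rows normalised to sum to 1, with σ the median over
cells of the nearest-lineage distance (recorded in the fit).  Cells on a
shared prefix are equidistant to the lineages sharing it and get equal
weights; cells committed to one branch are near one-hot — reproducing the
characteristic weight histogram with peaks at 0, ½ and 1.  The kernel form
and bandwidth are this package's choice; the field's tools only specify that
weights derive from distance and are normalised to sum to 1.

Per-condition trajectories recompute centroids from one condition's cells
while keeping the tree structure, so lineages stay mapped across conditions
by construction.  A condition with an empty skeleton cluster is an error
(remove the cluster or the condition); during permutation refits only, an
empty pseudo-condition cluster silently falls back to the all-cell centroid
so the null computation cannot abort.

## Distribution tests

**Weighted Kolmogorov–Smirnov.**  With observation weights in [0, 1], the
ECDFs are weight-normalised, D = sup|F̂₁ − F̂₂| is evaluated at the pooled
jump points, and the rejection region at level α is
√(−½·log(α/2)·(n′+m′)/(n′m′)) with Kish effective sizes n′ = (Σw)²/Σw².
An effect-size threshold t replaces D by D′ = max(D − t, 0); the p-value is
the asymptotic Kolmogorov tail of D′·√(n′m′/(n′+m′)), which is consistent
with the rejection region (both reduce to the classic test at unit weights).

**Classifier test.**  Groups are downsampled to the smallest group size, a
test split (30% per class by default) is held out, hyper-parameters are
tuned by 5-fold CV on the learning split (k-NN grid {5, 11, 21}; the random
forest uses a fixed 500 trees, so its grid has size one and CV is skipped),
and the number of correct test-set assignments is referred to
Binom(n_test, 1/C).  The thresholded null E[Acc] ≤ n_test/C + t is
discretised as floor(t·n_test) extra allowed successes, keeping the binomial
computation exact.  All splits are seeded; a seed reproduces Acc bit-exactly.

**Kernel two-sample test.**  Unbiased MMD² with an RBF kernel at the median
pairwise-distance bandwidth; permutation p-value with a fixed seed.  Note the
unbiased estimator is ≤ 0 for identical samples.

**Combination and multiplicity.**  Per-lineage p-values are combined with a
weighted Stouffer Z: z_l = Φ⁻¹(1 − p_l), Z = ΣW_l z_l / √(ΣW_l²), with
lineage weights W_l = Σ_i W_i[l]; p-values are clipped to
[1e−300, 1 − 1e−16] before transformation.  One-sided upper-tail evidence is
combined one-sidedly.  Across genes, Benjamini–Hochberg adjustment is used.
A combination formula circulating in the field sums the *p-values* rather
than their normal quantiles inside the Z statistic; that quantity can exceed
1 and is not a probability, so the standard z-score form is implemented here.

## Imbalance score

For each cell, the condition labels of its k nearest neighbours (self
excluded, distance ties broken by index) are compared with the global
proportions p via the multinomial likelihood-ratio statistic
G = 2Σ_c n_c log(n_c/(k·p_c)) (zero-count terms contribute 0), transformed to
z = (G − (C−1))/√(2(C−1)) by moment matching the χ²_{C−1} null.  The raw
scores are smoothed by an additive penalised regression with s cubic
B-spline basis functions per embedding dimension.  Defaults k = s = 10.  The
choice of the likelihood-ratio G (over, say, Pearson's X² or an exact
multinomial tail) is this package's; the score is an exploratory diagnostic
and no p-values are attached to it.

## The three trajectory-level tests

**Topology.**  Condition labels are permuted r times (default 100); each
time, per-pseudo-condition trajectories are refitted on the fixed skeleton
and every cell's pseudotime vector is recorded.  The observed pseudotimes are
compared against the per-cell average of the permuted refits (the pooled
r×n variant is also implemented; the average is the default).  The
comparison uses the weighted KS test when L = 1, the kernel test when C = 2
and L > 1, and the classifier test otherwise.  In our simulations the
classifier comparison has markedly better power than the kernel test against
geometric branch displacements — the observed-vs-averaged difference is a
local mass redistribution that a median-bandwidth RBF kernel essentially
cannot see — so `method="classifier"` is recommended whenever a topology
effect is plausible; the kernel default is retained for the C = 2, L > 1
case for continuity with common practice.

**Progression.**  Per lineage l, pseudotimes T[·, l] are compared between
conditions by weighted KS with weights W[·, l] (classifier test on the
univariate pseudotimes when C > 2, since the weighted KS is two-sample
only).  The global test is the weighted Stouffer combination (default), or a
classifier/MMD test on the full n×L pseudotime matrix.  A lineage with zero
total weight in some condition gets p = 1 with a warning and weight 0 in the
combination, mirroring workflows where a lineage exists in one condition
only.  With L = 1 the global test reduces exactly to the single lineage's
weighted KS p-value.

**Fate selection.**  Requires L ≥ 2.  The classifier test (random forest
default) is applied to the weight matrix grouped by condition, globally or
per lineage pair; cells with zero weight on both lineages of a pair are
retained, since non-membership is informative.

A caution on interpretation: a branch-probability shift necessarily changes
the *weighted* pseudotime mixture of the affected lineages (relatively more
or less post-branch mass), so the per-lineage progression test will often
also react to a pure fate effect in the depleted/enriched lineages.  The
reverse separation is clean: an effect confined past the last branch point
moves progression without touching fate proportions, and the simulator's
`tip_progression_shift` knob reproduces exactly that.

Default effect-size thresholds are t = 0 for all three tests; thresholding
is opt-in via configuration.

## Gene-level model

Expression of gene j in cell i follows Y_ji ~ NB(μ_ji, φ_j) with

log μ_ji = Σ_l Σ_c s_jlc(T_li) · Z_ilc + U_i α_j + log N_i,

where Z_i is a one-hot lineage assignment drawn from the multinomial with
proportions **W**_i (or argmax, both seeded), U an optional covariate matrix
with gene-specific coefficients α_j, and N_i the sequencing depth.  Each
smoother s_jlc(t) = Σ_k b_k(t) β_jlck uses K cubic B-spline basis functions
(default K = 6; K = 1 denotes the constant basis, and K ∈ {2, 3} is rejected
since a cubic basis needs at least 4 functions).  Knots sit at quantiles of
the pooled assigned pseudotimes and are *shared* across every (lineage,
condition) block — this is what makes coefficients comparable across blocks
and the condition contrasts meaningful.  Blocks with no assigned cells (a
lineage absent from a condition) are dropped and recorded.

Fitting is IRLS for β given φ alternating with maximum-likelihood updates of
the per-gene dispersion φ_j (profiled over log φ ∈ [log 1e−4, log 1e8]),
initialised at the method-of-moments value; convergence is a relative
deviance change below 1e−8 within 100 iterations.  A ridge of 1e−6 on the
smoother coefficients stabilises near-singular designs; the coefficient
covariance is the penalized-information sandwich A⁻¹(XᵀWX)A⁻¹ with
A = XᵀWX + P.  The linear predictor is clipped to ±30, which also tames
all-zero genes (flagged low-information and excluded from testing, as are
non-convergent fits, each with a reason column).  Dispersion is per-gene with
no shrinkage.

The condition test contrasts, per mapped lineage (present in ≥ 2 condition
blocks), the K coefficients of each condition against the first condition's;
the Wald statistic uses a pseudoinverse with relative tolerance 1e−10 and
degrees of freedom equal to the rank of the contrast covariance, referred to
χ²_df.  With a log₂ fold-change threshold, the fitted condition difference
is evaluated in log space at K representative pseudotime points (quantiles of
the fitting data) and the contrast row for point k is zeroed when the fitted
|log₂ difference| falls below the threshold — a gene whose entire fitted
difference is sub-threshold gets statistic 0 and p = 1.  The evaluation-point
zeroing rule is this package's documented choice.  Gene filtering before
fitting defaults to "≥ 10 cells with count ≥ 2", recorded in the run
metadata.

## Simulator

The generator emulates the *outcomes* of a branching differentiation process
rather than any gene-regulatory dynamics: cells advance along a 2-D tree
("linear" or "binary" built-in geometries), choose branches with
per-condition probabilities, and express genes with smooth NB log-mean
curves (intercept + slope + sinusoid + branch effect) around a per-cell
depth factor.  Condition effects are injected at the level the tests
consume: `progression_shift` warps the U(0, 1) progress variable
(t = u^{1/(1+shift)}), `tip_progression_shift` warps only the stretch past
the last branch point, `branch_probs` changes fate proportions, a
`topology_offset` displaces a condition's branch geometry, and a knock-out
multiplier m scales affected genes in the perturbed condition (m = 1: no
effect).  Clusters bin each tree segment in two so the cluster MST recovers
the generating topology.  Defaults — two conditions, two lineages, 1000
cells per condition, 200 genes, dispersion φ = 2, embedding noise 0.15,
depth ~ lognormal(σ = 0.3) around 2000 — are the package's standing study
conditions for calibration and power analysis.  The simulator reports true
depths as library sizes and exposes the generating log-mean curves for
recovery checks.

What the simulator does *not* emulate: gene-regulatory network dynamics,
transcriptional bursting, doublets and ambient contamination, batch effects,
or realistic UMAP geometry.  Passing calibration/power checks therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not performance guarantees on any particular real dataset.

A noise-injection protocol perturbs hard lineage assignments (a fraction
p ∈ [0, 0.5] of cells redrawn uniformly, so with L lineages a selected cell
actually changes with probability (L−1)/L) and multiplies pseudotimes by
independent Normal(1, sd) draws floored at zero, for robustness studies.
Benchmark metrics (TNR, TPR, PPV, NPV, F1) are computed from rejection
decisions against ground-truth effect flags; zero-denominator metrics are
reported as undefined, not zero.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the workflow at sizes chosen
to make the statistical assertions sharp while staying minutes-scale on one
core: classifier calibration/power at n = 300 per group over 200/100
replicates; topology calibration on single-lineage data with n = 1000 and
r = 50 over 100 replicates; progression/fate scenarios at the simulator
default n = 1000 per condition over 50 replicates; NB-GAM FDR with 500 null
and 100 affected genes (2-fold effect) at n = 2000 over 10 replicates; noise
robustness with p = 0.3, sd = 2 over 20 replicates.

## Known limitations

- Only tree topologies; no cycles, no automatic root detection, no automatic
  mapping between structurally different per-condition trajectories.
- The topology permutation test inherits the dependence caveats of comparing
  pseudotimes estimated on overlapping cell sets; its p-values are best read
  as diagnostics, and the kernel-test default is low-powered against
  geometry-only effects (use the classifier comparison).
- The weighted KS effective-size correction treats weights as fixed, not
  estimated; per-lineage p-values entering Stouffer are not independent.
- Per-gene dispersion is unshrunken, so very low-count genes carry noisy φ̂.
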