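# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, in the order the pipeline runs them.

## Prey-trait clustering

Prey items are points in {0,1}^T trait space; the Euclidean distance between
two items is √(number of differing traits), bounded by √T. Clustering is
Ward's minimum-variance agglomeration, implemented directly through the
Lance–Williams recurrence with coefficients
α_i = (n_i + n_k)/(n_i + n_j + n_k), β = −n_k/(n_i + n_j + n_k), γ = 0.

**Dialects.** Two incompatible conventions both circulate under the name
"Ward". In the `d2` dialect (default) the recurrence runs on squared
distances and merge heights are reported on the original distance scale;
this matches `scipy.cluster.hierarchy.linkage(..., "ward")` and R's
`hclust(..., "ward.D2")`. In the `d` dialect the recurrence runs on the
distances as given (R's historical `ward.D`). Both are supported because
published analyses rarely say which was used; on the packaged sculpin table
the two dialects produce different six-group partitions, which is exactly
why the choice must be explicit.

**Tie-break.** Binary trait data generate many exactly equal merge costs, and
library implementations break such ties by row order, so results silently
depend on input ordering. Here ties are broken by name: among tied pairs,
the pair whose lexicographically smallest member sorts first merges first.
Clustering output is therefore invariant (up to labels) under row
permutation, and the `d2` dialect is verified against scipy on tie-free
(continuous) data.

**Number of categories.** The WGSS curve is computed in the original trait
space — WGSS(k) = Σ_clusters Σ_members ‖x − centroid‖² over the partitions
read off the dendrogram — not from linkage heights, because "within-groups
sum of squares" is a trait-space quantity. The elbow is the point of maximum
perpendicular distance to the chord joining (1, WGSS(1)) and
(k_max, WGSS(k_max)), with k_max defaulting to min(n−1, 15). The rule is
parameter-free and reproducible, but any automatic elbow is a convention:
the selected k depends on k_max because the chord's slope does, and a
smooth, nearly exponential WGSS decay (as in the packaged sculpin table,
where the rule picks k = 4) simply has no sharp kink. The full curve is
always returned and `cut_to_categories` accepts any k, so a caller can
impose a substantively motivated number of groups — the packaged analyses
use k = 6 for comparability with the published grouping of these data.
A flat curve (all items identical) returns k = 1 with a degeneracy flag.

**Known limitation.** Cutting the packaged 29 × 25 sculpin trait table at
k = 6 reproduces three of the six published prey categories exactly
(benthic arthropods, pelagic arthropods, stationary benthic items — 16 of
29 items); under every supported dialect (and several alternative metrics
tried during development) Octopus and Gastropoda join the
tentacles-and-appendages group rather than the published squishy-swimmers
and vermes groups. Any one of several single-cell edits to the printed
table restores the published partition exactly, so the printed table and
the published dendrogram are almost certainly not the same matrix; the
package ships the table verbatim and does not recode it.

## Diet profiles and classification

Per-(species, study) records hold prey-item importances in [0, 1]; a study
total may fall short of 1 (unclassified remainder) but not exceed it beyond
1e−6. Studies partitioned by region or season are separate study ids
averaged uniformly. Descriptive accounts without quantities get equal
importance 1/m over their m items. Per-item means divide by the number of
studies for the species (an item absent from a study counts 0 there).
Records carry an optional life-stage tag; analysis prefers adults and falls
back to whatever a species has.

Category importance is the sum of member-item importances (conservation:
category totals equal item totals, tolerance 1e−9 on exact inputs). The
primary diet is the argmax category. Exact ties are real in rounded
published tables, so the tie rule is explicit: the default prefers the
category with the smaller dataset-wide total importance (the rarer niche),
which reproduces both tied assignments in the packaged sculpin table;
first-listed and error-on-tie variants are selectable. The coarse label
applies the strict > 50 % rule through a user-editable prey-item → prey-type
mapping and falls back to "omnivore".

Concentration summaries count species whose best category exceeds a
threshold (strict >), and within a focal category count members above
secondary thresholds — strict for the first (0.70), inclusive at printed
precision for the second (0.90), matching how such tables are summarized.

## Functional jaw characters

All seven characters are ratios of same-specimen lengths, hence exactly
invariant to uniform scaling. Mechanical advantage follows the standard
lower-jaw lever convention in-lever/out-lever (the quotient direction is a
convention, stated here because published character names rarely fix it).
The occlusal-offset and symphyseal-height normalizers are not canonical;
defaults are the posterior out-lever (which shares the jaw-joint landmark)
and dentary length (jaw-local size), both configurable. Tooth aspect ratio
is height/width of a representative tooth supplied as direct measurements;
no landmark protocol for tooth choice is imposed. Standardization is
(x − mean)/sd with the n−1 denominator; zero-variance columns are a named
error. Normality checks are visual: quantile–quantile pairs are returned
for plotting with no decision rule.

## Phylogenetic comparative analyses

**PCA.** Eigen-decomposition of the sample covariance of the z-scored table
via SVD; axis signs are fixed so each axis's largest-magnitude loading is
positive, making outputs byte-stable across BLAS builds. Broken-stick
retention keeps leading axes whose variance fraction exceeds
b_j = (1/p) Σ_{i=j}^p 1/i, stopping at the first failure.

**Phylomorphospace.** Ancestral node scores per retained axis are BM
maximum-likelihood estimates, computed by solving the weighted
squared-change-parsimony linear system (edge weights 1/branch-length) with
tips fixed; for a Gaussian model the joint optimum equals the marginal
means. Verified against the closed-form GLS conditional mean on small
trees at 1e−10.

**Phylogenetic MANOVA.** Observed Wilks Λ = det(W)/det(W+B) from the
ordinary scatter decomposition. The null holds the group labels fixed and
simulates trait evolution: multivariate BM on the tree with rate matrix
estimated from the data via standardized independent contrasts (raw
covariance selectable for sensitivity), uniform root. The p-value uses the
+1 correction, so p ∈ [1/(nsim+1), 1]. Since Λ is invariant to nonsingular
linear transforms of the characters, on a star tree the simulated null
reduces to the classical Wilks distribution regardless of the estimated
rate matrix; the test suite confirms a type-I error within [0.02, 0.10] at
α = 0.05 over 200 null replicates at the study's dimensions (n = 54, p = 7,
six groups, nsim = 500). More characters than residual degrees of freedom
is a named error, not a silent pseudo-inverse.

**Mk1 ancestral states.** Single-rate symmetric Markov model; q is
parameterized as each off-diagonal rate, giving the closed-form transition
matrix P_same(t) = 1/k + (1 − 1/k)e^{−kqt} (verified against the matrix
exponential). The rate is fitted by bounded one-dimensional maximization of
the pruning-algorithm log-likelihood on log₁₀ q, bracketed around 1/total
tree length (1e−4 to 1e4 times it). Marginal reconstructions use the
up–down algorithm with a uniform root prior; for this reversible model that
equals re-rooting at every node, and the log-likelihood is re-rooting
invariant (tested at 1e−8). The transition summary lists edges whose
most-probable state differs between parent and child, with both marginal
vectors attached — an expected-change summary, not a stochastic mapping.

**Discriminant re-classification.** LDA with shared within-class covariance
(pooled divisor n−g), priors proportional to class sizes by default
(uniform or explicit selectable), posteriors by the Gaussian discriminant
rule, and a ridge λ = 1e−8·trace/p added only if the pooled covariance is
numerically singular. Resubstitution accuracy is reported with the
confusion matrix and the mismatch list; resubstitution flatters accuracy
relative to cross-validation, which is why re-classification accuracy is
treated as a property of the data rather than a target.

**Label reconciliation.** Tree tips absent from the trait table are pruned
and table species absent from the tree dropped, each with a logged warning,
never silently.

## Synthetic data

The generators target the statistical structure the analyses assume, not
any empirical measurement distribution. Defaults mirror the real study's
dimensions: 54 species; 7 characters; 6 prey categories in blocks of 5
items × 4 characteristic traits; flip noise p = 0.01; diet Dirichlet tilted
to put mean weight 0.8 on a focal category with concentration 10 (strong
single-category dominance, as in the real table where 48/54 species exceed
0.5); birth rate 1, death rate 0. Birth–death trees are conditioned on the
tip count by retrying (cap 1000) rather than GSA sampling — a mild,
documented bias acceptable for test data. All generators are
bit-reproducible under (seed, config); pipelines spawn fixed offsets from
one run seed.

Because the generators produce exactly block-structured traits and exactly
Dirichlet diets, passing recovery tests demonstrates that the pipeline's
inference is self-consistent at realistic noise, not that real prey tables
satisfy the block model — real trait tables are far less separable, as the
packaged sculpin table shows.

## Numerical conventions

Distances, WGSS and characters are exact floating-point computations with
no tolerance knobs. Merge-cost ties use a 1e−12 absolute band. The MANOVA
null adds 1e−12 jitter to the tree covariance and a relative 1e−12 ridge to
the rate matrix before Cholesky, guarding ultrametric degeneracies. JSON
reports are written with sorted keys so identical runs are byte-identical.
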