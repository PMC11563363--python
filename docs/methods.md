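# Methods

## Domain model

The unit of analysis is the clinic visit. Each visit records the six CDR
component scores (memory, orientation, judgment & problem solving,
community affairs, home & hobbies, personal care) and the global CDR
stage, all on the ordinal scale {0, 0.5, 1, 2, 3}, plus a brief cognitive
battery (Boston Naming 0–15, MMSE 0–30, Short Blessed 0–28, Word List
Memory 0–20, Verbal Fluency ≥ 0; ranges are configuration defaults used
only for validation and synthesis). Visit order within a patient stands in
for calendar time when dates have been stripped from an extract: rows are
taken as pre-sorted by visit date, and `visit_index` is assigned by file
order. Missing cells are encoded as empty strings and never coerced to 0.

Global CDR aggregation implements the published Washington University
scoring rules: memory is the primary category; the rating equals the
memory score when at least three secondary domains agree with it; a
majority of at least three secondaries on one side of memory (with at most
one on the other) imposes its most frequent value, ties resolved toward
the memory score; 3–2 splits and two-per-side configurations fall back to
the memory score. Boundary rules: memory 0 yields global 0 unless two or
more secondaries are impaired (then 0.5); memory 0.5 yields 0.5 unless
three or more secondaries reach 1 (then 1); with memory ≥ 1 the rating can
never be 0 — three or more unimpaired secondaries pull it to 0.5, and a
formally computed majority of 0 is clamped to 0.5. The function is total
and exhaustively tested over all 5⁶ component combinations. Input files
that already carry a recorded global CDR are taken at face value; the rule
function serves synthesis and optional consistency checks.

## Preprocessing

Per feature, pooled over all visits of all patients: clip to the 5th/95th
percentiles (linear-interpolation percentiles between order statistics),
impute missing cells with the median of the clipped non-missing values,
then min-max scale to [0, 1] on the post-clip range. The order
clip → impute → scale, with the median computed after clipping, guarantees
imputed values stay inside the scaled range. Zero-range (constant)
features scale to 0 rather than NaN. The ordinal CDR components pass
through the same pipeline for uniformity; clipping is a no-op on them in
practice. Fitted parameters are stored per feature on the original scale
and serialize to JSON so a transform can be re-applied bit-identically.

## Clustering

Distances default to Euclidean on the preprocessed [0, 1] features
(configurable: manhattan, cosine). Silhouette widths follow the standard
definition with two conventions: singleton clusters score 0, and points
coincident with both their own and the nearest other cluster (a = b = 0)
score 0.

The refinement loop computes the full silhouette vector, stops if the
minimum is non-negative (termination `no_negative_at_start` when no move
was ever made, else `all_nonnegative`), otherwise moves the
lowest-silhouette point (ties: lowest row index) to the cluster attaining
its b(i) (ties: lowest cluster id). Additional stops: an exact repeat of
the silhouette vector within the last `cycle_window` iterations (default
10) and a cap of `max_iterations` reassignments (default 100). A cluster
emptied by a move is retired and K shrinks; in practice this cannot be
triggered by the loop itself, because the moved point always has a
negative silhouette and singletons score 0. Per-cluster distance sums are
maintained incrementally (a rank-1 update per move), so one iteration
costs O(nK) after an O(n²K) setup.

A deliberate consequence of the stopping rule: the loop optimizes the
*minimum* silhouette, not the mean. Removing the last negative silhouette
can end at a slightly lower MSW than the initialization, and cycle
termination returns the current state, not the best state seen. The
package treats MSW improvement as an empirical tendency (it holds in the
median across instances; see the property tests), not an invariant.

Initializations: agglomerative clustering of the distance matrix (scipy
linkage, Ward default, complete/average/single available) cut at K, or
uniform random labels resampled until all K clusters are occupied. The
random-restart variant runs `random_restarts` (default 100) refinements
with seeds spawned from a master seed and keeps the highest-MSW result.

Baselines behind the same contract: K-means (scikit-learn, on the feature
matrix, its natural input), DBSCAN (scikit-learn, on the distance matrix,
defaults eps 0.25 on the [0, 1] scale and min_samples 5 — necessarily
arbitrary since density parameters have no K), and PAM. No maintained
k-medoids implementation is available in the dependency stack, so PAM is
implemented here directly: deterministic greedy BUILD seeding followed by
best-single-swap passes until no medoid/non-medoid exchange lowers the
total distance-to-medoid cost; tests check it against exhaustive medoid
enumeration on small instances. DBSCAN noise points are treated as
singleton clusters (silhouette 0), and runs yielding fewer than two core
clusters are flagged invalid for MSW comparison. Every method's solution
carries silhouettes computed from the shared distance matrix, so MSW is
comparable across methods.

## Model selection and embeddings

`sweep_k` runs one method over a contiguous K range (default 2–16),
tabulates MSW, termination and final cluster count per K, and marks local
maxima. `chosen_k` is deliberately a reported configuration decision
(default: the MSW argmax only when no choice is supplied), because
cluster-count choice in practice weighs interpretability alongside MSW.

`pca_variance` reports eigenvalues of the sample covariance as proportions
of total variance, on preprocessed features by default with a raw-input
flag, since scaling changes the answer and both views are informative when
comparing feature sets. Embeddings are evaluation-only exports: seeded
Barnes–Hut t-SNE (perplexity 30, clamped below n/3 on small inputs) and
classical Torgerson MDS. Classical MDS was chosen over iterative stress
majorization because it is deterministic and exactly reproduces Euclidean
configurations, which makes it testable in closed form; coordinate signs
are fixed by making each axis's largest-magnitude loading positive.

## Subtype profiles and transitions

Profiles are computed at two levels: visit-level for stage composition and
component distributions, baseline-visit-level (each patient's first visit)
for demographics and cognitive summaries. Clusters are reported in
severity order — ascending mean member global CDR — which is invariant to
label permutation. A subtype is "homogeneous" when its member visits share
one global CDR level.

The transition graph has one edge occurrence per consecutive visit pair of
each patient, self-transitions included; single-visit patients contribute
nothing, and total edge weight always equals Σ(visits−1) over patients.
Progression is operationalized as an increase in the *recorded global CDR*
between consecutive visits (stable = equal, regression = decrease);
cluster-dominant stages are ambiguous for composite clusters, so the
visit-level stage is primary, with coarse stage groups (≤0.5, 1, >1) also
reported. A progressor is a multi-visit patient with at least one
progression transition; the fraction is over multi-visit patients and is
null for cohorts without any. Regressions are reported, never filtered.
Interval comparisons between transition groups use the two-sided Wilcoxon
rank-sum test (exact when both groups have ≤25 tie-free values, normal
approximation with tie correction otherwise) alongside the group medians,
the conventional companion to a median-based comparison; absent visit
dates produce an explicit "intervals unavailable" result.

## Synthetic cohorts

The generator draws, per patient: a visit count, a latent subtype chain
(initial state from the mixing proportions, subsequent states from a
row-stochastic Markov matrix), and positive truncated-normal inter-visit
intervals (mean 8.8, sd 3.6 months — the target clinic's reported interval
distribution). Per visit: each CDR component is drawn from the subtype's
level distribution — a truncated normal on the level-index scale 0–4
discretized at half-integer boundaries, centered on the subtype's target
level with spread `sd` — the global CDR is then aggregated from the drawn
components (so recorded stage and components are rule-consistent by
construction), cognitive scores follow linear severity trends with
integer-rounded Gaussian noise clipped to each test's range (MMSE, Boston
Naming, Word List Memory and Verbal Fluency decrease with severity, Short
Blessed increases), and missingness is applied independently per cell
(defaults: 1% components, 4% cognitive, matching the <5% regime the
pipeline is designed for). Everything is driven by one seeded generator,
so cohorts are bit-identical given a seed.

Two presets ship as YAML. `paper_like` has 10 subtypes whose target
profiles echo the qualitative structure reported for the clinic cohort —
a healthy cluster; memory-only versus memory-plus-functional very-mild
clusters; mild clusters differing in judgment/community/home impairment
and self-care; moderate-to-severe clusters differing mainly in personal
care — with mixing proportions matching the reported per-cluster patient
counts and a progression-biased Markov matrix (self 0.40, forward 0.53
split 0.30/0.35/0.35 over the next three severity ranks, backward 0.07),
chosen so the share of multi-visit patients with a stage progression comes
out near the reported 39%; because severity-adjacent subtypes often share
a stage and the most severe subtype cannot progress, the realized share
saturates around 34–37%. The visit-count distribution reproduces the
~52% single-visit share with a maximum of 5 visits; the reported cohort
shape implies multi-visit patients average exactly 2.0 visits, which is
unattainable with support {2..5} and any mass above 2, so the preset puts
95% of multi-visit mass at 2 visits and generates ~3% more visits than
the clinic total. `toy` has 3 well-separated subtypes (near-point-mass
component distributions) for fast exact-recovery tests.

What the generator does *not* emulate: informative missingness, ordinal
measurement error correlated across components, site or drift effects,
real demographic covariate structure (demographic columns are optional
inputs, not synthesized), and any quantitative fit to the real extract's
joint distribution. Tests passing on synthetic cohorts therefore establish
correctness of the pipeline's computations and its behavior under the
stated cohort shape — not that the clinic's reported cluster statistics
are reproduced, which requires the original extract.

## Numerical and design choices

- Distance metric, linkage and DBSCAN parameters are unstated degrees of
  freedom of the original analysis; defaults (Euclidean, Ward, eps 0.25 /
  min_samples 5) are recorded in every solution's method metadata.
- Tie-breaks everywhere favor the lowest index/id, for determinism.
- Silhouette denominators of 0 (coincident points) score 0.
- K-means runs on features, PAM on distances — each method's natural
  input; silhouettes always come from the shared distance matrix.
- CLI runs write to caller-named output directories rather than
  timestamped ones, so a replay with the same config and input is
  byte-identical; manifests carry seeds and library versions.
- Problem sizes in the test-suite properties (e.g. 200 oracle instances at
  n ≤ 50, 100 blob instances at n = 200, Markov recovery at 2,000
  multi-visit patients) were chosen as the smallest scales at which the
  statistical assertions have comfortable margins.

## Known limitations

- The refinement loop inherits the heuristic's limitations: no MSW
  monotonicity, possible cycling (handled by detection), and sensitivity
  to initialization.
- PAM is exact only in the sense of local swap-optimality; global
  optimality is verified only on tiny instances.
- The progression analysis is descriptive; no trajectory model (e.g. HMM)
  or confounder adjustment is attempted.
- Chi-square goodness-of-fit checks on generated component distributions
  pool sparse cells and tolerate the nominal false-positive rate.
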