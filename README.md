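# cdrsubtypes

Data-driven subtyping of longitudinal memory-clinic cohorts from Clinical
Dementia Rating (CDR) profiles.

Patients evaluated for memory concerns are heterogeneous: people at the
same overall dementia stage can differ widely in which cognitive and
functional domains are impaired and in how fast they decline. This package
implements a visit-level subtyping pipeline for such cohorts: every clinic
visit carries the six CDR component ("box") scores — memory, orientation,
judgment & problem solving, community affairs, home & hobbies, personal
care, each on the ordinal scale {0, 0.5, 1, 2, 3} — and visits are
clustered into subtypes without using the temporal linkage between them.
Temporality returns afterwards: because every visit of every patient is
clustered, a patient occupies one subtype per visit and their consecutive
visits define transitions between subtypes, which the package summarizes
as a directed transition graph and progression statistics.

## Method

The core clusterer is **silhouette-refinement clustering** ("SillyPutty").
For a dissimilarity matrix *d* and a partition into clusters, each point
*i* has silhouette width

&nbsp;&nbsp;&nbsp;&nbsp;*s(i) = (b(i) − a(i)) / max(a(i), b(i))*,

where *a(i)* is the mean distance from *i* to the other members of its
cluster and *b(i)* the smallest mean distance from *i* to any other
cluster (singletons score 0 by convention). The refinement loop repeatedly
takes the point with the lowest silhouette width and reassigns it to the
cluster attaining *b(i)*, stopping when no silhouette is negative, when
the silhouette vector exactly repeats within a recent window, or at an
iteration cap. Initialized from an agglomerative (Ward) cut of the same
distance matrix this is *hierarchical SillyPutty*, the pipeline's default;
random-restart initialization, plain hierarchical clustering, PAM
(k-medoids), K-means and DBSCAN are available behind the same contract,
all scored by mean silhouette width (MSW) on one shared distance matrix.
The number of clusters K is chosen by sweeping K (default 2–16) over MSW.

Around the clusterer the package provides: validated visit-table I/O with
the published CDR component-to-global scoring rules; deterministic
preprocessing (clip to the 5th/95th percentiles, median imputation,
min-max scaling to [0, 1]); PCA variance profiles and t-SNE/classical-MDS
exports for feature-set comparison; subtype profiles (stage composition,
component distributions, baseline demographics); transition graphs with
progression/stable/regression classification by global-CDR change and
rank-sum comparison of inter-visit intervals; and a fully seeded synthetic
cohort generator (latent subtypes with discretized-normal component
distributions, progression-biased Markov transitions, truncated-normal
visit intervals, severity-linked cognitive scores, low missingness) so the
entire pipeline is testable with known ground truth.

## Worked example

```python
import cdrsubtypes as cs

spec = cs.load_preset("paper_like")            # 10-subtype synthetic preset
cohort, truth = cs.generate_cohort(spec, seed=1)
print(cs.cohort_summary(cohort))               # 1,845 patients / 2,818 visits

features = cs.preprocess(cohort, "cdr_components")
sol = cs.run_method(features, "hierarchical_sillyputty", k=10, seed=1)
graph = cs.build_transition_graph(cohort, sol)
stats = cs.progression_stats(graph, cohort)
```

Output of this run:

```
patients=1845 visits=2818 single=933 multi=912 interval=8.9+/-3.5 months
MSW=0.47783 clusters=10 termination=max_iterations
hierarchical alone: MSW=0.45823
progressors=312/912 (34% of multi-visit patients)
least severe subtype: cluster 10, stages [0.0, 0.5], 759 visits
```

Reading: the generated cohort matches the target clinic shape (about half
single-visit patients, ~9-month visit intervals); refining the Ward cut
lifts the mean silhouette width from 0.458 to 0.478 at K=10; about a third
of multi-visit patients progress to a more severe global CDR stage across
at least one consecutive-visit transition; and the least severe subtype
mixes stages 0 and 0.5 (a "composite" subtype).

The same stages are available as a CLI over run-configuration files:

```bash
cdrsubtypes simulate --preset toy --seed 5 --out runs/sim
cdrsubtypes cluster  --config config.yaml --out runs/cluster
cdrsubtypes sweep    --config config.yaml --out runs/sweep
cdrsubtypes transitions --config config.yaml --labels runs/cluster/labels.csv --out runs/trans
```

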