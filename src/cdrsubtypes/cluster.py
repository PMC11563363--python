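"""Silhouette-refinement clustering and baseline methods.

The core heuristic ("SillyPutty") maximizes the mean silhouette width (MSW)
by iteratively taking the point with the lowest silhouette width s(i) =
(b(i) - a(i)) / max(a(i), b(i)) and reassigning it to its nearest other
cluster (the cluster attaining b(i)). The loop stops when no silhouette is
negative, on an iteration cap, or when the silhouette-width vector exactly
repeats within a recent window (cycle detection).

All methods — SillyPutty with hierarchical or random initialization,
plain agglomerative clustering, PAM (k-medoids, build+swap), Lloyd
K-means and DBSCAN — return the same :class:`ClusterSolution` contract
with silhouettes computed from one shared distance matrix, so their MSW
values are directly comparable.

Conventions: singleton clusters get s(i) = 0; ties in the reassignment
pick the lowest row index and lowest cluster id; an emptied cluster id is
retired (K shrinks).
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN, KMeans

from .preprocess import FeatureMatrix

KNOWN_METHODS = (
    "hierarchical_sillyputty",
    "random_sillyputty",
    "hierarchical",
    "pam",
    "kmeans",
    "dbscan",
)

LINKAGES = ("ward", "complete", "average", "single")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("distance matrix must be square")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_distances(features, metric: str = "euclidean") -> DistanceMatrix:
    """Exact pairwise distances between rows under the named metric."""
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    try:
        condensed = pdist(x, metric=metric)
    except ValueError as exc:
        raise ValueError(f"unknown metric {metric!r}") from exc
    return DistanceMatrix(squareform(condensed), metric=metric)


@dataclass
class SillyPuttyConfig:
    """Stopping rules and restart budget for the refinement loop."""

    max_iterations: int = 100
    cycle_window: int = 10
    random_restarts: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.cycle_window < 1:
            raise ValueError("cycle_window must be >= 1")
        if self.random_restarts < 1:
            raise ValueError("random_restarts must be >= 1")


@dataclass
class ClusterSolution:
    """Labels, per-row silhouettes and MSW under one method run.

    ``termination`` is one of ``all_nonnegative``, ``max_iterations``,
    ``cycle_detected``, ``no_negative_at_start`` for SillyPutty runs and
    ``not_applicable`` for one-shot baselines.
    """

    labels: np.ndarray
    silhouette: np.ndarray
    msw: float
    method: dict = field(default_factory=dict)
    n_iterations: int = 0
    termination: str = "not_applicable"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.silhouette = np.asarray(self.silhouette, dtype=float)
        if len(self.labels) != len(self.silhouette):
            raise ValueError("labels and silhouette vector differ in length")
        if len(self.silhouette) and (
            self.silhouette.min() < -1 - 1e-12 or self.silhouette.max() > 1 + 1e-12
        ):
            raise ValueError("silhouette values outside [-1, 1]")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def to_frame(self, row_keys=None) -> pd.DataFrame:
        df = pd.DataFrame({"label": self.labels, "silhouette": self.silhouette})
        if row_keys is not None:
            df.insert(0, "patient_id", [k[0] for k in row_keys])
            df.insert(1, "visit_index", [k[1] for k in row_keys])
        return df

    def manifest(self) -> dict:
        return {
            "method": self.method,
            "msw": None if np.isnan(self.msw) else float(self.msw),
            "n_clusters": int(self.n_clusters),
            "n_iterations": int(self.n_iterations),
            "termination": self.termination,
        }


def write_solution(solution: ClusterSolution, csv_path, manifest_path=None, row_keys=None):
    """Serialize labels+silhouettes as CSV and the run manifest as JSON."""
    solution.to_frame(row_keys).to_csv(csv_path, index=False)
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump(solution.manifest(), fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Silhouette widths
# ---------------------------------------------------------------------------

def _cluster_sums(d: np.ndarray, labels: np.ndarray):
    """Per-point sums of distances to each cluster, plus cluster sizes.

    Returns (ids, counts, sums, own) where ``sums[i, j]`` is the total
    distance from point i to members of cluster ids[j] and ``own[i]`` is
    the column of point i's cluster.
    """
    ids, own = np.unique(labels, return_inverse=True)
    onehot = np.zeros((len(labels), len(ids)))
    onehot[np.arange(len(labels)), own] = 1.0
    counts = onehot.sum(axis=0)
    sums = d @ onehot
    return ids, counts, sums, own


def _silhouette_from_sums(counts, sums, own):
    n, k = sums.shape
    rows = np.arange(n)
    own_counts = counts[own]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[rows, own] / (own_counts - 1)
    means = sums / counts
    means[rows, own] = np.inf
    b = means.min(axis=1)
    nearest = means.argmin(axis=1)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (b - a) / denom
    s = np.where(denom == 0, 0.0, s)   # coincident points: a = b = 0
    s = np.where(own_counts == 1, 0.0, s)  # singleton convention
    return s, b, nearest


def silhouette_widths(d: DistanceMatrix | np.ndarray, labels) -> np.ndarray:
    """Per-row silhouette widths s(i) = (b - a) / max(a, b).

    a(i) is the mean distance to the other members of i's cluster and b(i)
    the smallest mean distance to any other cluster; singletons score 0.
    """
    dm = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, float)
    labels = np.asarray(labels)
    if len(labels) != dm.shape[0]:
        raise ValueError("labels length does not match distance matrix")
    ids, counts, sums, own = _cluster_sums(dm, labels)
    if len(ids) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    s, _, _ = _silhouette_from_sums(counts, sums, own)
    return s


def mean_silhouette(silhouette) -> float:
    """Arithmetic mean of a silhouette-width vector (the MSW)."""
    s = np.asarray(silhouette, dtype=float)
    if s.size == 0:
        raise ValueError("empty silhouette vector")
    return float(s.mean())


# ---------------------------------------------------------------------------
# SillyPutty refinement
# ---------------------------------------------------------------------------

def sillyputty_refine(
    d: DistanceMatrix | np.ndarray,
    initial_labels,
    config: SillyPuttyConfig | None = None,
) -> ClusterSolution:
    """Refine an initial partition by lowest-silhouette reassignment.

    Each iteration moves the strictly lowest-silhouette point (ties: lowest
    row index) to the cluster attaining its b(i) (ties: lowest cluster id).
    Stops when all silhouettes are non-negative, when the silhouette vector
    exactly matches one of the last ``cycle_window`` vectors, or at
    ``max_iterations`` reassignments.
    """
    config = config or SillyPuttyConfig()
    dm = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, float)
    labels = np.asarray(initial_labels).copy()
    ids, counts, sums, own = _cluster_sums(dm, labels)
    if len(ids) < 2:
        raise ValueError("initial labels must reference >= 2 clusters")
    ids = list(ids)
    history: deque = deque(maxlen=config.cycle_window)
    n_iter = 0
    while True:
        s, b, nearest = _silhouette_from_sums(counts, sums, own)
        if s.min() >= 0:
            termination = "no_negative_at_start" if n_iter == 0 else "all_nonnegative"
            break
        if any(np.array_equal(s, h) for h in history):
            termination = "cycle_detected"
            break
        if n_iter >= config.max_iterations:
            termination = "max_iterations"
            break
        history.append(s.copy())
        i = int(np.argmin(s))
        target = int(nearest[i])
        source = own[i]
        # incremental update of per-cluster distance sums (rank-1 move)
        sums[:, source] -= dm[:, i]
        sums[:, target] += dm[:, i]
        counts[source] -= 1
        counts[target] += 1
        own[i] = target
        if counts[source] == 0:
            # retire the emptied cluster id; K shrinks
            keep = np.ones(len(ids), dtype=bool)
            keep[source] = False
            sums = sums[:, keep]
            counts = counts[keep]
            del ids[source]
            own = own - (own > source).astype(own.dtype)
            history.clear()
        n_iter += 1
    final_labels = np.asarray(ids)[own]
    return ClusterSolution(
        labels=final_labels,
        silhouette=s,
        msw=mean_silhouette(s),
        method={
            "name": "sillyputty_refine",
            "max_iterations": config.max_iterations,
            "cycle_window": config.cycle_window,
        },
        n_iterations=n_iter,
        termination=termination,
    )


# ---------------------------------------------------------------------------
# Initializations
# ---------------------------------------------------------------------------

def hierarchical_init(d: DistanceMatrix | np.ndarray, k: int, linkage: str = "ward") -> np.ndarray:
    """Agglomerative clustering of a distance matrix cut at k clusters."""
    dm = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, float)
    n = dm.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; known: {LINKAGES}")
    z = scipy_linkage(squareform(dm, checks=False), method=linkage)
    return fcluster(z, t=k, criterion="maxclust")


def random_init(n: int, k: int, seed) -> np.ndarray:
    """Uniform random labels 1..k with every cluster occupied."""
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    rng = np.random.default_rng(seed)
    while True:
        labels = rng.integers(1, k + 1, size=n)
        if len(np.unique(labels)) == k:
            return labels


# ---------------------------------------------------------------------------
# PAM (k-medoids, build + swap)
# ---------------------------------------------------------------------------

def pam(d: DistanceMatrix | np.ndarray, k: int, max_swaps: int = 200) -> np.ndarray:
    """Partitioning Around Medoids on a dissimilarity matrix.

    Classic deterministic BUILD (greedy seeding) followed by SWAP passes
    that apply the best medoid/non-medoid exchange until no exchange lowers
    the total within-cluster distance-to-medoid cost.
    """
    dm = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, float)
    n = dm.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    medoids = [int(np.argmin(dm.sum(axis=0)))]
    nearest_d = dm[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest_d[:, None] - dm, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        new = int(np.argmax(gains))
        medoids.append(new)
        nearest_d = np.minimum(nearest_d, dm[:, new])
    medoids = np.array(sorted(medoids))
    for _ in range(max_swaps):
        dmed = dm[:, medoids]                      # n x k
        order = np.argsort(dmed, axis=1)
        d1 = dmed[np.arange(n), order[:, 0]]       # nearest medoid distance
        n1 = order[:, 0]                           # nearest medoid column
        d2 = dmed[np.arange(n), order[:, 1]]       # second-nearest distance
        best_delta, best_swap = 0.0, None
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        for j in range(len(medoids)):
            in_j = n1 == j
            # removing medoid j: its members fall back to d2 or the candidate
            delta = (
                np.minimum(dm[in_j], d2[in_j, None]).sum(axis=0)
                - d1[in_j].sum()
                + np.minimum(dm[~in_j] - d1[~in_j, None], 0.0).sum(axis=0)
            )
            delta[is_medoid] = np.inf
            o = int(np.argmin(delta))
            if delta[o] < best_delta - 1e-12:
                best_delta, best_swap = float(delta[o]), (j, o)
        if best_swap is None:
            break
        j, o = best_swap
        medoids[j] = o
        medoids = np.sort(medoids)
    assignment = np.argmin(dm[:, medoids], axis=1)
    return assignment + 1


# ---------------------------------------------------------------------------
# Uniform method dispatch
# ---------------------------------------------------------------------------

def _solution_from_labels(dm, labels, method_meta) -> ClusterSolution:
    s = silhouette_widths(dm, labels)
    return ClusterSolution(
        labels=np.asarray(labels),
        silhouette=s,
        msw=mean_silhouette(s),
        method=method_meta,
        n_iterations=0,
        termination="not_applicable",
    )


def run_method(
    features: FeatureMatrix | np.ndarray,
    method: str,
    k: int | None = None,
    *,
    metric: str = "euclidean",
    linkage: str = "ward",
    config: SillyPuttyConfig | None = None,
    seed: int = 0,
    dbscan_eps: float = 0.25,
    dbscan_min_samples: int = 5,
    distance: DistanceMatrix | None = None,
) -> ClusterSolution:
    """Run one clustering method and score it on the shared distance matrix.

    Every method returns a :class:`ClusterSolution` whose silhouettes come
    from the same distances (default Euclidean on the preprocessed
    features), making MSW comparable across methods. ``random_sillyputty``
    runs ``config.random_restarts`` restarts with seeds derived from
    ``seed`` and returns the restart with the highest MSW. DBSCAN ignores
    ``k``; its noise points are treated as singleton clusters (silhouette 0
    by convention) and a run yielding fewer than two core clusters is
    flagged invalid for MSW comparison.
    """
    if method not in KNOWN_METHODS:
        raise ValueError(f"unknown method {method!r}; known: {KNOWN_METHODS}")
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    d = distance if distance is not None else pairwise_distances(x, metric)
    config = config or SillyPuttyConfig(seed=seed)
    meta = {"name": method, "metric": d.metric, "seed": seed}
    if method != "dbscan":
        if k is None:
            raise ValueError(f"method {method!r} requires k")
        meta["k"] = int(k)

    if method == "hierarchical":
        meta["linkage"] = linkage
        return _solution_from_labels(d, hierarchical_init(d, k, linkage), meta)

    if method == "hierarchical_sillyputty":
        meta["linkage"] = linkage
        init = hierarchical_init(d, k, linkage)
        sol = sillyputty_refine(d, init, config)
        sol.method = {**meta, **{k_: v for k_, v in sol.method.items() if k_ != "name"}}
        return sol

    if method == "random_sillyputty":
        seeds = np.random.SeedSequence(seed).spawn(config.random_restarts)
        best = None
        for r, ss in enumerate(seeds):
            init = random_init(d.n, k, ss)
            sol = sillyputty_refine(d, init, config)
            if best is None or sol.msw > best.msw:
                best = sol
                best.method = {**meta, "restarts": config.random_restarts, "best_restart": r}
        return best

    if method == "pam":
        return _solution_from_labels(d, pam(d, k), meta)

    if method == "kmeans":
        km = KMeans(n_clusters=k, random_state=int(seed) % (2**31), n_init=10)
        labels = km.fit_predict(x) + 1
        return _solution_from_labels(d, labels, meta)

    # dbscan
    meta.update({"eps": dbscan_eps, "min_samples": dbscan_min_samples})
    db = DBSCAN(eps=dbscan_eps, min_samples=dbscan_min_samples, metric="precomputed")
    raw = db.fit_predict(d.values)
    n_core = len(set(raw) - {-1})
    labels = raw + 1
    next_id = labels.max() + 1 if n_core else 1
    noise = np.flatnonzero(raw == -1)
    for idx in noise:  # each noise point becomes its own singleton cluster
        labels[idx] = next_id
        next_id += 1
    meta["n_core_clusters"] = n_core
    meta["valid_for_msw"] = n_core >= 2
    if len(np.unique(labels)) < 2:
        return ClusterSolution(
            labels=labels,
            silhouette=np.zeros(d.n),
            msw=float("nan"),
            method=meta,
        )
    return _solution_from_labels(d, labels, meta)
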