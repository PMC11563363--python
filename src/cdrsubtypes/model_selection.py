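"""Cluster-count selection and qualitative evaluation exports.

The number of clusters is chosen by sweeping K over a contiguous range
(default 2..16) and recording the mean silhouette width at each K; local
MSW maxima are candidate models, but the reported ``chosen_k`` remains a
configuration decision rather than a blind argmax. Feature sets are
compared by the proportion of variance captured by their leading principal
components, and 2-D embeddings (t-SNE, classical MDS) are exported as
plot-ready tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .cohort import Cohort, CohortError
from .preprocess import FeatureMatrix, preprocess, resolve_feature_set
from .cluster import SillyPuttyConfig, pairwise_distances, run_method


@dataclass
class KSweepResult:
    """MSW per K over a contiguous sweep range."""

    table: pd.DataFrame  # columns: k, msw, termination, n_final_clusters, valid
    chosen_k: int
    local_maxima: list[int] = field(default_factory=list)

    def msw_at(self, k: int) -> float:
        return float(self.table.set_index("k").loc[k, "msw"])


def sweep_k(
    features: FeatureMatrix | np.ndarray,
    k_range=range(2, 17),
    method: str = "hierarchical_sillyputty",
    seed: int = 0,
    chosen_k: int | None = None,
    config: SillyPuttyConfig | None = None,
    **method_kwargs,
) -> KSweepResult:
    """Run *method* at every K in a contiguous range and tabulate MSW.

    ``local_maxima`` lists K values whose MSW exceeds both neighbours.
    ``chosen_k`` defaults to the MSW argmax but is normally supplied from
    configuration, reflecting that cluster-count choice weighs qualitative
    criteria alongside MSW.
    """
    ks = list(k_range)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k_range must be a contiguous integer range")
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if not (2 <= ks[0] and ks[-1] <= x.shape[0] - 1):
        raise ValueError(f"k_range {ks[0]}..{ks[-1]} outside [2, n-1]")
    distance = pairwise_distances(x, method_kwargs.get("metric", "euclidean"))
    rows = []
    for k in ks:
        try:
            sol = run_method(
                x, method, k, seed=seed, config=config, distance=distance, **method_kwargs
            )
            rows.append(
                {
                    "k": k,
                    "msw": sol.msw,
                    "termination": sol.termination,
                    "n_final_clusters": sol.n_clusters,
                    "valid": sol.n_clusters >= 2 and np.isfinite(sol.msw),
                }
            )
        except ValueError as exc:
            rows.append(
                {
                    "k": k,
                    "msw": float("nan"),
                    "termination": f"failed: {exc}",
                    "n_final_clusters": 0,
                    "valid": False,
                }
            )
    table = pd.DataFrame(rows)
    msw = table["msw"].to_numpy()
    local_maxima = []
    for i, k in enumerate(ks):
        left = msw[i - 1] if i > 0 else -np.inf
        right = msw[i + 1] if i < len(ks) - 1 else -np.inf
        if np.isfinite(msw[i]) and msw[i] > left and msw[i] > right:
            local_maxima.append(k)
    if chosen_k is None:
        chosen_k = int(table.loc[table["msw"].idxmax(), "k"])
    if chosen_k not in ks:
        raise ValueError(f"chosen_k={chosen_k} outside sweep range {ks[0]}..{ks[-1]}")
    return KSweepResult(table=table, chosen_k=int(chosen_k), local_maxima=local_maxima)


@dataclass
class VarianceProfile:
    """Ordered proportions of variance explained by principal components."""

    feature_set: str
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if not np.isclose(self.proportions.sum(), 1.0, atol=1e-9):
            raise ValueError("variance proportions must sum to 1")


def pca_variance(
    cohort: Cohort,
    feature_set="cdr_components",
    preprocess_features: bool = True,
) -> VarianceProfile:
    """Proportion of variance per principal component of a feature set.

    With ``preprocess_features`` (default) the clip/impute/scale pipeline is
    applied first; otherwise raw values are used with median imputation
    only (PCA tolerates no missing cells). Eigenvalues of the sample
    covariance matrix are reported as proportions of the total variance,
    sorted descending.
    """
    names = resolve_feature_set(feature_set)
    if len(names) < 2:
        raise CohortError("PCA needs at least two features")
    if preprocess_features:
        x = preprocess(cohort, names).values
    else:
        cols = []
        for feat in names:
            v = cohort.visits[feat].to_numpy(dtype=float)
            if np.isnan(v).all():
                raise CohortError(f"feature {feat!r} has no non-missing values")
            v = np.where(np.isnan(v), np.nanmedian(v), v)
            cols.append(v)
        x = np.column_stack(cols)
    cov = np.cov(x, rowvar=False)
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    total = eigvals.sum()
    if total == 0:
        raise CohortError("features have zero total variance")
    label = feature_set if isinstance(feature_set, str) else ",".join(names)
    return VarianceProfile(feature_set=label, proportions=eigvals / total)


def classical_mds(d: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS by double-centering the squared distances.

    Deterministic up to sign; each coordinate axis is sign-fixed so that
    its largest-magnitude loading is positive.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1][:n_components]
    vals = np.clip(eigvals[order], 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(vals)
    for c in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, c]))
        if coords[pivot, c] < 0:
            coords[:, c] = -coords[:, c]
    return coords


def embed_2d(
    features: FeatureMatrix | np.ndarray,
    method: str = "tsne",
    seed: int = 0,
    perplexity: float = 30.0,
    n_iter: int = 1000,
) -> np.ndarray:
    """2-D embedding for qualitative cluster inspection.

    ``tsne`` uses scikit-learn's Barnes-Hut t-SNE seeded for determinism
    (perplexity clamped below n/3 on small inputs); ``mds`` is classical
    metric MDS on Euclidean distances, deterministic without a seed.
    Evaluation-only: embeddings never feed back into clustering.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("embedding needs at least 3 rows")
    if method == "mds":
        return classical_mds(pairwise_distances(x).values)
    if method == "tsne":
        perp = min(perplexity, (n - 1) / 3)
        tsne = TSNE(
            n_components=2,
            perplexity=perp,
            max_iter=n_iter,
            random_state=int(seed) % (2**31),
            init="pca",
        )
        return tsne.fit_transform(x)
    raise ValueError(f"unknown embedding method {method!r}")


def embedding_frame(
    features: FeatureMatrix,
    coords: np.ndarray,
    cohort: Cohort | None = None,
    labels=None,
) -> pd.DataFrame:
    """Tidy export of 2-D coordinates with row keys, global CDR and labels."""
    df = pd.DataFrame(coords, columns=["dim1", "dim2"])
    df.insert(0, "patient_id", [k[0] for k in features.row_keys])
    df.insert(1, "visit_index", [k[1] for k in features.row_keys])
    if cohort is not None:
        merged = df.merge(
            cohort.visits[["patient_id", "visit_index", "global_cdr"]],
            on=["patient_id", "visit_index"],
            how="left",
        )
        df["global_cdr"] = merged["global_cdr"].to_numpy()
    if labels is not None:
        df["cluster"] = np.asarray(labels)
    return df
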