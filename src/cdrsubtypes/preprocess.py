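"""Deterministic feature preparation for clustering.

Pipeline, fitted on all visits of all patients (visit-level pooling):

1. clip each feature to its 5th/95th percentile (linear-interpolation
   percentiles between order statistics);
2. impute missing cells with the feature median computed on the clipped,
   non-missing values;
3. min-max scale to [0, 1] using the post-clip range (zero-range features
   scale to 0).

The fitted parameters are stored per feature on the original scale and are
JSON-serializable so a transform can be re-applied bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import FEATURE_SETS, Cohort, CohortError, SchemaError


def resolve_feature_set(feature_set) -> list[str]:
    """Map a named feature set ('cdr_components', 'cognitive_scores') or an
    explicit column list to a list of canonical column names."""
    if isinstance(feature_set, str):
        try:
            return list(FEATURE_SETS[feature_set])
        except KeyError:
            raise SchemaError(
                f"unknown feature set {feature_set!r}; "
                f"known: {sorted(FEATURE_SETS)} or an explicit column list"
            ) from None
    return list(feature_set)


@dataclass(frozen=True)
class FeatureParams:
    """Fitted per-feature parameters, all on the original feature scale."""

    p5: float
    p95: float
    clip_min: float
    clip_max: float
    median: float

    def __post_init__(self) -> None:
        if self.p5 > self.p95 or self.clip_min > self.clip_max:
            raise ValueError("percentile/clip bounds out of order")


@dataclass
class PreprocessParams:
    """Ordered per-feature :class:`FeatureParams` plus bookkeeping."""

    per_feature: dict[str, FeatureParams]
    percentile_method: str = "linear"

    @property
    def feature_names(self) -> list[str]:
        return list(self.per_feature)

    @classmethod
    def identity(cls, feature_names) -> "PreprocessParams":
        """No-op params for data already on the [0, 1] scale."""
        return cls({f: FeatureParams(0.0, 1.0, 0.0, 1.0, 0.5) for f in feature_names})

    def to_json(self, path=None) -> str:
        payload = {
            "percentile_method": self.percentile_method,
            "features": {k: vars(v) for k, v in self.per_feature.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PreprocessParams":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        per_feature = {k: FeatureParams(**v) for k, v in payload["features"].items()}
        return cls(per_feature, payload.get("percentile_method", "linear"))


@dataclass
class FeatureMatrix:
    """Preprocessed numeric matrix: rows = visits, values in [0, 1]."""

    values: np.ndarray
    feature_names: list[str]
    row_keys: list[tuple]
    params: PreprocessParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape != (len(self.row_keys), len(self.feature_names)):
            raise ValueError("feature matrix shape does not match row/column keys")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing entries")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("feature matrix entries outside [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "patient_id", [k[0] for k in self.row_keys])
        df.insert(1, "visit_index", [k[1] for k in self.row_keys])
        return df


def fit_preprocess(cohort: Cohort, feature_set="cdr_components") -> PreprocessParams:
    """Fit clipping percentiles, post-clip range and imputation median.

    Parameters are pooled over all visits of all patients; the median is
    computed on the clipped non-missing values so imputation can never land
    outside the clipped range.
    """
    features = resolve_feature_set(feature_set)
    per_feature: dict[str, FeatureParams] = {}
    for feat in features:
        if feat not in cohort.visits.columns:
            raise SchemaError(f"feature column {feat!r} absent from cohort")
        values = cohort.visits[feat].dropna().to_numpy(dtype=float)
        if len(values) == 0:
            raise CohortError(f"feature {feat!r} has no non-missing values")
        p5, p95 = np.percentile(values, [5.0, 95.0], method="linear")
        clipped = np.clip(values, p5, p95)
        per_feature[feat] = FeatureParams(
            p5=float(p5),
            p95=float(p95),
            clip_min=float(clipped.min()),
            clip_max=float(clipped.max()),
            median=float(np.median(clipped)),
        )
    return PreprocessParams(per_feature)


def apply_preprocess(
    cohort: Cohort,
    params: PreprocessParams,
    feature_set=None,
) -> FeatureMatrix:
    """Clip, impute and scale cohort features with fitted *params*."""
    features = (
        params.feature_names if feature_set is None else resolve_feature_set(feature_set)
    )
    columns = []
    for feat in features:
        if feat not in params.per_feature:
            raise SchemaError(f"feature {feat!r} has no fitted parameters")
        if feat not in cohort.visits.columns:
            raise SchemaError(f"feature column {feat!r} absent from cohort")
        p = params.per_feature[feat]
        raw = cohort.visits[feat].to_numpy(dtype=float)
        clipped = np.clip(raw, p.p5, p.p95)
        clipped = np.where(np.isnan(clipped), p.median, clipped)
        span = p.clip_max - p.clip_min
        if span > 0:
            scaled = (clipped - p.clip_min) / span
        else:
            scaled = np.zeros_like(clipped)
        columns.append(np.clip(scaled, 0.0, 1.0))
    matrix = np.column_stack(columns) if columns else np.empty((cohort.n_visits, 0))
    return FeatureMatrix(
        values=matrix,
        feature_names=list(features),
        row_keys=cohort.row_keys(),
        params=params,
    )


def preprocess(cohort: Cohort, feature_set="cdr_components") -> FeatureMatrix:
    """Fit-and-apply convenience wrapper."""
    return apply_preprocess(cohort, fit_preprocess(cohort, feature_set), feature_set)
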