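"""Visit-level cohort model for a memory-clinic population.

The unit of analysis is the clinic *visit*: each visit carries the six
Clinical Dementia Rating (CDR) component ("box") scores — memory,
orientation, judgment & problem solving, community affairs, home & hobbies,
personal care — the clinician-recorded global CDR stage, and a brief
cognitive assessment battery. All scores on the CDR scale take one of the
five ordinal levels 0, 0.5, 1, 2, 3 (0 = normal cognition, 3 = severe
impairment).

A :class:`Cohort` wraps a validated :class:`pandas.DataFrame` with one row
per visit, ordered by patient and visit index. Visit order stands in for
calendar time when dates have been stripped from an extract: rows are
assumed pre-sorted by visit date within each patient.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The five admissible CDR ordinal levels (component and global scale).
CDR_LEVELS: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0)

#: Canonical names of the six CDR component ("box") scores, memory first.
CDR_COMPONENTS: tuple[str, ...] = (
    "memory",
    "orientation",
    "judgment_problem_solving",
    "community_affairs",
    "home_hobbies",
    "personal_care",
)

#: Canonical column names of the CDR components in a cohort table.
CDR_COLUMNS: tuple[str, ...] = tuple(f"cdr_{c}" for c in CDR_COMPONENTS)

#: Canonical names of the cognitive assessment battery.
COGNITIVE_TESTS: tuple[str, ...] = (
    "boston_naming",
    "mmse",
    "short_blessed",
    "word_list_memory",
    "verbal_fluency",
)

#: Default valid ranges for the cognitive tests (validation & synthesis only).
COGNITIVE_RANGES: dict[str, tuple[int, int]] = {
    "boston_naming": (0, 15),
    "mmse": (0, 30),
    "short_blessed": (0, 28),
    "word_list_memory": (0, 20),
    "verbal_fluency": (0, 60),
}

DEMOGRAPHIC_COLUMNS: tuple[str, ...] = ("age_at_visit", "sex", "race", "ethnicity")

#: Prefix marking boolean disorder-flag columns (precomputed upstream).
DISORDER_PREFIX = "disorder_"

MANDATORY_COLUMNS: tuple[str, ...] = ("patient_id",) + CDR_COLUMNS + ("global_cdr",)

#: Named feature sets selectable throughout the pipeline.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "cdr_components": CDR_COLUMNS,
    "cognitive_scores": COGNITIVE_TESTS,
}


class CohortError(Exception):
    """Base class for cohort validation failures."""


class SchemaError(CohortError):
    """A required column is missing or mis-mapped."""


class RowError(CohortError):
    """A row holds an unparseable or out-of-range value."""


class IntegrityError(CohortError):
    """Cross-row invariants violated (duplicates, broken visit order)."""


# ---------------------------------------------------------------------------
# Global CDR aggregation (Washington University scoring rules)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CdrComponents:
    """The six CDR box scores for one visit, each in {0, 0.5, 1, 2, 3}."""

    memory: float
    orientation: float
    judgment_problem_solving: float
    community_affairs: float
    home_hobbies: float
    personal_care: float

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.memory,
            self.orientation,
            self.judgment_problem_solving,
            self.community_affairs,
            self.home_hobbies,
            self.personal_care,
        )

    def __post_init__(self) -> None:
        for name, value in zip(CDR_COMPONENTS, self.as_tuple()):
            if value not in CDR_LEVELS:
                raise ValueError(f"CDR component {name!r}={value} not in {CDR_LEVELS}")


def _majority_value(scores: Sequence[float], memory: float) -> float:
    """Most frequent score in *scores*; ties broken toward the memory score."""
    values, counts = np.unique(np.asarray(scores, dtype=float), return_counts=True)
    best = counts == counts.max()
    candidates = values[best]
    return float(candidates[np.argmin(np.abs(candidates - memory))])


@functools.lru_cache(maxsize=None)
def _aggregate(memory: float, secondaries: tuple[float, ...]) -> float:
    sec = np.asarray(secondaries, dtype=float)
    if memory == 0.0:
        # Memory unimpaired: global 0 unless >= 2 secondary domains impaired.
        return 0.5 if int((sec >= 0.5).sum()) >= 2 else 0.0
    if memory == 0.5:
        # Global cannot be 0; promoted to 1 only if >= 3 secondaries score >= 1.
        return 1.0 if int((sec >= 1.0).sum()) >= 3 else 0.5
    # memory >= 1: global cannot be 0; a majority of unimpaired secondaries
    # pulls the rating down to 0.5.
    if int((sec == 0.0).sum()) >= 3:
        return 0.5
    n_equal = int((sec == memory).sum())
    greater = sec[sec > memory]
    lesser = sec[sec < memory]
    if n_equal >= 3:
        result = memory
    elif len(greater) >= 3 and len(lesser) <= 1:
        result = _majority_value(greater, memory)
    elif len(lesser) >= 3 and len(greater) <= 1:
        result = _majority_value(lesser, memory)
    else:
        # Split verdicts (3-2 or at most two on either side): memory decides.
        result = memory
    if result == 0.0:
        result = 0.5
    return float(result)


def aggregate_global_cdr(cdr: CdrComponents | Sequence[float]) -> float:
    """Aggregate six CDR component scores into the global CDR stage.

    Implements the published Washington University scoring rules: memory is
    the primary category; the five remaining (secondary) domains outvote it
    only when at least three of them fall on the same side of the memory
    score, with special handling of the unimpaired-memory and very-mild
    boundary cases. Deterministic and total over all 5^6 component
    combinations; the result is always one of the five ordinal levels.
    """
    if isinstance(cdr, CdrComponents):
        values = cdr.as_tuple()
    else:
        values = tuple(float(v) for v in cdr)
        if len(values) != 6:
            raise ValueError("expected six CDR component scores")
        CdrComponents(*values)  # validates levels
    if any(v != v for v in values):  # NaN check
        raise ValueError("cannot aggregate: missing CDR component")
    return _aggregate(values[0], values[1:])


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Validated visit-level table plus provenance tag.

    ``visits`` has one row per clinic visit with canonical column names
    (``patient_id``, ``visit_index``, the ``cdr_*`` components,
    ``global_cdr``, cognitive tests, optional demographics and
    ``disorder_*`` flags), sorted by patient then visit index.
    """

    visits: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.visits = self.visits.reset_index(drop=True)
        _validate_cohort_frame(self.visits)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def n_patients(self) -> int:
        return self.visits["patient_id"].nunique()

    @property
    def patient_ids(self) -> np.ndarray:
        return self.visits["patient_id"].unique()

    def visits_per_patient(self) -> pd.Series:
        return self.visits.groupby("patient_id", sort=False).size()

    def baseline(self) -> pd.DataFrame:
        """First-visit rows, one per patient."""
        return self.visits[self.visits["visit_index"] == 1]

    def disorder_columns(self) -> list[str]:
        return [c for c in self.visits.columns if c.startswith(DISORDER_PREFIX)]

    def row_keys(self) -> list[tuple[str, int]]:
        return list(
            zip(self.visits["patient_id"].tolist(), self.visits["visit_index"].tolist())
        )


def _validate_cohort_frame(df: pd.DataFrame) -> None:
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if "visit_index" not in df.columns:
        raise SchemaError("missing mandatory column(s): visit_index")
    for col in CDR_COLUMNS + ("global_cdr",):
        values = df[col].dropna()
        bad = ~values.isin(CDR_LEVELS)
        if bad.any():
            row = int(values.index[bad][0])
            raise RowError(
                f"row {row}: column {col!r} value {values[bad].iloc[0]!r} "
                f"is not an admissible CDR level {CDR_LEVELS}"
            )
    dup = df.duplicated(subset=["patient_id", "visit_index"])
    if dup.any():
        pid, vix = df.loc[dup.idxmax(), ["patient_id", "visit_index"]]
        raise IntegrityError(f"duplicate (patient_id, visit_index) = ({pid!r}, {vix})")
    for pid, grp in df.groupby("patient_id", sort=False):
        idx = grp["visit_index"].to_numpy()
        if not np.array_equal(np.sort(idx), np.arange(1, len(idx) + 1)):
            raise IntegrityError(
                f"patient {pid!r}: visit_index values {sorted(idx)} are not "
                f"consecutive starting at 1"
            )
        if "visit_date" in grp.columns and grp["visit_date"].notna().all():
            ordered = grp.sort_values("visit_index")["visit_date"].to_numpy()
            if np.any(ordered[1:] < ordered[:-1]):
                raise IntegrityError(f"patient {pid!r}: visit dates decrease over visits")


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _parse_ordinal_column(raw: pd.Series, col: str) -> pd.Series:
    values = raw.replace("", np.nan)
    numeric = pd.to_numeric(values, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowError(f"row {row}: column {col!r} value {values.iloc[row]!r} is not numeric")
    out = numeric.astype(float)
    present = out.dropna()
    invalid = ~present.isin(CDR_LEVELS)
    if invalid.any():
        row = int(present.index[invalid][0])
        raise RowError(
            f"row {row}: column {col!r} value {present[invalid].iloc[0]} "
            f"is not an admissible CDR level {CDR_LEVELS}"
        )
    return out


def read_visits(
    path,
    schema_map: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> Cohort:
    """Read a visit-level CSV into a validated :class:`Cohort`.

    ``schema_map`` maps canonical column names to the column names used in
    the file (identity by default), so arbitrary extracts can bind to the
    domain model. When the file lacks a ``visit_index`` column, rows are
    assumed pre-sorted by visit date within each patient and file order
    defines the visit order. Empty cells denote missing values; they are
    never coerced to 0.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace("", np.nan)
    schema_map = dict(schema_map or {})
    rename = {}
    for canonical, source in schema_map.items():
        if source not in raw.columns:
            raise SchemaError(f"mapped column {source!r} (for {canonical!r}) not in file")
        rename[source] = canonical
    df = raw.rename(columns=rename)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    out = pd.DataFrame()
    out["patient_id"] = df["patient_id"].astype(str)
    if out["patient_id"].isna().any():
        raise RowError("missing patient_id")
    if "visit_index" in df.columns:
        out["visit_index"] = pd.to_numeric(df["visit_index"]).astype(int)
    else:
        out["visit_index"] = df.groupby("patient_id", sort=False).cumcount() + 1
    if "visit_date" in df.columns:
        out["visit_date"] = pd.to_datetime(df["visit_date"])
    for col in CDR_COLUMNS + ("global_cdr",):
        out[col] = _parse_ordinal_column(df[col], col)
    for col in COGNITIVE_TESTS:
        if col in df.columns:
            out[col] = pd.to_numeric(df[col], errors="raise")
    if "age_at_visit" in df.columns:
        out["age_at_visit"] = pd.to_numeric(df["age_at_visit"], errors="raise")
    for col in ("sex", "race", "ethnicity"):
        if col in df.columns:
            out[col] = df[col]
    for col in df.columns:
        if col.startswith(DISORDER_PREFIX):
            flags = df[col].map(
                {"True": True, "False": False, "1": True, "0": False, np.nan: np.nan}
            )
            out[col] = flags
    return Cohort(out, provenance=provenance or str(path))


def _format_cell(value) -> str:
    if pd.isna(value):
        return ""
    if isinstance(value, float) and float(value).is_integer():
        return str(int(value))
    return str(value)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as canonical CSV; round-trips through :func:`read_visits`.

    Ordinal CDR values are serialized exactly as ``0, 0.5, 1, 2, 3``;
    missing cells are written empty.
    """
    df = cohort.visits.copy()
    if "visit_date" in df.columns:
        df["visit_date"] = pd.to_datetime(df["visit_date"]).dt.strftime("%Y-%m-%d")
    formatted = df.apply(lambda s: s.map(_format_cell))
    formatted.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _percentages(series: pd.Series) -> dict[str, float]:
    counts = series.dropna().value_counts()
    total = counts.sum()
    return {str(k): 100.0 * v / total for k, v in counts.items()} if total else {}


def cohort_summary(cohort: Cohort) -> dict:
    """Cohort-level descriptive summary based on baseline visits.

    Returns patient/visit counts, the single- vs multi-visit split, and —
    when the corresponding columns are present — baseline age median/IQR,
    sex/race/ethnicity percentages and disorder-flag percentages. Interval
    statistics (months between consecutive visits) are included when visit
    dates are available.
    """
    if cohort.n_visits == 0:
        raise CohortError("empty cohort")
    per_patient = cohort.visits_per_patient()
    baseline = cohort.baseline()
    summary: dict = {
        "n_patients": int(cohort.n_patients),
        "n_visits": int(cohort.n_visits),
        "n_single_visit": int((per_patient == 1).sum()),
        "n_multi_visit": int((per_patient > 1).sum()),
        "max_visits": int(per_patient.max()),
    }
    if "age_at_visit" in baseline.columns and baseline["age_at_visit"].notna().any():
        age = baseline["age_at_visit"].dropna()
        summary["baseline_age_median"] = float(age.median())
        summary["baseline_age_iqr"] = (
            float(age.quantile(0.25)),
            float(age.quantile(0.75)),
        )
    for col in ("sex", "race", "ethnicity"):
        if col in baseline.columns:
            summary[f"{col}_pct"] = _percentages(baseline[col])
    for col in cohort.disorder_columns():
        flags = baseline[col].dropna()
        if len(flags):
            summary[f"{col}_pct"] = 100.0 * float(flags.astype(bool).mean())
    if "visit_date" in cohort.visits.columns:
        intervals = visit_intervals_months(cohort)
        if len(intervals):
            summary["interval_mean_months"] = float(np.mean(intervals))
            summary["interval_sd_months"] = float(np.std(intervals, ddof=1))
    return summary


def visit_intervals_months(cohort: Cohort) -> np.ndarray:
    """Months between consecutive visits, pooled over multi-visit patients."""
    if "visit_date" not in cohort.visits.columns:
        return np.array([])
    df = cohort.visits.sort_values(["patient_id", "visit_index"])
    deltas = df.groupby("patient_id", sort=False)["visit_date"].diff().dropna()
    return deltas.dt.days.to_numpy() / 30.44
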