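"""Synthetic longitudinal memory-clinic cohorts with known subtype structure.

The generator emulates the statistical shape of a specialty-clinic extract:
~half of patients contribute a single visit, the rest up to five visits at
roughly 9-month intervals; each visit carries six ordinal CDR component
scores drawn from a latent subtype's discretized-normal level
distributions; the global CDR is aggregated from the components by the
published scoring rules; cognitive test scores follow monotone
severity-linked trends with integer-rounded Gaussian noise; a small
fraction of feature cells is masked missing completely at random; and
patients move between latent subtypes across visits following a
row-stochastic Markov matrix that favors progression to more severe
subtypes.

Because the latent state sequence is retained as :class:`GroundTruth`,
every pipeline stage (preprocessing, clustering, transitions) is testable
against known answers without any external data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm
from sklearn.metrics import adjusted_rand_score

from .cohort import (
    CDR_COLUMNS,
    CDR_LEVELS,
    COGNITIVE_RANGES,
    COGNITIVE_TESTS,
    Cohort,
    _aggregate,
)

LEVELS = np.asarray(CDR_LEVELS)


class SpecError(ValueError):
    """A synthetic specification violates one of its invariants."""


@dataclass
class SubtypeDef:
    """One latent subtype: target level per CDR component plus spread.

    ``targets`` are on the clinical level scale (0, 0.5, 1, 2, 3);
    ``sd`` is the standard deviation of the discretized truncated normal
    on the level-index scale (indices 0..4), so sd << 0.5 makes the
    component effectively deterministic.
    """

    name: str
    targets: list[float]
    sd: float = 0.35

    def __post_init__(self) -> None:
        if len(self.targets) != 6:
            raise SpecError(f"subtype {self.name!r}: expected 6 component targets")
        if self.sd <= 0:
            raise SpecError(f"subtype {self.name!r}: sd must be positive")

    def level_pmfs(self) -> np.ndarray:
        """6 x 5 matrix of per-component probabilities over the CDR levels."""
        idx_targets = np.interp(self.targets, LEVELS, np.arange(5))
        edges = np.array([-np.inf, 0.5, 1.5, 2.5, 3.5, np.inf])
        cdf = norm.cdf(edges[None, :], loc=idx_targets[:, None], scale=self.sd)
        pmf = np.diff(cdf, axis=1)
        return pmf / pmf.sum(axis=1, keepdims=True)

    @property
    def severity(self) -> float:
        """Expected mean component level divided by 3 (range [0, 1])."""
        return float((self.level_pmfs() @ LEVELS).mean() / 3.0)


#: Cognitive-score model: expected = intercept + slope * severity, with
#: N(0, sd) noise, integer rounding, and clipping to the test's range.
DEFAULT_COGNITIVE_MODEL: dict[str, dict[str, float]] = {
    "boston_naming": {"intercept": 15.0, "slope": -6.0, "sd": 1.5},
    "mmse": {"intercept": 29.0, "slope": -16.0, "sd": 2.5},
    "short_blessed": {"intercept": 2.0, "slope": 22.0, "sd": 3.0},
    "word_list_memory": {"intercept": 18.0, "slope": -10.0, "sd": 2.0},
    "verbal_fluency": {"intercept": 15.0, "slope": -8.0, "sd": 2.0},
}


def progressive_markov(
    k: int,
    self_prob: float = 0.40,
    forward: float = 0.53,
    backward: float = 0.07,
    forward_split: tuple[float, ...] = (0.30, 0.35, 0.35),
) -> np.ndarray:
    """Row-stochastic matrix over severity-ordered subtypes favoring
    progression: mass splits into staying put, moving forward by 1..len
    (forward_split) severity ranks, and rarely moving one rank back; mass
    that would leave the state space folds into staying put."""
    if not np.isclose(self_prob + forward + backward, 1.0):
        raise SpecError("self_prob + forward + backward must equal 1")
    if not np.isclose(sum(forward_split), 1.0):
        raise SpecError("forward_split must sum to 1")
    m = np.zeros((k, k))
    for i in range(k):
        m[i, i] = self_prob
        for step, p in enumerate(forward_split, start=1):
            j = i + step
            if j < k:
                m[i, j] += forward * p
            else:
                m[i, i] += forward * p
        if i - 1 >= 0:
            m[i, i - 1] += backward
        else:
            m[i, i] += backward
    return m


@dataclass
class SyntheticSpec:
    """Complete generative description of a synthetic cohort."""

    n_patients: int
    subtypes: list[SubtypeDef]
    mixing: list[float]
    markov: np.ndarray
    visit_count_dist: dict[int, float]
    interval_mean_months: float = 8.8
    interval_sd_months: float = 3.6
    component_missingness: float = 0.01
    cognitive_missingness: float = 0.04
    cognitive_model: dict = field(default_factory=lambda: dict(DEFAULT_COGNITIVE_MODEL))
    first_visit: str = "2014-06-01"
    enrollment_window_days: int = 1095
    seed: int = 0

    def __post_init__(self) -> None:
        self.markov = np.asarray(self.markov, dtype=float)
        self.validate()

    def validate(self) -> None:
        k = len(self.subtypes)
        problems = []
        if self.n_patients < 1:
            problems.append("n_patients must be >= 1")
        if len(self.mixing) != k:
            problems.append("mixing length must equal number of subtypes")
        if not np.isclose(np.sum(self.mixing), 1.0):
            problems.append("mixing proportions must sum to 1")
        if np.min(self.mixing) < 0:
            problems.append("mixing proportions must be non-negative")
        if self.markov.shape != (k, k):
            problems.append("markov matrix must be K x K")
        elif not np.allclose(self.markov.sum(axis=1), 1.0):
            problems.append("markov rows must sum to 1")
        elif (self.markov < 0).any():
            problems.append("markov entries must be non-negative")
        counts = sorted(self.visit_count_dist)
        if min(counts) < 1:
            problems.append("visit counts must be >= 1")
        if not np.isclose(sum(self.visit_count_dist.values()), 1.0):
            problems.append("visit_count_dist must sum to 1")
        for rate, name in (
            (self.component_missingness, "component_missingness"),
            (self.cognitive_missingness, "cognitive_missingness"),
        ):
            if not 0 <= rate < 1:
                problems.append(f"{name} must be in [0, 1)")
        if self.interval_mean_months <= 0 or self.interval_sd_months <= 0:
            problems.append("interval model parameters must be positive")
        if problems:
            raise SpecError("; ".join(problems))

    @property
    def max_visits(self) -> int:
        return max(self.visit_count_dist)

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "subtypes": [
                {"name": s.name, "targets": list(map(float, s.targets)), "sd": s.sd}
                for s in self.subtypes
            ],
            "mixing": [float(v) for v in self.mixing],
            "markov": self.markov.tolist(),
            "visit_count_dist": {int(k): float(v) for k, v in self.visit_count_dist.items()},
            "interval_mean_months": self.interval_mean_months,
            "interval_sd_months": self.interval_sd_months,
            "component_missingness": self.component_missingness,
            "cognitive_missingness": self.cognitive_missingness,
            "cognitive_model": self.cognitive_model,
            "first_visit": self.first_visit,
            "enrollment_window_days": self.enrollment_window_days,
            "seed": self.seed,
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticSpec":
        payload = dict(payload)
        payload["subtypes"] = [SubtypeDef(**s) for s in payload["subtypes"]]
        payload["visit_count_dist"] = {
            int(k): float(v) for k, v in payload["visit_count_dist"].items()
        }
        return cls(**payload)

    @classmethod
    def from_yaml(cls, source) -> "SyntheticSpec":
        if isinstance(source, str) and "\n" in source:
            payload = yaml.safe_load(source)
        else:
            with open(source) as fh:
                payload = yaml.safe_load(fh)
        return cls.from_dict(payload)


def load_preset(name: str, **overrides) -> SyntheticSpec:
    """Load a shipped preset ('paper_like' or 'toy'), optionally overriding
    top-level fields (e.g. ``n_patients`` or ``seed``)."""
    ref = importlib.resources.files("cdrsubtypes") / "presets" / f"{name}.yaml"
    try:
        payload = yaml.safe_load(ref.read_text())
    except FileNotFoundError:
        raise SpecError(f"unknown preset {name!r}") from None
    payload.update(overrides)
    return SyntheticSpec.from_dict(payload)


@dataclass
class GroundTruth:
    """Latent subtype per visit plus the generating specification."""

    assignments: pd.DataFrame  # patient_id, visit_index, subtype (0-based)
    spec: SyntheticSpec

    @property
    def visit_subtypes(self) -> np.ndarray:
        return self.assignments["subtype"].to_numpy()

    def to_csv(self, path) -> None:
        self.assignments.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _truncated_normal_positive(rng, mean, sd, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def generate_cohort(spec: SyntheticSpec, seed: int | None = None) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort from *spec*; bit-identical for a given seed.

    Per patient: visit count, then a Markov chain of latent subtypes
    starting from the mixing distribution, then positive truncated-normal
    inter-visit intervals. Per visit: CDR components from the subtype's
    level distributions, global CDR aggregated from the components (the
    recorded value is therefore always rule-consistent), severity-linked
    cognitive scores, then independent missingness masks per feature cell.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    k = len(spec.subtypes)
    counts = np.array(sorted(spec.visit_count_dist))
    count_p = np.array([spec.visit_count_dist[c] for c in counts], dtype=float)
    count_p = count_p / count_p.sum()
    mixing = np.asarray(spec.mixing, dtype=float)

    rows_pid, rows_vix, rows_sub, rows_date = [], [], [], []
    base_date = np.datetime64(spec.first_visit)
    width = len(str(spec.n_patients))
    for p in range(spec.n_patients):
        pid = f"P{p + 1:0{width}d}"
        m = int(rng.choice(counts, p=count_p))
        chain = [int(rng.choice(k, p=mixing))]
        for _ in range(m - 1):
            chain.append(int(rng.choice(k, p=spec.markov[chain[-1]])))
        start = base_date + np.timedelta64(int(rng.integers(0, spec.enrollment_window_days)), "D")
        offsets = np.concatenate(
            [
                [0.0],
                np.cumsum(
                    _truncated_normal_positive(
                        rng, spec.interval_mean_months, spec.interval_sd_months, m - 1
                    )
                ),
            ]
        )
        for t in range(m):
            rows_pid.append(pid)
            rows_vix.append(t + 1)
            rows_sub.append(chain[t])
            rows_date.append(start + np.timedelta64(int(round(offsets[t] * 30.44)), "D"))

    n = len(rows_pid)
    subtype = np.array(rows_sub)
    components = np.empty((n, 6))
    for s in range(k):
        mask = subtype == s
        if not mask.any():
            continue
        pmf = spec.subtypes[s].level_pmfs()
        for c in range(6):
            draws = rng.choice(5, size=int(mask.sum()), p=pmf[c])
            components[mask, c] = LEVELS[draws]
    global_cdr = np.array(
        [_aggregate(row[0], tuple(row[1:])) for row in components]
    )
    severity = np.array([spec.subtypes[s].severity for s in range(k)])[subtype]

    cognitive = {}
    for test in COGNITIVE_TESTS:
        model = spec.cognitive_model[test]
        lo, hi = COGNITIVE_RANGES[test]
        raw = model["intercept"] + model["slope"] * severity + rng.normal(0, model["sd"], n)
        cognitive[test] = np.clip(np.round(raw), lo, hi)

    masked_components = components.copy()
    if spec.component_missingness > 0:
        mask = rng.random((n, 6)) < spec.component_missingness
        masked_components[mask] = np.nan
    for test in COGNITIVE_TESTS:
        if spec.cognitive_missingness > 0:
            mask = rng.random(n) < spec.cognitive_missingness
            cognitive[test] = np.where(mask, np.nan, cognitive[test])

    df = pd.DataFrame({"patient_id": rows_pid, "visit_index": rows_vix})
    df["visit_date"] = pd.to_datetime(np.array(rows_date))
    for j, col in enumerate(CDR_COLUMNS):
        df[col] = masked_components[:, j]
    df["global_cdr"] = global_cdr
    for test in COGNITIVE_TESTS:
        df[test] = cognitive[test]
    cohort = Cohort(df, provenance=f"synthetic(seed={spec.seed if seed is None else seed})")
    truth = GroundTruth(
        assignments=pd.DataFrame(
            {"patient_id": rows_pid, "visit_index": rows_vix, "subtype": rows_sub}
        ),
        spec=spec,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

def recovery_report(truth: GroundTruth, solution, graph=None) -> dict:
    """Agreement between latent subtypes and an estimated clustering.

    Returns the adjusted Rand index, the subtype-by-cluster confusion
    matrix, the Hungarian-optimal cluster-to-subtype matching, and — when a
    transition graph is supplied — the maximum absolute cell error between
    the generating Markov matrix and the empirical transition matrix after
    relabeling clusters through the matching (rows without observed
    transitions are skipped).
    """
    true_labels = truth.visit_subtypes
    est_labels = np.asarray(solution.labels)
    if len(true_labels) != len(est_labels):
        raise ValueError("ground truth and solution cover different numbers of visits")
    ari = adjusted_rand_score(true_labels, est_labels)
    true_ids = np.unique(true_labels)
    est_ids = np.unique(est_labels)
    conf = np.zeros((len(true_ids), len(est_ids)), dtype=int)
    for i, t in enumerate(true_ids):
        for j, e in enumerate(est_ids):
            conf[i, j] = int(np.sum((true_labels == t) & (est_labels == e)))
    row_ind, col_ind = linear_sum_assignment(-conf)
    mapping = {int(est_ids[j]): int(true_ids[i]) for i, j in zip(row_ind, col_ind)}
    report = {
        "ari": float(ari),
        "confusion": conf,
        "true_ids": true_ids,
        "cluster_ids": est_ids,
        "mapping": mapping,
    }
    if graph is not None:
        k = len(truth.spec.subtypes)
        trans = graph.transitions
        src = trans["source"].map(mapping)
        dst = trans["target"].map(mapping)
        ok = src.notna() & dst.notna()
        counts = np.zeros((k, k))
        for a, b in zip(src[ok].astype(int), dst[ok].astype(int)):
            counts[a, b] += 1
        row_sums = counts.sum(axis=1)
        errors = []
        for i in range(k):
            if row_sums[i] > 0:
                errors.append(np.abs(counts[i] / row_sums[i] - truth.spec.markov[i]).max())
        report["empirical_markov"] = counts / np.where(row_sums[:, None] == 0, 1, row_sums[:, None])
        report["markov_max_abs_error"] = float(max(errors)) if errors else float("nan")
        report["n_unmatched_transitions"] = int((~ok).sum())
    return report
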