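"""Shared fixtures and independent oracle helpers.

The oracle functions here are deliberately naive (double loops, exhaustive
enumeration) and independent of the vectorized implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from cdrsubtypes import CDR_COLUMNS, Cohort, generate_cohort, load_preset


# ---------------------------------------------------------------------------
# Cohort builders
# ---------------------------------------------------------------------------

def make_cohort(records: list[dict], **defaults) -> Cohort:
    """Build a cohort from compact per-visit dicts; unspecified CDR
    components default to the global CDR value."""
    rows = []
    for rec in records:
        row = {
            "patient_id": rec["pid"],
            "visit_index": rec["visit"],
            "global_cdr": rec.get("global", 0.0),
        }
        for col in CDR_COLUMNS:
            row[col] = rec.get(col, rec.get("global", 0.0))
        for key, value in rec.items():
            if key not in {"pid", "visit", "global"} and key not in CDR_COLUMNS:
                row[key] = value
        row.update(defaults)
        rows.append(row)
    return Cohort(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def toy_cohort_truth():
    spec = load_preset("toy")
    return generate_cohort(spec, seed=7)


@pytest.fixture(scope="session")
def toy_cohort(toy_cohort_truth):
    return toy_cohort_truth[0]


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def naive_silhouette(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Textbook per-point silhouette by explicit double loops."""
    n = len(labels)
    out = np.zeros(n)
    ids = sorted(set(labels.tolist()))
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            out[i] = 0.0
            continue
        a = float(np.mean([d[i, j] for j in own]))
        b = np.inf
        for c in ids:
            if c == labels[i]:
                continue
            members = [j for j in range(n) if labels[j] == c]
            b = min(b, float(np.mean([d[i, j] for j in members])))
        denom = max(a, b)
        out[i] = 0.0 if denom == 0 else (b - a) / denom
    return out


def all_bipartitions(n: int):
    """Every 2-cluster partition of n points as a label array (1/2)."""
    for bits in itertools.product([1, 2], repeat=n - 1):
        labels = np.array((1,) + bits)
        if len(set(labels.tolist())) == 2:
            yield labels


def best_bipartition_msw(d: np.ndarray) -> float:
    """Global maximum MSW over all 2-cluster partitions (exhaustive)."""
    best = -np.inf
    for labels in all_bipartitions(d.shape[0]):
        best = max(best, float(np.mean(naive_silhouette(d, labels))))
    return best


def pam_cost(d: np.ndarray, medoids) -> float:
    return float(d[:, list(medoids)].min(axis=1).sum())


def best_pam_cost(d: np.ndarray, k: int) -> float:
    """Exhaustive optimal k-medoids cost (tiny n only)."""
    n = d.shape[0]
    return min(pam_cost(d, m) for m in itertools.combinations(range(n), k))
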