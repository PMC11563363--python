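"""Subtype characterization and longitudinal cluster-transition analysis.

Clustering treats visits as independent; temporality returns here. Each
patient occupies one subtype (cluster) per visit and may move between
subtypes across consecutive visits. The transition graph counts those
moves (self-transitions included); a transition is *progression* when the
recorded global CDR stage increases from one visit to the next, *stable*
when it is unchanged, and *regression* when it decreases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .cohort import (
    CDR_COLUMNS,
    CDR_COMPONENTS,
    CDR_LEVELS,
    COGNITIVE_TESTS,
    Cohort,
    visit_intervals_months,
)
from .cluster import ClusterSolution


# ---------------------------------------------------------------------------
# Subtype profiles
# ---------------------------------------------------------------------------

@dataclass
class SubtypeProfile:
    """Visit-level composition and baseline demographics of one subtype."""

    cluster_id: int
    severity_rank: int
    n_visits: int
    mean_global_cdr: float
    cdr_composition: dict[float, int]
    component_distributions: dict[str, dict[float, int]]
    baseline_demographics: dict
    cognitive_summaries: dict[str, tuple[float, float]]

    @property
    def is_homogeneous(self) -> bool:
        """True when member visits share a single global CDR level."""
        return sum(1 for v in self.cdr_composition.values() if v > 0) == 1

    @property
    def global_cdr_levels(self) -> list[float]:
        return [lvl for lvl, cnt in sorted(self.cdr_composition.items()) if cnt > 0]


def profile_subtypes(cohort: Cohort, solution: ClusterSolution) -> list[SubtypeProfile]:
    """Characterize every cluster, ordered by ascending mean global CDR.

    Composition and component distributions are visit-level; demographics
    and cognitive summaries are computed over the baseline visits of the
    patients whose baseline visit falls in the cluster.
    """
    df = cohort.visits.copy()
    if len(solution.labels) != len(df):
        raise ValueError("solution labels do not cover every visit")
    df["cluster"] = np.asarray(solution.labels)
    order = (
        df.groupby("cluster")["global_cdr"].mean().sort_values(kind="stable").index
    )
    profiles = []
    baseline = df[df["visit_index"] == 1]
    for rank, cid in enumerate(order, start=1):
        members = df[df["cluster"] == cid]
        base = baseline[baseline["cluster"] == cid]
        composition = {
            lvl: int((members["global_cdr"] == lvl).sum()) for lvl in CDR_LEVELS
        }
        component_distributions = {
            comp: {
                lvl: int((members[f"cdr_{comp}"] == lvl).sum()) for lvl in CDR_LEVELS
            }
            for comp in CDR_COMPONENTS
        }
        demographics: dict = {"n_patients": int(base["patient_id"].nunique())}
        if "age_at_visit" in base.columns and base["age_at_visit"].notna().any():
            age = base["age_at_visit"].dropna()
            demographics["age_median"] = float(age.median())
            demographics["age_iqr"] = float(age.quantile(0.75) - age.quantile(0.25))
        for col in ("sex", "race", "ethnicity"):
            if col in base.columns and base[col].notna().any():
                counts = base[col].value_counts(normalize=True)
                demographics[f"{col}_pct"] = {
                    str(k): 100.0 * float(v) for k, v in counts.items()
                }
        for col in [c for c in base.columns if c.startswith("disorder_")]:
            flags = base[col].dropna()
            if len(flags):
                demographics[f"{col}_pct"] = 100.0 * float(flags.astype(bool).mean())
        cognitive = {}
        for test in COGNITIVE_TESTS:
            if test in base.columns and base[test].notna().any():
                v = base[test].dropna()
                cognitive[test] = (
                    float(v.median()),
                    float(v.quantile(0.75) - v.quantile(0.25)),
                )
        profiles.append(
            SubtypeProfile(
                cluster_id=int(cid),
                severity_rank=rank,
                n_visits=int(len(members)),
                mean_global_cdr=float(members["global_cdr"].mean()),
                cdr_composition=composition,
                component_distributions=component_distributions,
                baseline_demographics=demographics,
                cognitive_summaries=cognitive,
            )
        )
    return profiles


def profiles_to_frames(profiles: list[SubtypeProfile]) -> dict[str, pd.DataFrame]:
    """Tidy CSV-ready tables: stage composition, component distributions,
    baseline demographics."""
    comp_rows, dist_rows, demo_rows = [], [], []
    for p in profiles:
        for lvl, cnt in p.cdr_composition.items():
            comp_rows.append(
                {
                    "cluster": p.cluster_id,
                    "severity_rank": p.severity_rank,
                    "global_cdr": lvl,
                    "n_visits": cnt,
                }
            )
        for comp, dist in p.component_distributions.items():
            for lvl, cnt in dist.items():
                dist_rows.append(
                    {
                        "cluster": p.cluster_id,
                        "severity_rank": p.severity_rank,
                        "component": comp,
                        "score": lvl,
                        "n_visits": cnt,
                    }
                )
        row = {
            "cluster": p.cluster_id,
            "severity_rank": p.severity_rank,
            "n_visits": p.n_visits,
            "mean_global_cdr": p.mean_global_cdr,
            "n_patients": p.baseline_demographics.get("n_patients", 0),
        }
        for test, (med, iqr) in p.cognitive_summaries.items():
            row[f"{test}_median"] = med
            row[f"{test}_iqr"] = iqr
        demo_rows.append(row)
    return {
        "composition": pd.DataFrame(comp_rows),
        "components": pd.DataFrame(dist_rows),
        "demographics": pd.DataFrame(demo_rows),
    }


# ---------------------------------------------------------------------------
# Transition graph
# ---------------------------------------------------------------------------

@dataclass
class TransitionGraph:
    """Directed weighted graph of consecutive-visit subtype transitions.

    ``transitions`` has one row per consecutive visit pair: patient, step,
    source/target cluster, source/target global CDR and (when dates exist)
    the interval in months. ``graph`` aggregates edge weights = counts.
    """

    graph: nx.DiGraph
    transitions: pd.DataFrame
    node_stages: dict[int, float] = field(default_factory=dict)

    @property
    def total_transitions(self) -> int:
        return len(self.transitions)

    def edge_weights(self) -> dict[tuple[int, int], int]:
        return {(u, v): data["weight"] for u, v, data in self.graph.edges(data=True)}

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "weight": data["weight"]}
            for u, v, data in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"]).sort_values(
            ["source", "target"], ignore_index=True
        )

    def pivot_table(self) -> pd.DataFrame:
        """Source-by-target count matrix with a row-total column."""
        nodes = sorted(self.graph.nodes)
        mat = pd.DataFrame(0, index=nodes, columns=nodes)
        for (u, v), w in self.edge_weights().items():
            mat.loc[u, v] = w
        mat["total"] = mat.sum(axis=1)
        mat.index.name = "source"
        return mat


def build_transition_graph(cohort: Cohort, solution: ClusterSolution) -> TransitionGraph:
    """One edge occurrence per consecutive visit pair of each patient.

    Self-transitions count; single-visit patients contribute nothing.
    Nodes are annotated with their dominant (modal) member global CDR.
    """
    df = cohort.visits.copy()
    if len(solution.labels) != len(df):
        raise ValueError("solution labels do not cover every visit")
    df["cluster"] = np.asarray(solution.labels)
    df = df.sort_values(["patient_id", "visit_index"], kind="stable")
    grp = df.groupby("patient_id", sort=False)
    nxt = grp[["cluster", "global_cdr"]].shift(-1)
    has_next = nxt["cluster"].notna()
    trans = pd.DataFrame(
        {
            "patient_id": df.loc[has_next, "patient_id"].to_numpy(),
            "step": df.loc[has_next, "visit_index"].to_numpy(),
            "source": df.loc[has_next, "cluster"].to_numpy(),
            "target": nxt.loc[has_next, "cluster"].to_numpy().astype(df["cluster"].dtype),
            "source_global_cdr": df.loc[has_next, "global_cdr"].to_numpy(),
            "target_global_cdr": nxt.loc[has_next, "global_cdr"].to_numpy(),
        }
    )
    if "visit_date" in df.columns:
        next_date = grp["visit_date"].shift(-1)
        delta = (next_date - df["visit_date"]).dt.days / 30.44
        trans["interval_months"] = delta[has_next].to_numpy()
    graph = nx.DiGraph()
    stages = df.groupby("cluster")["global_cdr"].agg(
        lambda s: s.mode().iloc[0] if len(s.mode()) else np.nan
    )
    for cid, stage in stages.items():
        graph.add_node(int(cid), dominant_stage=float(stage))
    for (u, v), w in trans.groupby(["source", "target"]).size().items():
        graph.add_edge(int(u), int(v), weight=int(w))
    return TransitionGraph(
        graph=graph,
        transitions=trans.reset_index(drop=True),
        node_stages={int(c): float(s) for c, s in stages.items()},
    )


# ---------------------------------------------------------------------------
# Progression statistics
# ---------------------------------------------------------------------------

def stage_group(global_cdr: float) -> str:
    """Coarse dementia stage: '<=0.5' (none/very mild), '1' (mild), '>1'."""
    if global_cdr <= 0.5:
        return "<=0.5"
    if global_cdr == 1.0:
        return "1"
    return ">1"


def progression_stats(graph: TransitionGraph, cohort: Cohort) -> dict:
    """Classify transitions by global-CDR change and count progressors.

    A transition is progression / stable / regression according to whether
    the later visit's recorded global CDR is greater / equal / smaller. A
    *progressor* is a multi-visit patient with at least one progression
    transition; the fraction is over multi-visit patients and is reported
    as None for a cohort without any.
    """
    t = graph.transitions
    delta = t["target_global_cdr"] - t["source_global_cdr"]
    n_multi = int((cohort.visits_per_patient() > 1).sum())
    progressors = t.loc[delta > 0, "patient_id"].nunique()
    per_source = (
        t[delta > 0].groupby("source").size().astype(int).to_dict()
        if len(t)
        else {}
    )
    stage_moves = (
        t.assign(
            source_stage=t["source_global_cdr"].map(stage_group),
            target_stage=t["target_global_cdr"].map(stage_group),
        )
        .groupby(["source_stage", "target_stage"])
        .size()
        .astype(int)
        .to_dict()
        if len(t)
        else {}
    )
    return {
        "n_transitions": int(len(t)),
        "n_progression": int((delta > 0).sum()),
        "n_stable": int((delta == 0).sum()),
        "n_regression": int((delta < 0).sum()),
        "n_multi_visit_patients": n_multi,
        "n_progressors": int(progressors),
        "progressor_fraction": (progressors / n_multi) if n_multi else None,
        "per_source_progressions": {int(k): v for k, v in per_source.items()},
        "stage_transitions": {f"{a}->{b}": v for (a, b), v in stage_moves.items()},
    }


# ---------------------------------------------------------------------------
# Interval comparison
# ---------------------------------------------------------------------------

def compare_intervals(graph: TransitionGraph, filter_a, filter_b) -> dict:
    """Compare inter-visit intervals between two transition groups.

    ``filter_a``/``filter_b`` are callables mapping the transitions
    DataFrame to a boolean mask (e.g. transitions out of one subtype into a
    more severe stage). Reports each group's median interval in months and
    a two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value, exact when both
    groups are small and tie-free.
    """
    t = graph.transitions
    if "interval_months" not in t.columns or t["interval_months"].isna().all():
        return {"available": False, "reason": "intervals unavailable (no visit dates)"}
    a = t.loc[np.asarray(filter_a(t), bool), "interval_months"].dropna().to_numpy()
    b = t.loc[np.asarray(filter_b(t), bool), "interval_months"].dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        return {"available": False, "reason": "a filtered group has no transitions"}
    exact = len(a) <= 25 and len(b) <= 25 and len(np.unique(np.r_[a, b])) == len(a) + len(b)
    stat, p = mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return {
        "available": True,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "u_statistic": float(stat),
        "p_value": float(p),
        "test": "wilcoxon_rank_sum_two_sided_" + ("exact" if exact else "asymptotic"),
    }
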