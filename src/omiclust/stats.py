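"""Survival separation and cluster-enrichment feature selection.

Survival: clinical records (overall survival, disease-specific survival,
progression-free and disease-free intervals) are censored by cohort rules
-- for OS, deaths within 30 days and patients over 80 at baseline are
treated as censored; every metric is capped at a 10-year horizon -- then
cluster separation is assessed by Kaplan-Meier curves and the k-sample
log-rank test.  Clusters of size one are removed before testing.

Feature selection: per cluster and gene, alterations are discretized
(copy-number gain >= 1 / loss <= -1 on GISTIC-style values, expression
z-score >= 1 / <= -1, methylation beta >= 0.75 / <= 0.25, mutations as-is)
and tested for enrichment with an upper-tail hypergeometric test,
BH-adjusted per (cluster, data type, direction) family.  Copy-number,
expression and methylation calls additionally pass a representativeness
filter: altered in at least 2/3 of the cluster and in under 1/3 of at
least one other cluster.  Mutations rely on the FDR criterion alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import OmicsMatrix

SURVIVAL_METRICS = ("OS", "DSS", "PFI", "DFI")

DEFAULT_HORIZON_DAYS = 3650    # 10-year observation window
EARLY_DEATH_DAYS = 30          # OS-only early-death censoring rule
MAX_AGE_AT_START = 80          # OS-only age censoring rule

#: discretization thresholds per data type: direction -> (comparator, cut)
_DISCRETIZE_RULES: dict[str, dict[str, tuple[str, float]]] = {
    "mutation": {"mutated": ("ge", 1.0)},
    "cna": {"gain": ("ge", 1.0), "loss": ("le", -1.0)},
    "expression": {"over": ("ge", 1.0), "under": ("le", -1.0)},
    "methylation": {"hyper": ("ge", 0.75), "hypo": ("le", 0.25)},
}


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up for one outcome metric."""

    patient_id: str
    time: float                  # days
    event: bool
    age_at_start: float | None = None
    metric: str = "OS"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.patient_id}")
        if self.metric not in SURVIVAL_METRICS:
            raise ValueError(f"unknown survival metric {self.metric!r}")


def read_clinical(path) -> list[SurvivalRecord]:
    """Clinical TSV: patient_id, time_days, event, age, metric."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    records = []
    for row in df.itertuples(index=False):
        age = getattr(row, "age", None)
        records.append(
            SurvivalRecord(
                patient_id=str(row.patient_id),
                time=float(row.time_days),
                event=bool(int(row.event)),
                age_at_start=None if age is None or pd.isna(age) else float(age),
                metric=str(getattr(row, "metric", "OS")),
            )
        )
    return records


def write_clinical(records: Sequence[SurvivalRecord], path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time_days": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "age": [r.age_at_start for r in records],
            "metric": [r.metric for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def apply_censoring(
    records: Sequence[SurvivalRecord], horizon_days: float = DEFAULT_HORIZON_DAYS
) -> list[SurvivalRecord]:
    """Administrative censoring rules.

    OS only: deaths at <= 30 days and patients over 80 at baseline become
    censored observations.  All metrics: times beyond the horizon are
    capped there with event = False.
    """
    out = []
    for r in records:
        if r.metric == "OS":
            if r.event and r.time <= EARLY_DEATH_DAYS:
                r = replace(r, event=False)
            if r.age_at_start is not None and r.age_at_start > MAX_AGE_AT_START:
                r = replace(r, event=False)
        if r.time > horizon_days:
            r = replace(r, time=float(horizon_days), event=False)
        out.append(r)
    return out


def drop_singleton_clusters(
    labels: np.ndarray, records: Sequence[SurvivalRecord]
) -> tuple[np.ndarray, list[SurvivalRecord]]:
    """Remove patients whose cluster has a single member (survival only)."""
    labels = np.asarray(labels)
    if len(labels) != len(records):
        raise ValueError("labels and records must align")
    values, counts = np.unique(labels, return_counts=True)
    keep_clusters = set(values[counts > 1])
    if not keep_clusters:
        raise ValueError("all clusters are singletons; no survival groups remain")
    mask = np.isin(labels, list(keep_clusters))
    return labels[mask], [r for r, m in zip(records, mask) if m]


@dataclass(frozen=True)
class KMCurve:
    """Right-continuous product-limit survival curve."""

    times: np.ndarray            # event/censor times in increasing order
    probs: np.ndarray            # S(t) at those times

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.probs[np.maximum(idx, 0)], 1.0)
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.probs})


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one group."""
    if not records:
        raise ValueError("no records to estimate from")
    kmf = KaplanMeierFitter()
    kmf.fit(
        durations=[r.time for r in records],
        event_observed=[int(r.event) for r in records],
    )
    sf = kmf.survival_function_
    return KMCurve(
        times=sf.index.to_numpy(dtype=float), probs=sf.iloc[:, 0].to_numpy(dtype=float)
    )


def logrank_test(
    records: Sequence[SurvivalRecord], groups: np.ndarray
) -> tuple[float, int, float]:
    """Unstratified k-sample log-rank test; returns (chi2, df, p).

    With no events at all the test is vacuous: returns (0, k-1, 1) with a
    warning rather than an error.
    """
    groups = np.asarray(groups)
    if len(groups) != len(records):
        raise ValueError("groups and records must align")
    uniq = np.unique(groups)
    k = len(uniq)
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([int(r.event) for r in records])
    if events.sum() == 0:
        warnings.warn("no events in any group; log-rank test is vacuous", stacklevel=2)
        return 0.0, k - 1, 1.0
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), k - 1, float(res.p_value)


def survival_separation(
    labels: np.ndarray,
    records: Sequence[SurvivalRecord],
    horizon_days: float = DEFAULT_HORIZON_DAYS,
) -> dict:
    """Censor, drop singleton clusters, fit per-cluster KM, log-rank test."""
    censored = apply_censoring(records, horizon_days)
    labels_kept, records_kept = drop_singleton_clusters(np.asarray(labels), censored)
    curves = {
        int(c): km_estimate([r for r, g in zip(records_kept, labels_kept) if g == c])
        for c in np.unique(labels_kept)
    }
    chi2, df, p = logrank_test(records_kept, labels_kept)
    return {"curves": curves, "chi2": chi2, "df": df, "p_value": p,
            "n_used": len(records_kept)}


def discretize(m: OmicsMatrix) -> dict[str, np.ndarray]:
    """Per-direction binary alteration indicators from raw-scale values.

    Requires the un-normalized matrix (GISTIC-style values for CNA,
    z-scores for expression, beta-values for methylation); methylation
    values outside [0, 1] are rejected.
    """
    if m.normalized and m.data_type != "mutation":
        raise ValueError(
            f"discretize needs raw-scale {m.data_type} values, got a normalized matrix"
        )
    if m.data_type == "methylation" and m.values.size:
        if m.values.min() < 0 or m.values.max() > 1:
            raise ValueError("methylation beta-values must lie in [0, 1]")
    rules = _DISCRETIZE_RULES[m.data_type]
    out = {}
    for direction, (op, cut) in rules.items():
        out[direction] = m.values >= cut if op == "ge" else m.values <= cut
    return out


def hypergeom_enrich(
    indicator: np.ndarray, labels: np.ndarray, cluster: int
) -> float:
    """Upper-tail hypergeometric p-value for alteration enrichment.

    P(X >= x) of drawing x altered patients in a cluster of size n from a
    cohort of N with K altered overall.
    """
    indicator = np.asarray(indicator, dtype=bool)
    labels = np.asarray(labels)
    in_cluster = labels == cluster
    n = int(in_cluster.sum())
    if n == 0:
        raise ValueError(f"cluster {cluster} is empty")
    total = len(labels)
    k_total = int(indicator.sum())
    x = int(indicator[in_cluster].sum())
    return float(hypergeom.sf(x - 1, total, k_total, n))


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p elementwise)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def representativeness_filter(
    indicator: np.ndarray, labels: np.ndarray, cluster: int
) -> bool:
    """Altered in >= 2/3 of the cluster and < 1/3 of at least one other."""
    indicator = np.asarray(indicator, dtype=bool)
    labels = np.asarray(labels)
    others = [c for c in np.unique(labels) if c != cluster]
    if not others:
        raise ValueError("representativeness filter needs at least 2 clusters")
    frac_in = indicator[labels == cluster].mean()
    if frac_in < 2.0 / 3.0:
        return False
    return any(indicator[labels == c].mean() < 1.0 / 3.0 for c in others)


def cluster_fractions(
    indicator: np.ndarray, labels: np.ndarray, cluster: int
) -> tuple[float, float]:
    """(in-cluster altered fraction, minimum altered fraction elsewhere)."""
    indicator = np.asarray(indicator, dtype=bool)
    labels = np.asarray(labels)
    frac_in = float(indicator[labels == cluster].mean())
    others = [c for c in np.unique(labels) if c != cluster]
    min_out = min(float(indicator[labels == c].mean()) for c in others) if others else 1.0
    return frac_in, min_out


def enrichment_table(
    raw_matrices: Sequence[OmicsMatrix],
    labels: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (cluster, gene, direction) enrichment across all data types.

    One BH family per (cluster, data type, direction) across genes.  The
    ``significant`` column applies q < alpha, plus the representativeness
    filter for non-mutation data types.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    rows = []
    for m in raw_matrices:
        indicators = discretize(m)
        for direction, ind in indicators.items():
            for cluster in clusters:
                p_raw = np.array(
                    [hypergeom_enrich(ind[:, g], labels, cluster) for g in range(m.n_features)]
                )
                q = fdr_adjust(p_raw)
                for g, gene in enumerate(m.feature_ids):
                    frac_in, min_out = cluster_fractions(ind[:, g], labels, cluster)
                    passes = (
                        True
                        if m.data_type == "mutation"
                        else representativeness_filter(ind[:, g], labels, cluster)
                    )
                    rows.append(
                        {
                            "cluster": int(cluster),
                            "gene": gene,
                            "data_type": m.data_type,
                            "direction": direction,
                            "p_raw": p_raw[g],
                            "q_fdr": q[g],
                            "frac_in": frac_in,
                            "min_frac_out": min_out,
                            "passes_representativeness": passes,
                            "significant": bool(q[g] < alpha and passes),
                        }
                    )
    return pd.DataFrame(rows)
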