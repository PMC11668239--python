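"""Group-comparison statistics.

The reporting layer over per-fly summaries: Kruskal-Wallis omnibus with
rank-sum (Mann-Whitney) post hoc tests under Holm-Bonferroni correction,
Fisher's exact test for incidence fractions, log-rank survival comparison
with Kaplan-Meier medians, and the 5/25/50/75/95-percentile box summaries
used for figures.  The post hoc family is the declared list of pairs, not
automatically all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

__all__ = [
    "GroupedMeasurements", "PairwiseResult", "ComparisonReport",
    "kruskal_wallis_posthoc", "holm_bonferroni", "fisher_exact",
    "logrank_test", "LogrankResult", "box_stats", "significance_stars",
]


def significance_stars(p: float) -> str:
    """Figure-caption convention: * p<=0.05, ** p<=0.01, *** p<=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class GroupedMeasurements:
    """One metric, one vector of per-fly values per group."""

    values: Dict[str, np.ndarray]
    metric: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = {g: np.asarray(v, float) for g, v in self.values.items()}
        if len(self.values) < 2:
            raise ValueError("comparisons need >= 2 groups")
        for g, v in self.values.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"group {g!r} contains non-finite values")


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    stars: str

    def __post_init__(self) -> None:
        if self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot fall below raw p")


@dataclass
class ComparisonReport:
    metric: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: List[PairwiseResult]


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment, order-preserving.

    Sort ascending, multiply the i-th smallest by ``m - i``, enforce a running
    maximum, cap at 1 and restore the input order.  Never decreases a p value
    and preserves the significance ordering.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[i]))
        adj[i] = running
    return adj


def _rank_sum(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Two-sided rank-sum p: exact for combined n <= 20 without ties,
    normal approximation with tie/continuity correction otherwise."""
    exact = (len(x) + len(y) <= 20
             and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y))
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis_posthoc(
    data: GroupedMeasurements,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
) -> ComparisonReport:
    """Omnibus Kruskal-Wallis (tie-corrected H) plus Holm-adjusted rank-sum
    post hoc tests over the requested comparison family.

    ``pairs`` defaults to all group pairs; a declared family (e.g.
    overexpression vs matched control) should be passed explicitly.
    """
    for g, v in data.values.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    groups = list(data.values)
    H, p_omni = sps.kruskal(*[data.values[g] for g in groups])
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    for a, b in pairs:
        if a not in data.values or b not in data.values:
            raise KeyError(f"unknown group in pair ({a!r}, {b!r})")
    stats_p = [_rank_sum(data.values[a], data.values[b]) for a, b in pairs]
    raw = [p for _, p in stats_p]
    adj = holm_bonferroni(raw)
    pairwise = [
        PairwiseResult(a, b, s, p, float(q), significance_stars(float(q)))
        for (a, b), (s, p), q in zip(pairs, stats_p, adj)
    ]
    return ComparisonReport(data.metric, float(H), float(p_omni), pairwise)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Exact hypergeometric two-sided p: the sum of the probabilities of all
    tables (with the observed margins) no more probable than the observed
    one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return float(p)


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p: float
    median_a: Optional[float]  # None when survival never drops below 0.5
    median_b: Optional[float]


def logrank_test(
    durations_a: Sequence[float],
    events_a: Sequence[int],
    durations_b: Sequence[float],
    events_b: Sequence[int],
) -> LogrankResult:
    """Standard two-group log-rank chi-square (1 df) with KM medians."""
    da, ea = np.asarray(durations_a, float), np.asarray(events_a, int)
    db, eb = np.asarray(durations_b, float), np.asarray(events_b, int)
    if len(da) == 0 or len(db) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank undefined: all observations censored")
    res = _ll_logrank(da, db, event_observed_A=ea, event_observed_B=eb)

    def km_median(d, e) -> Optional[float]:
        km = KaplanMeierFitter().fit(d, e)
        med = km.median_survival_time_
        return None if np.isinf(med) else float(med)

    return LogrankResult(float(res.test_statistic), float(res.p_value),
                         km_median(da, ea), km_median(db, eb))


def box_stats(values: Sequence[float]) -> Dict[str, float]:
    """5th/25th/50th/75th/95th percentiles, linear interpolation (inclusive)."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("empty vector")
    q = np.percentile(v, [5, 25, 50, 75, 95], method="linear")
    return {"p5": float(q[0]), "p25": float(q[1]), "p50": float(q[2]),
            "p75": float(q[3]), "p95": float(q[4])}
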