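"""Survival and contingency statistics for cluster-wise outcome comparison.

Kaplan–Meier product-limit estimation, the k-sample log-rank test with the
standard hypergeometric (tie-corrected) variance, and Fisher's exact test
(2x2 hypergeometric tail; 2xk Freeman–Halton enumeration) are implemented
directly on top of numpy/scipy primitives.  Conventions:

* censoring at an event time is processed after the event (the censored
  subject is still at risk for that event);
* the two-sided Fisher p sums tables whose exact probability does not
  exceed the observed table's (probability-mass ordering), decided on exact
  integer hypergeometric weights so borderline tables are handled without
  floating-point tolerance;
* no continuity correction in the log-rank statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from math import comb
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .clustering import ClusterAssignment
    from .io import OutcomeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "ClusterOutcomeReport",
    "km_estimate",
    "logrank_test",
    "fisher_exact",
    "compare_clusters",
]


@dataclass
class SurvivalCurve:
    """Kaplan–Meier product-limit estimate at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.at_risk = np.asarray(self.at_risk, dtype=int)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if self.survival.size and (
            self.survival[0] > 1 + 1e-12 or self.survival[-1] < -1e-12
        ):
            raise ValueError("survival must lie in [0, 1]")

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
            }
        )


@dataclass
class LogRankResult:
    """Chi-square statistic, degrees of freedom and p of a log-rank test."""

    statistic: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.statistic < -1e-9:
            raise ValueError("negative log-rank statistic")


def _clean_times(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0) or np.any(~np.isfinite(times)):
        raise ValueError("times must be finite and nonnegative")
    return times, events


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan–Meier estimator.

    ``events`` is True for an observed event, False for censoring.  Censored
    observations only shrink the risk set; a censoring tied to an event time
    counts as at risk for that event.
    """
    times, events = _clean_times(times, events)
    n = times.size
    event_times = np.unique(times[events])
    survival = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        r = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / r
        survival[i] = s
        at_risk[i] = r
    return SurvivalCurve(event_times, survival, at_risk, n_total=n)


def logrank_test(groups: Sequence[tuple]) -> LogRankResult:
    """k-sample log-rank test.

    ``groups`` is a list of ``(times, events)`` pairs.  The statistic uses
    the hypergeometric variance (tie-corrected) at each distinct event time
    and is referred to a chi-square distribution with k-1 degrees of
    freedom.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    cleaned = [_clean_times(t, e) for t, e in groups]
    k = len(cleaned)
    all_times = np.concatenate([t for t, _ in cleaned])
    all_events = np.concatenate([e for _, e in cleaned])
    if not all_events.any():
        raise ValueError("no events in any group")
    event_times = np.unique(all_times[all_events])
    observed = np.zeros(k)
    expected = np.zeros(k)
    # covariance of the first k-1 group event counts
    cov = np.zeros((k - 1, k - 1))
    for t in event_times:
        n_at_risk = np.array([np.sum(times >= t) for times, _ in cleaned], dtype=float)
        d_g = np.array(
            [np.sum((times == t) & events) for times, events in cleaned],
            dtype=float,
        )
        n_tot = n_at_risk.sum()
        d_tot = d_g.sum()
        if n_tot == 0 or d_tot == 0:
            continue
        observed += d_g
        expected += d_tot * n_at_risk / n_tot
        if n_tot > 1:
            # hypergeometric variance: V_ij = d(n-d)/(n-1) * p_i (delta_ij - p_j)
            factor = d_tot * (n_tot - d_tot) / (n_tot - 1)
            p_g = n_at_risk / n_tot
            for i in range(k - 1):
                for j in range(k - 1):
                    delta = 1.0 if i == j else 0.0
                    cov[i, j] += factor * p_g[i] * (delta - p_g[j])
    z = (observed - expected)[: k - 1]
    try:
        statistic = float(z @ np.linalg.solve(cov, z))
    except np.linalg.LinAlgError:
        statistic = float(z @ np.linalg.pinv(cov) @ z)
    statistic = max(statistic, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(statistic, df))
    return LogRankResult(statistic=statistic, df=df, p=max(p, np.finfo(float).tiny))


def _fisher_2x2(table: np.ndarray) -> float:
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, r2 = a + b, c + d
    m = a + c  # first-column margin
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, m - r2), min(r1, m)
    # exact integer hypergeometric weights: P(x) = w_x / C(n, m)
    weights = [comb(r1, x) * comb(r2, m - x) for x in range(lo, hi + 1)]
    observed = weights[a - lo]
    total = sum(weights)
    tail = sum(w for w in weights if w <= observed)
    return tail / total


def _fisher_2xk(table: np.ndarray) -> float:
    """Freeman–Halton exact test for a 2 x k table via full enumeration."""
    r1 = int(table[0].sum())
    col = table.sum(axis=0).astype(int)
    k = table.shape[1]
    obs_weight = 1
    for j in range(k):
        obs_weight *= comb(col[j], int(table[0, j]))
    total = 0
    tail = 0
    ranges = [range(min(r1, col[j]) + 1) for j in range(k - 1)]
    for head in product(*ranges):
        s = sum(head)
        if s > r1:
            continue
        last = r1 - s
        if last > col[k - 1]:
            continue
        w = comb(col[k - 1], last)
        for j, a in enumerate(head):
            w *= comb(col[j], a)
        total += w
        if w <= obs_weight:
            tail += w
    return tail / total


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 or 2xk (k <= 4) count table.

    Accepts any r x c layout with min(r, c) <= 2; the table is oriented so
    the smaller dimension indexes the rows.  Two-sidedness follows the
    probability-mass ordering: the p-value sums all tables with the observed
    margins whose exact probability does not exceed the observed table's.
    """
    table = np.asarray(table)
    if table.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(table < 0):
        raise ValueError("negative count in contingency table")
    if not np.all(table == np.floor(table)):
        raise ValueError("counts must be integers")
    table = table.astype(int)
    if min(table.shape) > 2:
        raise ValueError("only 2xk tables are supported")
    if table.shape[0] != 2:
        table = table.T
    if table.shape[1] > 4:
        raise ValueError("Freeman-Halton enumeration supports k <= 4 columns")
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    if table.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    # empty columns contribute nothing to the enumeration
    table = table[:, table.sum(axis=0) > 0]
    # a zero row margin (or a single remaining column) admits a single table
    if (table.sum(axis=1) == 0).any() or table.shape[1] < 2:
        return 1.0
    if table.shape[1] == 2:
        return _fisher_2x2(table)
    return _fisher_2xk(table)


@dataclass
class ClusterOutcomeReport:
    """Cluster-wise MRD and survival comparison."""

    mrd_table: pd.DataFrame  # clusters x (positive, negative)
    mrd_overall_p: float | None
    mrd_cluster1_vs_rest_p: float | None
    mrd_pairwise_p: dict[tuple[int, int], float]
    km_curves: dict[str, dict[int, SurvivalCurve]]  # endpoint -> cluster -> curve
    logrank_omnibus: dict[str, LogRankResult]
    logrank_pairwise: dict[str, dict[tuple[int, int], float]]
    n_excluded: dict[str, int]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        if self.mrd_overall_p is not None:
            rows.append({"test": "mrd_fisher_overall", "p": self.mrd_overall_p})
        if self.mrd_cluster1_vs_rest_p is not None:
            rows.append(
                {"test": "mrd_fisher_cluster1_vs_rest",
                 "p": self.mrd_cluster1_vs_rest_p}
            )
        for (a, b), p in sorted(self.mrd_pairwise_p.items()):
            rows.append({"test": f"mrd_fisher_cluster{a}_vs_cluster{b}", "p": p})
        for endpoint, res in self.logrank_omnibus.items():
            rows.append(
                {"test": f"logrank_omnibus_{endpoint}", "p": res.p,
                 "statistic": res.statistic, "df": res.df}
            )
        for endpoint, pairs in self.logrank_pairwise.items():
            for (a, b), p in sorted(pairs.items()):
                rows.append(
                    {"test": f"logrank_{endpoint}_cluster{a}_vs_cluster{b}", "p": p}
                )
        return pd.DataFrame(rows)


def compare_clusters(
    assignment: "ClusterAssignment",
    outcomes: Sequence["OutcomeRecord"] | Mapping[str, "OutcomeRecord"],
) -> ClusterOutcomeReport:
    """MRD day-29 Fisher tests plus KM / log-rank survival comparison across
    the marker clusters.

    ``outcomes`` is either a mapping sample_id -> record or a list aligned
    with ``assignment.sample_ids``.  Samples missing an outcome are dropped
    from that analysis (counts logged and reported).
    """
    sample_ids = assignment.sample_ids
    if isinstance(outcomes, Mapping):
        records = {s: outcomes.get(s) for s in sample_ids}
    else:
        if len(outcomes) != len(sample_ids):
            raise ValueError("outcomes list does not align with assignment")
        records = dict(zip(sample_ids, outcomes))
    clusters = assignment.clusters
    present = sorted(
        c
        for c in clusters.unique()
        if any(records[s] is not None for s in sample_ids if clusters[s] == c)
    )
    if len(present) < 2:
        raise ValueError("need outcome data in >= 2 clusters")

    n_excluded: dict[str, int] = {}

    # MRD 29 contingency table (clusters x positive/negative)
    mrd_counts = {}
    excluded = 0
    for c in present:
        pos = neg = 0
        for s in sample_ids:
            if clusters[s] != c:
                continue
            rec = records[s]
            if rec is None or rec.mrd29_positive is None:
                excluded += 1
                continue
            if rec.mrd29_positive:
                pos += 1
            else:
                neg += 1
        mrd_counts[c] = {"positive": pos, "negative": neg}
    n_excluded["mrd29"] = excluded
    mrd_table = pd.DataFrame(mrd_counts).T
    have_mrd = int(mrd_table.to_numpy().sum()) > 0
    mrd_overall_p = fisher_exact(mrd_table.to_numpy()) if have_mrd else None

    mrd_c1_vs_rest_p = None
    mrd_pairwise: dict[tuple[int, int], float] = {}
    if have_mrd and 1 in mrd_table.index:
        rest = mrd_table.drop(index=1).sum(axis=0)
        mrd_c1_vs_rest_p = fisher_exact(
            np.array([mrd_table.loc[1].to_numpy(), rest.to_numpy()])
        )
        for c in mrd_table.index:
            if c == 1:
                continue
            mrd_pairwise[(1, int(c))] = fisher_exact(
                mrd_table.loc[[1, c]].to_numpy()
            )

    # survival endpoints
    km_curves: dict[str, dict[int, SurvivalCurve]] = {}
    logrank_omnibus: dict[str, LogRankResult] = {}
    logrank_pairwise: dict[str, dict[tuple[int, int], float]] = {}
    for endpoint in ("efs", "os"):
        per_cluster: dict[int, tuple[list, list]] = {c: ([], []) for c in present}
        excluded = 0
        for s in sample_ids:
            rec = records[s]
            c = clusters[s]
            if c not in per_cluster:
                continue
            t = getattr(rec, f"{endpoint}_time", None) if rec else None
            e = getattr(rec, f"{endpoint}_event", None) if rec else None
            if t is None or e is None:
                excluded += 1
                continue
            per_cluster[c][0].append(t)
            per_cluster[c][1].append(e)
        n_excluded[endpoint] = excluded
        usable = {c: te for c, te in per_cluster.items() if len(te[0]) > 0}
        if len(usable) < 2 or not any(any(e) for _, e in usable.values()):
            logger.info("endpoint %s: insufficient data for log-rank", endpoint)
            continue
        km_curves[endpoint] = {c: km_estimate(t, e) for c, (t, e) in usable.items()}
        logrank_omnibus[endpoint] = logrank_test(list(usable.values()))
        pair_p: dict[tuple[int, int], float] = {}
        keys = sorted(usable)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                if not (any(usable[a][1]) or any(usable[b][1])):
                    continue
                pair_p[(a, b)] = logrank_test([usable[a], usable[b]]).p
        logrank_pairwise[endpoint] = pair_p

    for key, count in n_excluded.items():
        if count:
            logger.info("%s: excluded %d samples without outcome data", key, count)

    return ClusterOutcomeReport(
        mrd_table=mrd_table,
        mrd_overall_p=mrd_overall_p,
        mrd_cluster1_vs_rest_p=mrd_c1_vs_rest_p,
        mrd_pairwise_p=mrd_pairwise,
        km_curves=km_curves,
        logrank_omnibus=logrank_omnibus,
        logrank_pairwise=logrank_pairwise,
        n_excluded=n_excluded,
    )
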