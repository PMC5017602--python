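"""Quartile binning of marker expression and the four-cluster rule on
IGHM / IGLL1 / VPREB1 positivity.

The clusters encode pre-B-cell-receptor component expression patterns:

* Cluster 1 — IGHM+ IGLL1+ VPREB1+ (all three high)
* Cluster 2 — IGHM+ but not Cluster 1
* Cluster 3 — IGHM- with IGLL1 and/or VPREB1 high
* Cluster 4 — IGHM- IGLL1- VPREB1- (all three low)

These four rules are mutually exclusive and exhaustive over the 8 possible
positivity patterns, so every cohort is partitioned.  The numeric threshold
behind a +/- call is configurable: per-marker median split (default, strict
``>``), top-half quartiles, or a fixed threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .io import ExpressionMatrix

__all__ = [
    "DEFAULT_MARKERS",
    "PositivityTable",
    "ClusterAssignment",
    "quartile_bins",
    "call_positivity",
    "assign_clusters",
]

DEFAULT_MARKERS = ("IGHM", "IGLL1", "VPREB1")


@dataclass
class PositivityTable:
    """Per-sample boolean positivity calls for a set of markers."""

    calls: pd.DataFrame  # samples x markers, bool
    thresholds: dict[str, float]
    method: str

    def __post_init__(self) -> None:
        if self.calls.isna().any().any():
            raise ValueError("positivity table contains missing calls")
        missing = [m for m in self.calls.columns if m not in self.thresholds]
        if missing:
            raise ValueError(f"no threshold recorded for markers {missing}")


@dataclass
class ClusterAssignment:
    """Cluster 1-4 label per sample plus the positivity pattern behind it."""

    table: pd.DataFrame  # columns: the three markers (bool) + "cluster" (int)
    method: str = ""
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "cluster" not in self.table.columns:
            raise ValueError("assignment table needs a 'cluster' column")
        if not self.table["cluster"].isin([1, 2, 3, 4]).all():
            raise ValueError("cluster labels must be in {1, 2, 3, 4}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def clusters(self) -> pd.Series:
        return self.table["cluster"]

    @classmethod
    def from_patterns(
        cls, patterns: dict[str, tuple[bool, bool, bool]], method: str = "manual"
    ) -> "ClusterAssignment":
        """Build an assignment directly from (IGHM, IGLL1, VPREB1) patterns."""
        rows = {
            sid: dict(zip(DEFAULT_MARKERS, map(bool, pat)))
            for sid, pat in patterns.items()
        }
        table = pd.DataFrame.from_dict(rows, orient="index")
        table["cluster"] = [
            cluster_of_pattern(tuple(table.loc[s, list(DEFAULT_MARKERS)]))
            for s in table.index
        ]
        return cls(table=table, method=method)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["method"] = self.method
        for marker, thr in self.thresholds.items():
            out[f"{marker}_threshold"] = thr
        return out


def quartile_bins(matrix: "ExpressionMatrix", marker: str) -> pd.Series:
    """Quartile index (1 = lowest .. 4 = highest) of each sample for one
    marker gene.

    Samples are sorted by marker expression (ties broken by sample id) and
    split into four bins whose sizes differ by at most one; when the cohort
    size is not divisible by four, the larger bins sit at the low end.
    """
    if marker not in matrix.data.index:
        raise KeyError(f"marker {marker!r} not in matrix")
    values = matrix.data.loc[marker]
    n = len(values)
    if n < 4:
        raise ValueError(f"need >= 4 samples for quartiles, got {n}")
    order = sorted(values.index, key=lambda s: (values[s], s))
    base, extra = divmod(n, 4)
    sizes = [base + (1 if i < extra else 0) for i in range(4)]
    bins = pd.Series(0, index=values.index, dtype=int, name=marker)
    start = 0
    for q, size in enumerate(sizes, start=1):
        for s in order[start:start + size]:
            bins[s] = q
        start += size
    return bins


def call_positivity(
    matrix: "ExpressionMatrix",
    markers: Sequence[str] = DEFAULT_MARKERS,
    method: str = "median",
) -> PositivityTable:
    """Binarise marker expression into +/- calls.

    ``method`` is ``"median"`` (positive iff strictly above the cohort
    median), ``"top_half_quartiles"`` (positive iff quartile index >= 3) or
    ``"threshold:<x>"`` (positive iff strictly above the fixed value x).
    """
    missing = [m for m in markers if m not in matrix.data.index]
    if missing:
        raise KeyError(f"markers not in matrix: {missing}")
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to call positivity")
    calls = {}
    thresholds = {}
    for marker in markers:
        values = matrix.data.loc[marker]
        if method == "median":
            thr = float(values.median())
            calls[marker] = values > thr
        elif method == "top_half_quartiles":
            bins = quartile_bins(matrix, marker)
            thr = float(values[bins == 3].min()) if (bins == 3).any() else float("nan")
            calls[marker] = bins >= 3
        elif method.startswith("threshold:"):
            thr = float(method.split(":", 1)[1])
            calls[marker] = values > thr
        else:
            raise ValueError(f"unknown positivity method {method!r}")
        thresholds[marker] = thr
    table = pd.DataFrame(calls, index=matrix.sample_ids).astype(bool)
    return PositivityTable(calls=table, thresholds=thresholds, method=method)


def cluster_of_pattern(pattern: Sequence[bool]) -> int:
    """Map one (IGHM, IGLL1, VPREB1) positivity pattern to Cluster 1-4."""
    ighm, igll1, vpreb1 = (bool(x) for x in pattern)
    if ighm and igll1 and vpreb1:
        return 1
    if ighm:
        return 2
    if igll1 or vpreb1:
        return 3
    return 4


def assign_clusters(positivity: PositivityTable) -> ClusterAssignment:
    """Apply the four-cluster rule to a positivity table.

    The table must contain calls for exactly IGHM, IGLL1 and VPREB1.
    """
    markers = list(positivity.calls.columns)
    if sorted(markers) != sorted(DEFAULT_MARKERS):
        raise ValueError(
            f"cluster rule needs exactly markers {DEFAULT_MARKERS}, got {markers}"
        )
    calls = positivity.calls[list(DEFAULT_MARKERS)]
    table = calls.copy()
    table["cluster"] = [
        cluster_of_pattern(tuple(calls.loc[s])) for s in calls.index
    ]
    return ClusterAssignment(
        table=table, method=positivity.method, thresholds=positivity.thresholds
    )
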