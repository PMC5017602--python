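"""Supervised derivation of "highly expressed" gene signatures.

A signature for a target group (developmental stage, leukemia subtype or
marker-defined cluster) is the top-N genes of a one-vs-rest ranking.  The
default ranking statistic is the Welch two-sample t (target minus rest,
unequal variances); a signal-to-noise ratio is available as an alternative.
Only up-regulated genes (positive statistic) enter a signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .io import ExpressionMatrix, SampleAnnotation

__all__ = [
    "RankedList",
    "GeneSignature",
    "rank_genes",
    "derive_signature",
    "derive_all_group_signatures",
    "write_rnk",
]


@dataclass
class RankedList:
    """Genes ordered by a descending two-group ranking statistic."""

    gene_ids: list[str]
    statistic: np.ndarray
    target_group: str = ""

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=float)
        if len(self.gene_ids) != len(self.statistic):
            raise ValueError("gene_ids and statistic length mismatch")
        # allow equal neighbours (ties), forbid increases
        if np.any(np.diff(self.statistic) > 1e-12):
            raise ValueError("statistic must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GeneSignature:
    """A named, ordered gene list derived for one group."""

    name: str
    genes: list[str]
    source_group: str = ""
    n_requested: int = 0

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")
        if self.n_requested and len(self.genes) > self.n_requested:
            raise ValueError(
                f"signature {self.name!r} has more genes than requested"
            )

    def __len__(self) -> int:
        return len(self.genes)


def welch_t(
    values: np.ndarray, target_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-row Welch t statistic for target-vs-rest.

    Returns ``(t, mean_difference)``.  Rows with zero variance in both groups
    get t = 0 when the means are equal, +/-inf otherwise.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    a = values[:, target_mask]
    b = values[:, ~target_mask]
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 samples")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    diff = m1 - m2
    se = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_se = se == 0
    t[zero_se & (diff == 0)] = 0.0
    t[zero_se & (diff > 0)] = np.inf
    t[zero_se & (diff < 0)] = -np.inf
    return t, diff


def signal_to_noise(
    values: np.ndarray, target_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row signal-to-noise ratio (mean difference over summed SDs)."""
    target_mask = np.asarray(target_mask, dtype=bool)
    a = values[:, target_mask]
    b = values[:, ~target_mask]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both groups need >= 2 samples")
    diff = a.mean(axis=1) - b.mean(axis=1)
    denom = a.std(axis=1, ddof=1) + b.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = diff / denom
    zero = denom == 0
    s[zero & (diff == 0)] = 0.0
    s[zero & (diff > 0)] = np.inf
    s[zero & (diff < 0)] = -np.inf
    return s, diff


_STATISTICS = {"welch_t": welch_t, "snr": signal_to_noise}


def rank_genes(
    matrix: "ExpressionMatrix",
    annotations: Sequence["SampleAnnotation"],
    target_group: str,
    statistic: str = "welch_t",
) -> RankedList:
    """Rank all genes by a one-vs-rest statistic for ``target_group``.

    Ties are broken by larger mean difference, then lexicographic gene id,
    so the ranking is fully deterministic.
    """
    groups = {ann.sample_id: ann.group for ann in annotations}
    missing = [s for s in matrix.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")
    mask = np.array([groups[s] == target_group for s in matrix.sample_ids])
    if mask.sum() < 2:
        raise ValueError(
            f"target group {target_group!r} has {int(mask.sum())} samples (need >= 2)"
        )
    if (~mask).sum() < 2:
        raise ValueError(
            f"complement of {target_group!r} has {int((~mask).sum())} samples "
            "(need >= 2)"
        )
    try:
        stat_fn = _STATISTICS[statistic]
    except KeyError:
        raise ValueError(f"unknown statistic {statistic!r}") from None
    t, diff = stat_fn(matrix.values, mask)
    gene_arr = np.asarray(matrix.gene_ids, dtype=object)
    # np.lexsort: last key is primary
    order = np.lexsort((gene_arr.astype(str), -diff, -t))
    return RankedList(
        gene_ids=[matrix.gene_ids[i] for i in order],
        statistic=t[order],
        target_group=target_group,
    )


def derive_signature(
    ranked: RankedList,
    n: int = 400,
    name: str | None = None,
    source_group: str | None = None,
) -> GeneSignature:
    """Take the top ``n`` up-regulated genes (statistic > 0) of a ranking.

    May return fewer than ``n`` genes (with a warning) when the ranking has
    fewer positive statistics.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    positive = int(np.sum(ranked.statistic > 0))
    k = min(n, positive)
    if k < n:
        warnings.warn(
            f"only {k} genes with positive statistic available "
            f"(requested {n})",
            stacklevel=2,
        )
    group = source_group if source_group is not None else ranked.target_group
    return GeneSignature(
        name=name if name is not None else group,
        genes=ranked.gene_ids[:k],
        source_group=group,
        n_requested=n,
    )


def derive_all_group_signatures(
    matrix: "ExpressionMatrix",
    annotations: Sequence["SampleAnnotation"],
    n: int = 400,
    statistic: str = "welch_t",
) -> list[GeneSignature]:
    """One top-``n`` signature per distinct group label, in order of first
    appearance in the annotations."""
    labels = list(dict.fromkeys(ann.group for ann in annotations))
    if len(labels) < 2:
        raise ValueError("need >= 2 distinct groups to derive signatures")
    return [
        derive_signature(rank_genes(matrix, annotations, g, statistic), n=n)
        for g in labels
    ]


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    """Export a ranked list as a two-column .rnk-style TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene, stat in zip(ranked.gene_ids, ranked.statistic):
            fh.write(f"{gene}\t{stat:.10g}\n")
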