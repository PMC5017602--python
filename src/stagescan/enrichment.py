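"""Rank-based gene-set enrichment with a permutation null.

The enrichment score (ES) is the classic weighted Kolmogorov–Smirnov running
sum: walking a ranked gene list, the sum rises at gene-set members and falls
at non-members; the ES is the running-sum value of maximal absolute
deviation.  With the default ``weight=0`` every member contributes an equal
step ``1/|S|`` and every non-member ``-1/(N-|S|)``, so the walk ends exactly
at zero.

The null distribution is obtained either by phenotype permutation (shuffle
group labels, re-rank, re-score) or, when the contrast is too small, by
scoring random gene sets of the same size on the fixed ranking.  The
normalised enrichment score (NES) divides the observed ES by the mean
absolute null ES of the same sign, and the permutation p-value counts
same-sign null scores at least as extreme (add-one rule for sampled nulls;
plain ratio for an exhaustively enumerated null, which already contains the
observed relabelling).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .signatures import GeneSignature, RankedList, rank_genes, welch_t

if TYPE_CHECKING:  # pragma: no cover
    from .io import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "enrichment_score",
    "permutation_null",
    "nes_and_p",
    "gsea",
]


@dataclass
class EnrichmentResult:
    """ES, NES, permutation p and leading edge for one (set, contrast) pair."""

    signature_name: str
    contrast: str
    es: float
    nes: float
    p_perm: float
    n_permutations: int
    leading_edge: list[str]
    running_sum: np.ndarray
    null_mode: str = "phenotype"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.es <= 1.0 + 1e-9:
            raise ValueError(f"ES out of [-1, 1]: {self.es}")
        if self.n_permutations > 0 and not (
            0.0 < self.p_perm <= 1.0 + 1e-12
        ):
            raise ValueError(f"invalid permutation p: {self.p_perm}")


def _membership(ranked_genes: Sequence[str], gene_set: GeneSignature) -> np.ndarray:
    members = set(gene_set.genes)
    hit = np.fromiter((g in members for g in ranked_genes), dtype=bool,
                      count=len(ranked_genes))
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError(
            f"no overlap between gene set {gene_set.name!r} and the ranked "
            "gene universe"
        )
    if nh == len(ranked_genes):
        raise ValueError(
            f"gene set {gene_set.name!r} covers the entire gene universe"
        )
    return hit


def _walk(hit: np.ndarray, weights: np.ndarray | None) -> np.ndarray:
    """Running sum over one ranked list given a membership indicator."""
    n = hit.size
    nh = int(hit.sum())
    steps = np.full(n, -1.0 / (n - nh))
    if weights is None:
        steps[hit] = 1.0 / nh
    else:
        w = weights[hit]
        total = w.sum()
        if total == 0:  # all member statistics zero: fall back to equal steps
            steps[hit] = 1.0 / nh
        else:
            steps[hit] = w / total
    return np.cumsum(steps)


def _es_from_running(running: np.ndarray) -> tuple[float, int]:
    # first index attaining the maximal |deviation|, with a small tolerance
    # so cumsum rounding cannot break exact ties between +/- extrema
    dev = np.abs(running)
    idx = int(np.argmax(dev >= dev.max() - 1e-12))
    return float(running[idx]), idx


def enrichment_score(
    ranked: RankedList,
    gene_set: GeneSignature,
    weight: float = 0,
) -> tuple[float, np.ndarray, list[str]]:
    """Score one gene set against one ranked list.

    Returns ``(es, running_sum, leading_edge)``.  The leading edge contains
    the set members at or before the running-sum extremum (at or after it for
    a negative ES), in rank order.

    When the largest positive and largest negative deviations tie in
    magnitude (possible for the unweighted walk, e.g. a set occupying both
    ends of the list symmetrically) the first extremum along the list is
    taken.  For such self-symmetric walks reversing the ranking preserves
    |ES| but no deterministic convention can also flip its sign.
    """
    hit = _membership(ranked.gene_ids, gene_set)
    weights = None if weight == 0 else np.abs(ranked.statistic) ** weight
    running = _walk(hit, weights)
    es, idx = _es_from_running(running)
    if es >= 0:
        edge_mask = hit & (np.arange(hit.size) <= idx)
    else:
        edge_mask = hit & (np.arange(hit.size) >= idx)
    leading_edge = [g for g, m in zip(ranked.gene_ids, edge_mask) if m]
    return es, running, leading_edge


def _null_orders_phenotype(
    values: np.ndarray,
    target_mask: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    exhaustive: bool,
) -> np.ndarray:
    """Rankings (argsort orders, columns = permutations) under label shuffles."""
    n = target_mask.size
    k = int(target_mask.sum())
    if exhaustive:
        masks = np.zeros((math.comb(n, k), n), dtype=bool)
        for i, combo in enumerate(combinations(range(n), k)):
            masks[i, list(combo)] = True
    else:
        masks = np.zeros((n_perm, n), dtype=bool)
        for i in range(n_perm):
            masks[i, rng.permutation(n)[:k]] = True
    t = _welch_t_batch(values, masks)
    # stable descending sort per permutation; tie order is positional
    return np.argsort(-t, axis=0, kind="stable")


def _welch_t_batch(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Welch t for many target masks at once.  Returns genes x permutations."""
    masks_f = masks.T.astype(float)  # n x p
    n = values.shape[1]
    n1 = masks_f.sum(axis=0)
    n2 = n - n1
    s1 = values @ masks_f
    q1 = (values**2) @ masks_f
    s_tot = values.sum(axis=1, keepdims=True)
    q_tot = (values**2).sum(axis=1, keepdims=True)
    m1 = s1 / n1
    m2 = (s_tot - s1) / n2
    v1 = (q1 - s1**2 / n1) / (n1 - 1)
    v2 = ((q_tot - q1) - (s_tot - s1) ** 2 / n2) / (n2 - 1)
    np.clip(v1, 0, None, out=v1)  # guard tiny negative rounding
    np.clip(v2, 0, None, out=v2)
    se = np.sqrt(v1 / n1 + v2 / n2)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero = se == 0
    t[zero & (diff == 0)] = 0.0
    t[zero & (diff > 0)] = np.inf
    t[zero & (diff < 0)] = -np.inf
    return t


def _es_batch(orders: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Weight-0 ES for one membership vector across many rankings.

    ``orders``: genes x permutations argsort indices; ``member``: bool per
    gene (original index).
    """
    hits = member[orders]  # genes x perms
    n = member.size
    nh = int(member.sum())
    steps = np.where(hits, 1.0 / nh, -1.0 / (n - nh))
    running = np.cumsum(steps, axis=0)
    dev = np.abs(running)
    idx = np.argmax(dev >= dev.max(axis=0) - 1e-12, axis=0)
    return running[idx, np.arange(running.shape[1])]


def permutation_null(
    matrix: "ExpressionMatrix",
    annotations: Sequence["SampleAnnotation"],
    target_group: str,
    gene_set: GeneSignature,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "phenotype",
    exhaustive: bool = False,
    weight: float = 0,
) -> np.ndarray:
    """Null ES distribution for one (set, contrast) pair.

    ``phenotype`` mode shuffles group labels and re-ranks; with
    ``exhaustive=True`` every distinct relabelling is enumerated exactly
    once.  ``gene_label`` mode scores random same-size gene sets on the fixed
    observed ranking.  When phenotype permutation is infeasible (a group
    with fewer than 2 samples under relabelling) the call falls back to
    gene_label mode with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("phenotype", "gene_label"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    groups = {ann.sample_id: ann.group for ann in annotations}
    mask = np.array([groups[s] == target_group for s in matrix.sample_ids])
    n, k = mask.size, int(mask.sum())
    if mode == "phenotype" and (k < 2 or n - k < 2):
        warnings.warn(
            "too few samples for phenotype permutation; falling back to "
            "gene_label mode",
            stacklevel=2,
        )
        mode = "gene_label"

    if mode == "phenotype":
        if weight != 0:
            # per-permutation loop keeps |statistic| weights available
            null = np.empty(n_perm if not exhaustive else math.comb(n, k))
            masks = (
                [np.isin(np.arange(n), c) for c in combinations(range(n), k)]
                if exhaustive
                else [
                    np.isin(np.arange(n), rng.permutation(n)[:k])
                    for _ in range(n_perm)
                ]
            )
            for i, m in enumerate(masks):
                t, diff = welch_t(matrix.values, m)
                order = np.argsort(-t, kind="stable")
                ranked = RankedList(
                    [matrix.gene_ids[j] for j in order], t[order], target_group
                )
                null[i], _, _ = enrichment_score(ranked, gene_set, weight)
            return null
        orders = _null_orders_phenotype(matrix.values, mask, n_perm, rng, exhaustive)
        member = _membership(matrix.gene_ids, gene_set)
        return _es_batch(orders, member)

    # gene_label mode: fixed observed ranking, random sets of the same size
    if k < 2 or n - k < 2:
        # a 1-sample group still has a mean: rank by mean difference
        values = matrix.values
        diff = values[:, mask].mean(axis=1) - values[:, ~mask].mean(axis=1)
        order = np.lexsort((np.asarray(matrix.gene_ids, dtype=str), -diff))
        ranked = RankedList(
            [matrix.gene_ids[i] for i in order], diff[order], target_group
        )
    else:
        ranked = rank_genes(matrix, annotations, target_group)
    member = _membership(ranked.gene_ids, gene_set)
    nh = int(member.sum())
    n_genes = member.size
    weights = None if weight == 0 else np.abs(ranked.statistic) ** weight
    null = np.empty(n_perm)
    if weight == 0:
        hits = np.zeros((n_genes, n_perm), dtype=bool)
        for i in range(n_perm):
            hits[rng.choice(n_genes, size=nh, replace=False), i] = True
        steps = np.where(hits, 1.0 / nh, -1.0 / (n_genes - nh))
        running = np.cumsum(steps, axis=0)
        dev = np.abs(running)
        idx = np.argmax(dev >= dev.max(axis=0) - 1e-12, axis=0)
        return running[idx, np.arange(n_perm)]
    for i in range(n_perm):
        rand = np.zeros(n_genes, dtype=bool)
        rand[rng.choice(n_genes, size=nh, replace=False)] = True
        running = _walk(rand, weights)
        null[i], _ = _es_from_running(running)
    return null


def nes_and_p(
    es: float, null_es: np.ndarray, exhaustive: bool = False
) -> tuple[float, float]:
    """Normalise an ES against its null and compute the permutation p.

    NES divides by the mean |null ES| of the observed sign (NaN when that
    subset is empty).  The p-value counts same-sign nulls at least as extreme,
    with the add-one rule for sampled nulls; for an exhaustive null the plain
    ratio is used because the observed relabelling is itself one of the
    enumerated nulls.
    """
    null_es = np.asarray(null_es, dtype=float)
    if null_es.size == 0:
        raise ValueError("empty null distribution")
    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    subset = np.abs(null_es[same_sign])
    if subset.size == 0 or subset.mean() == 0:
        nes = float("nan")
    else:
        nes = float(es) / float(subset.mean()) if es >= 0 else -abs(es) / float(
            subset.mean()
        )
    extreme = int(np.sum(subset >= abs(es) - 1e-12))
    if exhaustive:
        if subset.size == 0:
            return nes, 1.0
        p = extreme / subset.size
        p = max(p, 1.0 / null_es.size)  # the observed itself is in the null
    else:
        p = (1 + extreme) / (1 + subset.size)
    return nes, float(min(p, 1.0))


def gsea(
    matrix: "ExpressionMatrix",
    annotations: Sequence["SampleAnnotation"],
    target_group: str,
    gene_set: GeneSignature,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 0,
    mode: str | None = None,
    exhaustive: bool = False,
) -> EnrichmentResult:
    """Full enrichment test of one gene set for a one-vs-rest contrast.

    ``mode=None`` picks phenotype permutation when both groups have at least
    5 samples and gene_label otherwise.
    """
    groups = {ann.sample_id: ann.group for ann in annotations}
    mask = np.array([groups.get(s) == target_group for s in matrix.sample_ids])
    k, n = int(mask.sum()), mask.size
    if mode is None:
        mode = "phenotype" if min(k, n - k) >= 5 or exhaustive else "gene_label"
        if mode == "gene_label":
            logger.info(
                "contrast %s has a group with < 5 samples; using gene_label null",
                target_group,
            )
    ranked = rank_genes(matrix, annotations, target_group)
    es, running, leading_edge = enrichment_score(ranked, gene_set, weight)
    null = permutation_null(
        matrix,
        annotations,
        target_group,
        gene_set,
        n_perm=n_perm,
        seed=seed,
        mode=mode,
        exhaustive=exhaustive,
        weight=weight,
    )
    nes, p = nes_and_p(es, null, exhaustive=exhaustive)
    return EnrichmentResult(
        signature_name=gene_set.name,
        contrast=f"{target_group} vs rest",
        es=es,
        nes=nes,
        p_perm=p,
        n_permutations=int(null.size),
        leading_edge=leading_edge,
        running_sum=running,
        null_mode=mode,
        seed=seed,
    )
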