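"""Bidirectional stage projection: healthy-stage signatures tested in
leukemia subtypes and subtype signatures tested in healthy stages.

A leukemia subtype is called "arrested" at a developmental stage when the
stage signature is positively enriched in that subtype (forward direction)
AND the subtype signature is positively enriched in that stage (reverse
direction), both at the chosen significance level, and no other stage also
qualifies.  Subtypes with zero or several qualifying stages are reported as
"unassigned".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .enrichment import (
    EnrichmentResult,
    _es_batch,
    _membership,
    _null_orders_phenotype,
    enrichment_score,
    gsea,
    nes_and_p,
)
from .signatures import GeneSignature, derive_all_group_signatures, rank_genes

if TYPE_CHECKING:  # pragma: no cover
    from .io import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = ["ProjectionGrid", "StageCall", "cross_project", "call_arrest_stage"]


@dataclass
class ProjectionGrid:
    """Enrichment results for the full signature x contrast Cartesian grids.

    ``forward`` maps (stage signature, subtype contrast) and ``reverse``
    maps (subtype signature, stage contrast) to an
    :class:`~stagescan.enrichment.EnrichmentResult`.
    """

    forward: dict[tuple[str, str], EnrichmentResult]
    reverse: dict[tuple[str, str], EnrichmentResult]
    stages: list[str]
    subtypes: list[str]

    def __post_init__(self) -> None:
        want_fwd = {(st, su) for st in self.stages for su in self.subtypes}
        want_rev = {(su, st) for st in self.stages for su in self.subtypes}
        if set(self.forward) != want_fwd or set(self.reverse) != want_rev:
            raise ValueError("projection grid is not a full Cartesian product")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (direction, signature, contrast, es, nes, p)."""
        rows = []
        for direction, grid in (("healthy->leukemia", self.forward),
                                ("leukemia->healthy", self.reverse)):
            for (sig, contrast), res in sorted(grid.items()):
                rows.append(
                    {
                        "direction": direction,
                        "signature": sig,
                        "contrast": contrast,
                        "es": res.es,
                        "nes": res.nes,
                        "p_perm": res.p_perm,
                        "n_permutations": res.n_permutations,
                        "null_mode": res.null_mode,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class StageCall:
    """Arrest-stage call for one leukemia subtype."""

    subtype: str
    stage: str  # a stage label or "unassigned"
    forward_p: float
    reverse_p: float

    def __post_init__(self) -> None:
        if self.stage != "unassigned" and not (
            np.isfinite(self.forward_p) and np.isfinite(self.reverse_p)
        ):
            raise ValueError("assigned stage requires finite p-values")


def _contrast_enrichments(
    matrix: "ExpressionMatrix",
    annotations: Sequence["SampleAnnotation"],
    target_group: str,
    gene_sets: Sequence[GeneSignature],
    n_perm: int,
    seed: int,
    weight: float = 0,
) -> dict[str, EnrichmentResult]:
    """Score several gene sets against one contrast, sharing the permutation
    rankings across sets (phenotype null, weight 0)."""
    groups = {ann.sample_id: ann.group for ann in annotations}
    mask = np.array([groups[s] == target_group for s in matrix.sample_ids])
    k, n = int(mask.sum()), mask.size
    if weight != 0 or min(k, n - k) < 5:
        return {
            gs.name: gsea(
                matrix, annotations, target_group, gs,
                n_perm=n_perm, seed=seed, weight=weight,
            )
            for gs in gene_sets
        }
    ranked = rank_genes(matrix, annotations, target_group)
    rng = np.random.default_rng(seed)
    orders = _null_orders_phenotype(matrix.values, mask, n_perm, rng, False)
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    results: dict[str, EnrichmentResult] = {}
    for gs in gene_sets:
        es, running, leading_edge = enrichment_score(ranked, gs, weight)
        member = np.zeros(len(matrix.gene_ids), dtype=bool)
        member[[index[g] for g in gs.genes if g in index]] = True
        null = _es_batch(orders, member)
        nes, p = nes_and_p(es, null)
        results[gs.name] = EnrichmentResult(
            signature_name=gs.name,
            contrast=f"{target_group} vs rest",
            es=es,
            nes=nes,
            p_perm=p,
            n_permutations=n_perm,
            leading_edge=leading_edge,
            running_sum=running,
            null_mode="phenotype",
            seed=seed,
        )
    return results


def cross_project(
    healthy: tuple["ExpressionMatrix", Sequence["SampleAnnotation"]],
    leukemia: tuple["ExpressionMatrix", Sequence["SampleAnnotation"]],
    n: int = 400,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 0,
    statistic: str = "welch_t",
) -> ProjectionGrid:
    """Derive stage and subtype signatures and fill both enrichment grids.

    Both data sets are first restricted to their common gene universe, so a
    signature never contains a gene absent from the matrix it is projected
    into.
    """
    healthy_m, healthy_ann = healthy
    leukemia_m, leukemia_ann = leukemia
    shared = [g for g in healthy_m.gene_ids if g in set(leukemia_m.gene_ids)]
    if not shared:
        raise ValueError("healthy and leukemia gene universes do not intersect")
    if len(shared) < len(healthy_m.gene_ids) or len(shared) < len(leukemia_m.gene_ids):
        logger.info(
            "restricting to %d shared genes (healthy %d, leukemia %d)",
            len(shared), len(healthy_m.gene_ids), len(leukemia_m.gene_ids),
        )
    healthy_m = healthy_m.subset(genes=shared)
    leukemia_m = leukemia_m.subset(genes=shared)

    stage_sigs = derive_all_group_signatures(healthy_m, healthy_ann, n, statistic)
    subtype_sigs = derive_all_group_signatures(leukemia_m, leukemia_ann, n, statistic)
    stages = [s.name for s in stage_sigs]
    subtypes = [s.name for s in subtype_sigs]

    seq = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in seq.generate_state(len(subtypes) + len(stages))]

    forward: dict[tuple[str, str], EnrichmentResult] = {}
    for i, subtype in enumerate(subtypes):
        res = _contrast_enrichments(
            leukemia_m, leukemia_ann, subtype, stage_sigs,
            n_perm=n_perm, seed=child_seeds[i], weight=weight,
        )
        for stage in stages:
            forward[(stage, subtype)] = res[stage]

    reverse: dict[tuple[str, str], EnrichmentResult] = {}
    for j, stage in enumerate(stages):
        res = _contrast_enrichments(
            healthy_m, healthy_ann, stage, subtype_sigs,
            n_perm=n_perm, seed=child_seeds[len(subtypes) + j], weight=weight,
        )
        for subtype in subtypes:
            reverse[(subtype, stage)] = res[subtype]

    return ProjectionGrid(forward=forward, reverse=reverse,
                          stages=stages, subtypes=subtypes)


def call_arrest_stage(
    grid: ProjectionGrid, alpha: float = 0.05, specific: bool = True
) -> list[StageCall]:
    """Call the arrest stage of each subtype from a completed grid.

    A stage qualifies when both directions show positive enrichment with
    p <= alpha; a subtype is called only when exactly one stage qualifies.
    With ``specific=True`` (default) an enrichment additionally has to be
    *specific* in the sense of "enriched in this subtype but not other
    subtypes": a stage signature that is positively significant in more
    than one subtype contrast cannot support a call, and likewise a subtype
    signature positively significant in more than one stage.  This guards
    against the correlated-background artifact of one-vs-rest contrasts,
    where every gene set that merely avoids the down-regulated blocks of
    the *other* groups drifts to weak positive enrichment.

    For unassigned subtypes the reported p-values are the minima over
    stages in each direction.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    def _hit(res: EnrichmentResult) -> bool:
        return res.p_perm <= alpha and res.es > 0

    # contrasts each signature is positively significant in
    fwd_hits = {
        stage: {su for su in grid.subtypes if _hit(grid.forward[(stage, su)])}
        for stage in grid.stages
    }
    rev_hits = {
        su: {stage for stage in grid.stages if _hit(grid.reverse[(su, stage)])}
        for su in grid.subtypes
    }

    calls: list[StageCall] = []
    for subtype in grid.subtypes:
        qualifying = []
        for stage in grid.stages:
            fwd = grid.forward[(stage, subtype)]
            rev = grid.reverse[(subtype, stage)]
            ok = _hit(fwd) and _hit(rev)
            if ok and specific:
                ok = fwd_hits[stage] == {subtype} and rev_hits[subtype] == {stage}
            if ok:
                qualifying.append((stage, fwd.p_perm, rev.p_perm))
        if len(qualifying) == 1:
            stage, fp, rp = qualifying[0]
            calls.append(StageCall(subtype, stage, fp, rp))
        else:
            if len(qualifying) > 1:
                logger.info(
                    "subtype %s: multiple qualifying stages %s -> unassigned",
                    subtype, [q[0] for q in qualifying],
                )
            fp = min(grid.forward[(st, subtype)].p_perm for st in grid.stages)
            rp = min(grid.reverse[(subtype, st)].p_perm for st in grid.stages)
            calls.append(StageCall(subtype, "unassigned", fp, rp))
    return calls
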