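"""Synthetic expression cohorts with planted stage structure and outcomes.

The generator emulates the structure of healthy B-cell development and
B-cell precursor ALL microarray cohorts:

* four healthy stages (CLP, pro-B, pre-B, iB), each with a disjoint block of
  up-regulated genes and a stage-specific pattern of the five
  pre-B-cell-receptor component markers (IGHM, IGLL1, VPREB1, CD79A, CD79B):
  CLP expresses none, pro-B expresses VPREB1/IGLL1/CD79A/CD79B, pre-B all
  five, and immature B only IGHM/CD79A/CD79B;
* leukemia subtypes, each with its own up-regulated block; a subtype with a
  planted arrest stage additionally inherits that stage's mean profile
  (signature block plus markers), so the TCF3-PBX1-like subtype shows high
  IGHM/IGLL1/VPREB1 and the ETV6-RUNX1-like subtype baseline IGHM;
* cluster-dependent clinical outcomes: MRD day-29 positivity is Bernoulli
  with probability 0.13 in Cluster 1 and 0.45 elsewhere, survival times are
  exponential with cluster-specific hazards, censoring is independent
  exponential.

Expression is generated directly in log2 space as Gaussian noise around the
block-structured means (a log-normal model for raw intensities).  All three
generators are fully deterministic for a fixed spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .io import ExpressionMatrix, OutcomeRecord, SampleAnnotation

__all__ = [
    "MARKERS",
    "DEFAULT_STAGES",
    "DEFAULT_SUBTYPE_MAP",
    "DEFAULT_MARKER_PATTERN",
    "OutcomeModel",
    "CohortSpec",
    "simulate_healthy",
    "simulate_leukemia",
    "simulate_outcomes",
]

MARKERS = ("IGHM", "IGLL1", "VPREB1", "CD79A", "CD79B")

DEFAULT_STAGES = ("CLP", "pro-B", "pre-B", "iB")

# arrest stages of the leukemia subtypes; None = no stage structure
DEFAULT_SUBTYPE_MAP: dict[str, str | None] = {
    "ETV6-RUNX1": "pro-B",
    "TCF3-PBX1": "pre-B",
    "BCR-ABL1": None,
    "MLL": None,
    "HH": None,
    "other": None,
}

DEFAULT_MARKER_PATTERN: dict[str, frozenset[str]] = {
    "CLP": frozenset(),
    "pro-B": frozenset({"VPREB1", "IGLL1", "CD79A", "CD79B"}),
    "pre-B": frozenset(MARKERS),
    "iB": frozenset({"IGHM", "CD79A", "CD79B"}),
}


@dataclass(frozen=True)
class OutcomeModel:
    """Per-cluster outcome parameters (hazards per day)."""

    mrd_prob: float
    efs_hazard: float
    os_hazard: float
    censor_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mrd_prob <= 1.0:
            raise ValueError(f"mrd_prob must be in [0, 1], got {self.mrd_prob}")
        for name in ("efs_hazard", "os_hazard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")


def default_outcome_model() -> dict[int, OutcomeModel]:
    """MRD 13% in Cluster 1 versus 45% elsewhere; Cluster 1 has the lowest
    and Cluster 3 the highest event hazards."""
    return {
        1: OutcomeModel(0.13, 1 / 2000, 1 / 3000, 1 / 3000),
        2: OutcomeModel(0.45, 1 / 1000, 1 / 1500, 1 / 3000),
        3: OutcomeModel(0.45, 1 / 500, 1 / 800, 1 / 3000),
        4: OutcomeModel(0.45, 1 / 1000, 1 / 1500, 1 / 3000),
    }


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    ``delta`` is the planted log2 effect size shared by signature blocks and
    marker effects (an independent ``delta_marker`` can be set), ``sigma``
    the Gaussian noise SD in log2 units and ``baseline`` the background
    log2 expression level.
    """

    n_genes: int = 3000
    genes_per_stage_signature: int = 200
    stages: tuple[str, ...] = DEFAULT_STAGES
    subtype_map: dict[str, str | None] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_MAP)
    )
    samples_per_group: int = 20
    delta: float = 2.0
    sigma: float = 1.0
    baseline: float = 6.0
    delta_marker: float | None = None  # defaults to delta
    marker_pattern: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_PATTERN)
    )
    outcome_model: dict[int, OutcomeModel] = field(
        default_factory=default_outcome_model
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def subtypes(self) -> list[str]:
        return list(self.subtype_map)

    @property
    def marker_delta(self) -> float:
        return self.delta if self.delta_marker is None else self.delta_marker

    def validate(self) -> None:
        n_groups = len(self.stages) + len(self.subtype_map)
        needed = len(MARKERS) + n_groups * self.genes_per_stage_signature
        if self.n_genes < needed:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_groups} disjoint "
                f"signature blocks of {self.genes_per_stage_signature} genes "
                f"plus {len(MARKERS)} markers (need >= {needed})"
            )
        if self.samples_per_group < 2:
            raise ValueError("samples_per_group must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        for stage, markers in self.marker_pattern.items():
            unknown = set(markers) - set(MARKERS)
            if unknown:
                raise ValueError(f"unknown markers {unknown} for stage {stage!r}")
        for stage in self.stages:
            if stage not in self.marker_pattern:
                raise ValueError(f"no marker pattern for stage {stage!r}")
        for subtype, arrest in self.subtype_map.items():
            if arrest is not None and arrest not in ("none", *self.stages):
                raise ValueError(
                    f"subtype {subtype!r} references unknown stage {arrest!r}"
                )

    # --- gene universe layout -------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        n_plain = self.n_genes - len(MARKERS)
        width = len(str(n_plain))
        return list(MARKERS) + [f"G{i:0{width}d}" for i in range(1, n_plain + 1)]

    def _block(self, index: int) -> list[str]:
        """The index-th disjoint signature block (stages first, then
        subtypes)."""
        gps = self.genes_per_stage_signature
        start = len(MARKERS) + index * gps
        return self.gene_ids[start:start + gps]

    def stage_block(self, stage: str) -> list[str]:
        return self._block(self.stages.index(stage))

    def subtype_block(self, subtype: str) -> list[str]:
        return self._block(len(self.stages) + self.subtypes.index(subtype))

    def _arrest_of(self, subtype: str) -> str | None:
        arrest = self.subtype_map[subtype]
        return None if arrest in (None, "none") else arrest

    def stage_mean_profile(self, stage: str) -> np.ndarray:
        """Noise-free log2 mean vector of one healthy stage."""
        gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        mu = np.full(self.n_genes, self.baseline)
        for g in self.stage_block(stage):
            mu[gene_index[g]] += self.delta
        for m in self.marker_pattern[stage]:
            mu[gene_index[m]] += self.marker_delta
        return mu

    def subtype_mean_profile(self, subtype: str) -> np.ndarray:
        """Noise-free log2 mean vector of one leukemia subtype."""
        arrest = self._arrest_of(subtype)
        if arrest is not None:
            mu = self.stage_mean_profile(arrest)
        else:
            mu = np.full(self.n_genes, self.baseline)
        gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        for g in self.subtype_block(subtype):
            mu[gene_index[g]] += self.delta
        return mu


def _simulate_groups(
    spec: CohortSpec,
    groups: Sequence[str],
    mean_of: Mapping[str, np.ndarray],
    prefix: str,
    stream: int,
) -> tuple[ExpressionMatrix, list[SampleAnnotation]]:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))
    columns: dict[str, np.ndarray] = {}
    annotations: list[SampleAnnotation] = []
    width = len(str(spec.samples_per_group))
    for group in groups:
        mu = mean_of[group]
        noise = rng.normal(0.0, spec.sigma, size=(spec.n_genes, spec.samples_per_group))
        safe = group.replace(" ", "_")
        for j in range(spec.samples_per_group):
            sid = f"{prefix}_{safe}_{j + 1:0{width}d}"
            columns[sid] = mu + noise[:, j]
            annotations.append(SampleAnnotation(sid, group))
    data = pd.DataFrame(columns, index=spec.gene_ids)
    return ExpressionMatrix(data), annotations


def simulate_healthy(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, list[SampleAnnotation]]:
    """Healthy B-cell development cohort: one group per stage."""
    means = {stage: spec.stage_mean_profile(stage) for stage in spec.stages}
    return _simulate_groups(spec, spec.stages, means, "H", stream=0)


def simulate_leukemia(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, list[SampleAnnotation]]:
    """Leukemia cohort: one group per subtype, arrest profiles planted per
    ``spec.subtype_map``."""
    means = {st: spec.subtype_mean_profile(st) for st in spec.subtypes}
    return _simulate_groups(spec, spec.subtypes, means, "L", stream=1)


def simulate_outcomes(
    assignment: ClusterAssignment, spec: CohortSpec
) -> list[OutcomeRecord]:
    """Cluster-dependent outcomes for the samples of a cluster assignment.

    Returns records aligned with ``assignment.sample_ids``.  MRD day-29
    status is Bernoulli, event-free and overall survival times are
    exponential with the cluster's hazards, censored by an independent
    exponential clock.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    records: list[OutcomeRecord] = []
    for sid in assignment.sample_ids:
        cluster = int(assignment.clusters[sid])
        try:
            model = spec.outcome_model[cluster]
        except KeyError:
            raise ValueError(
                f"no outcome model for cluster {cluster} (sample {sid!r})"
            ) from None
        mrd = bool(rng.random() < model.mrd_prob)
        efs_raw = rng.exponential(1.0 / model.efs_hazard)
        os_raw = rng.exponential(1.0 / model.os_hazard)
        if model.censor_rate > 0:
            censor_efs = rng.exponential(1.0 / model.censor_rate)
            censor_os = rng.exponential(1.0 / model.censor_rate)
        else:
            censor_efs = censor_os = np.inf
        records.append(
            OutcomeRecord(
                mrd29_positive=mrd,
                efs_time=float(min(efs_raw, censor_efs)),
                efs_event=bool(efs_raw <= censor_efs),
                os_time=float(min(os_raw, censor_os)),
                os_event=bool(os_raw <= censor_os),
            )
        )
    return records
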