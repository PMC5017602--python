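# stagescan

Developmental-stage projection and pre-BCR marker clustering for B-cell
precursor acute lymphoblastic leukemia (BCP-ALL) expression cohorts.

## The problem

BCP-ALL blasts are developmentally arrested B-cell precursors.  Whether a
leukemia most resembles the common lymphoid progenitor (CLP), pro-B, pre-B
or immature-B (iB) transcriptional program — its *arrest stage* — relates to
the expression of the precursor B-cell receptor (pre-BCR) components
(*IGHM*, the surrogate light chain *IGLL1*/*VPREB1*, and the signaling
chains *CD79A*/*CD79B*) and to clinical outcome.  stagescan implements the
full analysis chain a transcriptomics group would run to ask that question:

1. **Signature derivation** — for each group (healthy stage, leukemia
   subtype, or marker-defined cluster), rank all genes by the one-vs-rest
   Welch *t* statistic and keep the top *N* (default 400) up-regulated genes.
2. **Rank-based gene-set enrichment** — the classic running-sum statistic:
   walking the ranked list, the sum rises by `1/|S|` at a set member and
   falls by `1/(N−|S|)` otherwise (weight 0); the enrichment score ES is
   the maximal absolute deviation.  NES normalises ES by the mean |ES| of a
   same-signed permutation null (phenotype relabelling, or random gene sets
   for small contrasts), and the permutation p uses the add-one rule
   `p = (1 + #{|ES*| ≥ |ES|}) / (1 + B)` over same-signed nulls.
3. **Bidirectional stage projection** — every stage signature is tested in
   every subtype-vs-rest contrast and every subtype signature in every
   stage-vs-rest contrast.  A subtype is called arrested at a stage when
   both directions are positively enriched at `α = 0.05`, the enrichment is
   *specific* (no other contrast lights up for the same signature), and the
   stage is unique; otherwise the subtype is `unassigned`.
4. **Marker clustering** — samples are split on per-marker medians (or
   quartiles, or a fixed threshold) of *IGHM*, *IGLL1*, *VPREB1* and mapped
   to four clusters: Cluster 1 = IGHM+IGLL1+VPREB1+, Cluster 2 = IGHM+ but
   not Cluster 1, Cluster 3 = IGHM− with IGLL1 and/or VPREB1 positive,
   Cluster 4 = triple negative.
5. **Outcome statistics** — Kaplan–Meier product-limit curves, the
   tie-corrected k-sample log-rank test, and Fisher's exact test (2×2
   hypergeometric tail; 2×k Freeman–Halton enumeration) compare minimal
   residual disease at day 29 (MRD 29) and event-free/overall survival
   across clusters.

A synthetic-cohort generator (`stagescan.simulate`) plants all of this
structure — stage-specific gene blocks, the stage-wise marker pattern,
subtype arrest profiles, and cluster-dependent outcomes — so the entire
pipeline is testable without external data.

## Worked example

```python
import stagescan as ss

spec = ss.CohortSpec(seed=0)                 # 3000 genes, 20 samples/group
healthy = ss.simulate_healthy(spec)
leukemia = ss.simulate_leukemia(spec)

grid = ss.cross_project(healthy, leukemia, n=400, n_perm=500, seed=1)
for call in ss.call_arrest_stage(grid):
    print(f"{call.subtype:<11s} -> {call.stage:<10s} "
          f"(forward p={call.forward_p:.3g}, reverse p={call.reverse_p:.3g})")

assignment = ss.assign_clusters(ss.call_positivity(leukemia[0]))
records = ss.simulate_outcomes(assignment, spec)
report = ss.compare_clusters(assignment, records)
print(report.mrd_table)
print(f"Cluster 1 vs rest Fisher p = {report.mrd_cluster1_vs_rest_p:.3g}")
print(f"EFS log-rank p = {report.logrank_omnibus['efs'].p:.3g}")
```

prints

```
ETV6-RUNX1  -> pro-B      (forward p=0.00441, reverse p=0.00368)
TCF3-PBX1   -> pre-B      (forward p=0.00455, reverse p=0.00386)
BCR-ABL1    -> unassigned (forward p=0.00364, reverse p=0.00386)
MLL         -> unassigned (forward p=0.00364, reverse p=0.0041)
HH          -> unassigned (forward p=0.00362, reverse p=0.00407)
other       -> unassigned (forward p=0.00379, reverse p=0.00431)
   positive  negative
1         3        17
2        16        24
3        23        17
4        12         8
Cluster 1 vs rest Fisher p = 0.00308
EFS log-rank p = 0.000284
```

The two subtypes simulated with a planted arrest stage are recovered
(TCF3-PBX1-like → pre-B, ETV6-RUNX1-like → pro-B); the four structureless
subtypes stay unassigned (their minimal p-values are small because of the
correlated one-vs-rest background, but no signature is *specifically*
enriched in them — see `docs/methods.md`).  Cluster 1 shows the low MRD 29
positivity (3/20) planted by the outcome model, and the survival difference
between clusters is detected by the log-rank test.

The same pipeline runs from the shell:

```sh
stagescan all --seed 0 --n-perm 500 --out run/
stagescan simulate --seed 0 --out sim/        # just the synthetic cohort
stagescan project --help                      # analyse your own matrices
```

Input formats are plain TSV (genes × samples expression matrix, sample
annotation table) and GMT for gene sets; `stagescan all` writes signatures
(GMT), the projection grid and stage calls, cluster assignments, outcome
tests (TSV) and a JSON run manifest carrying the config hash stamped on
every output.

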