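# Methods

This note documents the statistical procedures implemented in stagescan,
the defaults and the reasoning behind them, what the synthetic cohort
generator does and does not emulate, and the numerical conventions that
matter for reproducing results exactly.

## Signature derivation

A signature for a target group is obtained from a one-vs-rest contrast on
a log2-scale genes × samples matrix.  The default ranking statistic is the
Welch two-sample *t* (target mean minus rest mean, unequal variances);
"signal-to-noise" (mean difference over summed SDs) is available as an
alternative.  Both groups need at least two samples.  Ties are broken by
larger mean difference, then lexicographic gene id, so rankings are fully
deterministic.  Genes with zero variance in both groups score 0 when the
means agree and ±∞ otherwise (they sort to the extremes).

The signature is the top *N* genes with a *strictly positive* statistic
(default N = 400): a "highly expressed" signature must be up-regulated, so
fewer than *N* genes may be returned (with a warning).  No multiple-testing
correction is applied at this step — selection is by rank, not
significance.  Probe-to-gene collapsing is the caller's responsibility; the
matrix reader only collapses duplicate gene ids by keeping the
highest-mean row.

## Enrichment statistic

The enrichment score is the unweighted Kolmogorov–Smirnov running sum:
walking the ranked list, add `1/|S|` at a member of gene set S and subtract
`1/(N−|S|)` otherwise; ES is the running-sum value of maximal absolute
deviation, and the leading edge contains the members at or before (for
negative ES, at or after) the extremum.  Weight 0 is the default because
each hit and miss then contributes an equal step; `weight=1` (steps
proportional to |statistic|) is available.  The unweighted walk ends at 0
to within 1e−12, and ES ∈ [−1, 1] always.

Extremum ties: when the largest positive and largest negative deviations
agree in magnitude exactly (possible for sets occupying both ends of the
list symmetrically), the first extremum along the list is taken.  The
comparison uses a 1e−12 tolerance so cumulative-sum rounding cannot break
an exact tie.  For such reversal-symmetric walks, reversing the ranking
preserves |ES| but no deterministic convention can also flip its sign;
everywhere else reversal negates ES exactly.

### Null distributions and p-values

Two nulls are implemented:

* **phenotype** — shuffle group labels, re-rank, re-score.  Used by
  default when both groups have ≥ 5 samples.  An `exhaustive` flag
  enumerates every distinct relabelling exactly once (feasible for small
  contrasts, e.g. all C(6,3) = 20 relabellings of a 3-vs-3 contrast).
* **gene_label** — score random gene sets of the observed size on the
  fixed ranking.  Used for small contrasts, and as an automatic fallback
  (with a warning) when a group is too small to relabel.  If a group has a
  single sample the internal ranking falls back to the plain mean
  difference, since Welch's t needs two samples per group.

NES divides ES by the mean |null ES| of the same sign (undefined, reported
as NaN, when no null shares the sign).  The permutation p counts same-sign
nulls at least as extreme with the add-one rule,
`p = (1 + #{|ES*| ≥ |ES|}) / (1 + B_signed)`, so p ≥ 1/(B+1) and never 0.
For an exhaustive null the plain ratio `#{|ES*| ≥ |ES|} / B_signed` is used
instead: the observed relabelling is itself one of the enumerated nulls,
so adding one would double-count it.  Seeds are explicit arguments and are
recorded in every result object.

## Stage projection and arrest calls

Both matrices are first restricted to their shared gene universe, so no
signature contains a gene absent from the matrix it is projected into.
Stage signatures (healthy cohort) are tested in every subtype-vs-rest
contrast ("forward") and subtype signatures in every stage-vs-rest
contrast ("reverse"); permutation rankings are shared across gene sets
within a contrast, which changes nothing statistically but makes the
4 × 6 × 2 grid cheap.

A stage qualifies for a subtype when both directions show positive ES with
p ≤ α (default 0.05) **and** the enrichment is *specific*: the stage
signature must not be positively significant in any other subtype
contrast, nor the subtype signature in any other stage.  A subtype is
called only when exactly one stage qualifies; otherwise it is
`unassigned`.

The specificity requirement is the load-bearing design choice.  In a
one-vs-rest contrast the "rest" is heterogeneous: gene blocks up-regulated
in *other* groups sit at the bottom of the ranking, so any gene set that
merely avoids them drifts to a weak positive ES (≈ 0.1–0.2) whose
permutation p still reaches the floor, because label shuffling destroys
exactly the structure that produced the drift.  Requiring two significant
directions does not remove this artifact — a signature with no true match
lights up weakly in *every* structureless contrast.  Demanding that it
light up in exactly one is what separates a planted arrest profile
(ES ≈ 0.5, unique) from the background, and mirrors the scientific notion
of a subtype *specifically* resembling one developmental stage.  With the
requirement enabled (default) the planted arrest map is recovered
essentially always under the default generator settings; without it,
structureless subtypes are sporadically assigned a stage.

No multiple-testing correction is applied across the grid; raw p-values
are reported.

## Marker clustering

Positivity calls for *IGHM*, *IGLL1*, *VPREB1* use a per-marker median
split by default (positive iff strictly above the cohort median; a
constant marker is therefore all-negative).  Alternatives: top-half
quartiles (quartile index ≥ 3) and a fixed threshold.  Quartile binning
sorts by value with sample-id tie-breaks and puts the larger bins at the
low end when the cohort size is not divisible by four; it is invariant
under strictly monotone transforms of the values.  The threshold method
and per-marker cut-offs are recorded in every output.

The four clusters — Cluster 1 = IGHM+IGLL1+VPREB1+, Cluster 2 = IGHM+ not
Cluster 1, Cluster 3 = IGHM− with IGLL1 and/or VPREB1 positive, Cluster 4
= triple negative — are mutually exclusive and exhaustive over the 8
positivity patterns.  (An alternative reading of Cluster 2 as "IGHM+ and
exactly one of IGLL1/VPREB1" would leave the IGHM+IGLL1−VPREB1− pattern
unclassified; the definition used here is the one that partitions every
cohort.)

## Survival and contingency statistics

* **Kaplan–Meier**: product-limit estimator; censored observations shrink
  the risk set only, and a censoring tied to an event time is processed
  after the event (the subject counts as at risk).  With no censoring the
  curve equals one minus the empirical CDF.
* **Log-rank**: k-sample statistic with the hypergeometric (tie-corrected)
  variance at each distinct event time, no continuity correction, referred
  to χ² with k − 1 degrees of freedom.  The covariance matrix of the first
  k − 1 group event counts is inverted with a pseudo-inverse fallback for
  degenerate risk sets.
* **Fisher's exact test**: two-sided by probability-mass ordering — the p
  sums all tables with the observed margins whose probability does not
  exceed the observed table's.  Inclusion is decided on exact integer
  hypergeometric weights (products of binomial coefficients), so
  borderline tables are handled without floating-point tolerance, and the
  p-value itself is a single integer ratio.  2×k tables (k ≤ 4) use full
  Freeman–Halton enumeration; empty columns drop out, and a zero row
  margin admits a single table (p = 1).

The cluster report contains the clusters × MRD-29 table with the overall
Fisher p, Cluster-1-vs-rest and Cluster-1-vs-each pairwise 2×2 p-values,
and per-endpoint (event-free, overall survival) KM curves with omnibus and
pairwise log-rank tests.  Samples missing an outcome are excluded from
that analysis only, with counts reported.  No correction is applied across
pairwise contrasts.

## Synthetic cohort generator

Expression is Gaussian in log2 space (log-normal raw intensities) around a
block-structured mean: baseline μ0 = 6.0 log2 units, planted effect size
Δ = 2.0 log2 units, noise σ = 1.0.  Defaults: 3000 genes, 200 genes per
signature block, 20 samples per group.  Four healthy stages each get a
disjoint up-regulated block plus their marker pattern (CLP: none; pro-B:
VPREB1, IGLL1, CD79A/B; pre-B: all five; iB: IGHM, CD79A/B).  Each
leukemia subtype gets its own disjoint block; a subtype with a planted
arrest stage additionally inherits that stage's full mean profile, so the
TCF3-PBX1-like subtype is high in IGHM/IGLL1/VPREB1 and the
ETV6-RUNX1-like subtype keeps baseline IGHM.  The default arrest map
plants pre-B for TCF3-PBX1, pro-B for ETV6-RUNX1, and no stage structure
for BCR-ABL1, MLL, HH and "other".  Marker effects share Δ with the
blocks unless `delta_marker` is set.

Outcomes depend on expression only through the cluster label: MRD 29 is
Bernoulli with probability 0.13 in Cluster 1 and 0.45 in Clusters 2–4;
event times are exponential with per-cluster hazards (per day) chosen as
realistic childhood high-risk ALL figures — Cluster 1 best (EFS 1/2000,
OS 1/3000), Cluster 3 worst (1/500, 1/800), Clusters 2 and 4 intermediate
(1/1000, 1/1500) — with independent exponential censoring at rate 1/3000.
All three generators draw from independent streams of a single seed and
are bit-reproducible.

What the generator does **not** emulate: probe-level artifacts, batch and
platform effects, correlated gene-gene covariance beyond the planted
blocks, copy-number-driven expression changes, non-exponential hazards,
and informative censoring.  Passing tests therefore demonstrate that the
statistics and the calling logic behave correctly under a clean additive
model — not that the pipeline is robust to the full messiness of
cross-platform microarray cohorts, where normalisation and batch
harmonisation remain the user's responsibility.

## Problem sizes used in the test suite

The suite exercises the default cohort (3000 genes, 20 samples/group) for
planted-signal recovery, with 200 permutations per enrichment test and 20
replicate cohorts for the arrest-call check; null calibrations use 200
replicate no-signal cohorts (enrichment), 9 structureless cohorts ≈ 216
forward tests (projection), 500 two-group exponential simulations with
~20% censoring (log-rank) and 200 replicates of equal-outcome clusters
(Fisher).  Exhaustive oracles cover every membership pattern on up to 8
genes (enrichment score), all C(6,3) relabellings of 3-vs-3 contrasts
(permutation p and log-rank ordering) and every 2×2 table with total ≤ 40
(Fisher).  These sizes make the full suite run in a couple of minutes
while keeping every Monte-Carlo interval well inside its acceptance band.

## Known limitations

* The enrichment p-value floor is 1/(B+1); contrasts needing p far below
  1/n_perm require more permutations.
* The specificity rule assumes the signature × contrast grid is the whole
  analysis universe; adding unrelated contrasts to the grid can veto a
  true call.
* Freeman–Halton enumeration is exponential in the number of columns and
  is limited to 2×k with k ≤ 4.
* Arrest calls are per-subtype majority statements; within-subtype
  heterogeneity (mixtures of arrest stages) is not modelled.
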