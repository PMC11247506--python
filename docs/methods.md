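# Methods

## Copy-number model

Level-3 SNP-array segments carry log2 copy ratios; a gene receives a value
only when a single segment covers its entire span (straddled or uncovered
genes are missing, never interpolated). The observed linear fold `OCN` in a
tumor sample is a purity-weighted mixture of tumor and normal signal, so the
adjusted copy number is

    ACN = ((OCN − (1 − TP)) / TP) / GCN

with tumor purity `TP ∈ (0, 1]` and the germline fold `GCN` for that gene.
When purity or germline information is missing a value of 1 is substituted,
which degrades the statistic gracefully to a plain fold change. Properties
that define the contract: `ACN = 1` whenever the observed fold is 1
regardless of purity; the map is the identity at `TP = GCN = 1`; and it
exactly inverts the mixture `OCN = TP·t + (1 − TP)` for any planted tumor
fold `t`. The result is floored at 1e-6 because noise in impure samples can
push the numerator negative, and downstream ratio/log math must stay defined.

Discretization uses fold cutoffs `2^0.3` (amplified) and `2^−0.3` (deleted).
Ties at a cutoff count as altered — the boundary had to be fixed one way and
counting a tie as altered is the inclusive choice. Under the adjustment
formula the `2^0.3` cutoff corresponds to a single-copy gain in
`2·(2^0.3 − 1) ≈ 46%` of tumor cells.

## Direction filter

For each gene the counts of amplified and deleted TNBC tumors set a majority
direction; the upper-tail binomial probability `P(X ≥ k)` with
`k = max(n_amp, n_del)` under `Binomial(n_TNBC, p0)` is compared to 0.05.
The tail (rather than the point mass) is used because a tail is the
conservative superset and behaves monotonically in `k`. No multiplicity
correction is applied at this step, deliberately: the input regions already
survived a genome-wide recurrence analysis, so this is a mild extra filter,
not a discovery scan. The null probability `p0` defaults to the dataset-wide
alteration frequency of the matching direction (total altered calls over
total non-missing calls in the TNBC call matrix) — the only background
estimable from the data itself — and is configurable. Equal non-zero counts
are flagged `ambiguous_tie` and excluded, since the direction rule is defined
only for strict majorities.

## Expression concordance and retention

Expression SDs and z-scores are computed on `log2(1 + x)`-transformed
quantifications (sample SD, n−1 denominator); the scale of the SD > 0.25
rule is configurable because RSEM-style values are heavy-tailed on the raw
scale. Altered vs non-altered primary tumors are compared two-sided with
Student's *t* when a two-sided F-ratio test at 0.05 accepts equal variances,
Welch's test otherwise; p-values are Bonferroni-multiplied by the number of
genes tested. Groups of ≥ 30 are taken as covered by the CLT; smaller groups
are screened with Shapiro–Wilk and flagged (the parametric result is still
reported, since the pipeline's cohort-scale groups essentially always exceed
30).

Retention is directional: positive concordance and non-significance always
pass; amplified genes with *reduced* expression also pass (amplification can
plausibly silence a tumor suppressor through chromatin disruption); deleted
genes with significantly *increased* expression are removed — there is no
mechanism by which deleting a driver raises its expression, so such genes
are passengers or artifacts.

## Tiering

Precedence is 2G > 2I > 1I > 1G > 3 > 4; the discrepancy classes outrank
Group 1 because a candidate whose catalogs disagree is weaker evidence than
its within-region rank suggests. "Top 1–3 genes by Helios" is implemented as
configurable top-k (default 3, capped by region size); the per-region 1-vs-3
choice is editorial and not reproducible from any rule. The extended slice —
top 3 for regions of ≤ 12 genes, top quartile above — uses a count ceiling
(`ceil(size/4)`); ceiling vs floor is a coin flip and ceiling keeps the
slice non-empty. The 1G conditions are (1) concordant expression — positive
relation for amplified genes, negative for deleted ones, since the relation
is coded relative to the altered group, (2) an alteration-frequency rank
within the slice, computed on TNBC samples to match the TNBC-specific
direction (configurable to all samples), and (3) a region of fewer than 10
genes. GISTIC-only genes failing exactly one condition fall to Group 3,
everything else to Group 4; the 3/4 boundary is operational, the groups being
defined only as "the remainder". Orthology is a strict-majority vote over the
top-scoring candidate of each of five resources (DroID, DIOPT, HomoloGene,
Ensembl, OrthoDB); without a strict majority the gene is ambiguous and not
testable in the fly.

## Cohort clustering and survival

Mutation classes map to a 0–2 numeric scale (loss-like classes < 1,
gain-like > 1). The absence of a mutation encodes as 1.0 — the neutral
midpoint — and multiple mutations in one gene/sample encode as the value
farthest from neutral, ties resolved toward loss; both choices are
configurable, neither being forced by the data. Clustering is agglomerative
with average linkage by default (the common plotting default) on either
Euclidean distance over the numeric features or Gower distance over the
mixed representation (categorical mismatch 0/1, numeric `|a−b|/range`,
missing features skipped with renormalization). Survival contrasts carriers
of a gene's TNBC-direction alteration against all other samples: two-group
log-rank (raw p-values, deliberately no FDR — the analysis complements the
functional evidence rather than standing alone), Kaplan–Meier curves, and a
single-covariate Cox model for the hazard ratio. lifelines provides the
estimators; tests check them against hand-computed risk-set tallies.

## Screen statistics

Eclosion = `100·empty/(uneclosed + empty)`; relative pupariation =
`100·non-tubby/tubby` (undefined for balanced stocks, and it may exceed 100);
overgrowth = labeled pixels over disc pixels. Lethality is one-sided
(experimental arm lower than the same experiment's control); a gene needs
p < 0.05 in at least two independent experiments. Tissue phenotypes are
one-sided enhancement tests, and lines whose mean does not exceed the
control mean are not tested at all. The dual criterion — p < 0.05 against
the individual experiment's controls *and* Benjamini–Hochberg FDR < 0.1 in
the aggregate across experiments — trades a small power loss for robustness
to inter-experiment drift; both parts are always recomputed from the raw
replicate measurements. Overgrowth is only consulted for
translocation-negative candidates, enforcing the assay order. Drivers are
lethality hits with at least one enhanced tissue phenotype. Reported
percentages are rounded half-up to integers, with raw fractions retained.

Two-group comparisons use Student's *t* when both groups look normal and
Mann–Whitney U otherwise. The normality gate: n ≥ 30 is parametric outright;
8 ≤ n < 30 is decided by Shapiro–Wilk at 0.05; groups below 8 observations
always take the rank test, because Shapiro–Wilk has essentially no power
there and a parametric default on 3–4 replicates would be indefensible.
Exact Mann–Whitney p-values (full enumeration) are used whenever both groups
have ≤ 10 observations; the tie-corrected normal approximation otherwise.
Drug-rescue comparisons are always Mann–Whitney against the solvent-matched
vehicle (water vs water, DMSO vs 0.1% DMSO); a solvent mismatch is an error,
not a warning.

## Synthetic data

The generator emits the statistical structure the analysis assumes, not
genome realism: no realistic segment-length distribution, recombination
hotspots, linkage between regions, or expression covariance beyond the
planted dosage coupling. What it does emulate, with defaults fixed as the
study conditions:

- **Cohort scale**: 110 TNBC among 772 primary tumors.
- **Purity**: Beta(7, 3) (mean 0.7), clipped to [0.05, 1]; 5% of samples
  report no purity, exercising the substitution rule.
- **Copy number**: per-driver carrier probability uniform on (0.3, 0.8)
  among TNBC; single-copy gains/losses (tumor fold 1.5 / 0.5); observed
  fold = `TP·t + (1 − TP)` plus N(0, 0.1) noise on the log2 scale; 2% of
  gene-sample segments are split in two so the full-coverage rule leaves the
  value missing. Clonal fraction enters through the sample-level mixture;
  within-tumor subclonality is folded into the same term, which is all the
  adjustment math can see anyway.
- **Expression**: Gaussian on the log scale (matching the z-score machinery),
  drivers coupled at 3 expression-SDs per unit of (ACN − 1), i.e. a 1.5-SD
  shift for a single-copy event; two near-constant genes exercise the SD
  filter; deleted-with-increased-expression decoys (negative coupling)
  exercise the retention drop, and an amplified-with-reduced-expression gene
  the retention keep.
- **Regions**: eight regions plus a one-gene amplification overlapping the
  first deletion's driver, covering every group-assignment path (1I, 1G, 2G,
  2I, extended-slice Group 3, Group 4). Helios scores are planted
  driver-high (0.8–1.0) vs passenger-low (0–0.3); Helios computation itself
  is an input, not reproduced.
- **Mutations**: a TP53-like gene mutated in 80% of TNBC samples; sparse
  background mutations elsewhere; classes drawn from the encodable MAF
  vocabulary.
- **Survival**: exponential baseline (rate 1/1500 per day), uniform
  administrative censoring, hazard ratio 2 planted on two drivers.
- **Screen**: two independent experiments × eight replicates (two biological
  × four flips); control eclosion 0.85, driver lethality effect −30%
  relative; tissue effects of 2 control SDs, with 70% of drivers acting
  through translocation and the rest through overgrowth only (exercising the
  conditional assay); balancer bookkeeping follows the Mendelian 1:1
  expectation scaled by experimental-arm viability.

Identical configurations (including the seed) produce byte-identical files.
Because passengers are simulated without dosage coupling and with low Helios
scores, passing the recovery tests shows that the pipeline's machinery ranks
planted signal above planted noise under these conditions — it does not show
that the same separation holds in real cohorts, where passengers ride the
same segments as their drivers and are partially dosage-coupled.

## Problem sizes and numerics

The test suite and acceptance script run at the cohort scale above: 20
simulated cohorts for recovery, 2000 simulated genes for binomial
calibration and power, 50 replicates for decoy removal, 200 replicates of
n = 200 for Cox recovery, 500 replicates of n = 60 for log-rank calibration —
sizes at which the Monte-Carlo error of each check is a small fraction of
its margin. Deterministic seeds are fixed in tests; the acceptance script
derives all randomness from its `--seed`. Degenerate inputs are flagged
rather than silently dropped: zero pupae, balanced stocks, genes never
altered, groups without events, non-convergent Cox fits.

## Known limitations

- The binomial null `p0` is an in-dataset estimate; with a cohort dominated
  by drivers the background is inflated and the filter conservative.
- The concordance test assumes approximate normality of z-scores within
  groups; it is flagged, not switched, for small groups.
- Group 3 vs 4 boundaries are operational definitions of "the remainder".
- The generator's passengers are independent of their drivers; real
  passengers are co-altered by proximity, so real-data specificity will be
  lower than the synthetic recovery numbers.
- Orthology votes treat the five resources as independent and equally
  credible; no sequence-level fallback is attempted.
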