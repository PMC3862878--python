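# Methods

This note documents the models, parameter choices and numerical decisions
behind `jellynet`, and what the synthetic-data generator does and does not
emulate.

## Tag profiling

A library is a set of collapsed tags (unique sequence, read count).
Filtering keeps lengths 18–30 nt. Classification is exact, full-length,
sense-strand sequence identity against an annotation catalog; this
replaces alignment-based annotation deliberately: it is deterministic,
dependency-free, and mirrors a perfect-match mapping policy. A tag
matching several categories is assigned by a configurable precedence
(default `known_miRNA > tRNA > other_ncRNA > genic_mRNA`), placing miRNAs
first because the analysis is miRNA-centric. A tag shared by two miRNA
genes is credited once to each gene (isoform-sum rule); this is a
documented double-counting risk, bounded by the rarity of cross-gene
identical isoforms. Composition is reported over reads, not unique tags.
Per-gene digital expression is the read sum over the gene's isoforms, with
CPM = count·10⁶/library size.

## Audic–Claverie test

With counts x (library size N₁) and y (N₂) and r = N₂/N₁, the posterior
predictive p(y|x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)) is evaluated in log
space via log-gamma. The lower tail sums k ≤ y directly; the upper tail is
1 − Σ_{k<y} with a non-negativity clamp; two-sided p = min(1, 2·min of the
tails). Two caveats discovered while validating:

* The doubled-tail two-sided p is **not** invariant under swapping the two
  libraries, even at N₁ = N₂ (the upper tail is an infinite sum; e.g.
  p(5,0) = 1/32 vs p(0,5) = 1/16). The symmetric object is the predictive
  mass itself, p(y|x) = p(x|y) at equal depths. Tests assert the mass
  identity and verify the p-value against an exact-rational oracle on the
  full small-count grid at depth ratios 0.5, 1, 2 (1e-10 agreement).
* The test is mildly conservative at small expected counts (discreteness);
  under a multinomial null with log-normal concentration spread
  (2000 features, 10⁵ tags/library) the fraction of p < 0.05 sits near
  0.04.

Fold changes are ((x+c)/N₁)/((y+c)/N₂) with pseudocount c = 0.5 so that
zero counts give finite folds. The DE rule flags a feature when the fold
magnitude exceeds 2 (either direction) and p < 0.01. BH correction is
provided throughout (the raw-threshold rule is the historical default; q
values are attached for principled multiplicity control).

## Synthetic jelly libraries

`gen_jelly_libraries` draws each library multinomially over a shared
per-sequence probability vector: category mass × within-category weight.
Worker-jelly category masses default to 51% miRNA / 17% tRNA / 6% other
ncRNA / 26% unannotated. Within the miRNA category, gene concentrations
are log-normal (σ configurable; default 2.0 spans several orders of
magnitude, matching deep-sequencing profiles where a minority of genes
carry most reads).

**Depletion parameterization.** The planted truth is defined directly on
the normalized (per-million) scale: each miRNA's true worker/royal
concentration ratio is ρᵢ = depletion_factor × jᵢ/geomean(j), with jᵢ
log-uniform on `fold_range` (default 7–215). The royal-jelly miRNA
category share is then *derived* as the worker share times the mean of
wᵢ/ρᵢ, and the remaining royal mass is split over the non-miRNA categories
in the proportions of `composition_rj`. This guarantees that the global
(median) CPM fold equals the depletion factor — the property the pipeline
estimates — rather than letting an independently fixed royal miRNA share
silently rescale every per-miRNA fold. Pleasingly, the default settings
derive a royal miRNA share of ≈2%, consistent with the composition the
defaults emulate. When `depletion_factor` is 1 an explicit
`composition_rj` is honoured verbatim (null configuration).

**What is not emulated:** sequencing error, adapter artefacts, quality
strings (libraries are post-filter tags), isomiR end-heterogeneity beyond
discrete isoforms, and cross-category sequence homology. Passing tests
therefore demonstrate correctness of the statistics on ideally-classified
tags, not robustness to mapping ambiguity.

**Recovery problem sizes.** Composition recovery is checked at 2×10⁵ tags
(binomial SE of a 0.51 fraction ≈ 0.001, so a ±0.02 margin is ≈18σ). The
20× depletion-recovery analysis also runs at 2×10⁵ tags but uses 500 miRNA
genes with abundance σ = 1.0: the median of ~300 informative
(worker count ≥ 100) per-miRNA folds is then a stable estimator
(observed spread ≈ ±15% across seeds), whereas with 77 heavy-tailed genes
the informative set itself fluctuates too much for the median to be
meaningful. The depletion factor, jitter range, library size and
informativeness filter are unchanged between the two settings.

## Target maps, network and modules

The built-in seed matcher calls an edge when the reverse complement of
miRNA positions 2–8 occurs in the 3′UTR (DNA alphabet, U→T). It is a
deterministic stand-in for alignment/energy-based target prediction;
externally computed target TSVs can be ingested instead.

The concordant-pair rule keeps a target edge iff the miRNA passes
fold ≥ 2 and p < 0.01 in the jelly comparison and the target passes the
same thresholds in the opposite direction in the larval comparison (both
thresholds configurable; the defaults reuse the DE rule). The network is
deduplicated and bipartite; node counts include only connected nodes.

MCODE is re-implemented as published: vertex weight = core level × density
of the highest k-core of the closed neighborhood; seeds in decreasing
weight (ties by node id, for determinism); expansion admits unassigned
neighbors with weight ≥ seed weight × (1 − vwp), recursively; only
vertices actually added to a complex are consumed — examined-but-rejected
neighbors stay available to later seeds; haircut removes singly-connected
module vertices; candidates below two vertices or without edges are
dropped; score = density × size. Two structural facts worth knowing:

* On a bipartite graph every closed neighborhood is a star, so the weight
  reduces to 2/(degree+1) — *decreasing* in degree. Dense bipartite blocks
  are recovered when their vertices' degrees are homogeneous; hub vertices
  (high-degree miRNAs) fall below expansion thresholds, so hub-dominated
  networks legitimately yield few modules. The co-targeting statistic is
  the sharper instrument for bipartite co-regulation.
* The weight product is not monotone under edge removal (a shrinking core
  can get denser); the core level is. The property tests reflect this.

**Co-targeting null.** miRNA i targets any given mRNA independently with
pᵢ = |Tᵢ|/N. P(one mRNA hit by ≥ k of m) is the Poisson-binomial tail,
computed by exact O(m²) dynamic programming (validated against 2^m
enumeration); the count of such mRNAs in the universe is Poisson with mean
N·p_single, and its upper tail at the observed count is the reported
significance. This independence null ignores correlated targeting (shared
seed families, UTR length bias), so its p-values are anti-conservative on
real data and should be read as a screening statistic.

## Enrichment

One-sided hypergeometric over-representation: p = P(X ≥ k) for
X ~ Hypergeom(N, K, n), with term sets intersected with the universe
first, k = 0 reported as p = 1, and BH across all tested terms. The
universe defaults to the genes of the expression table — an
expression-conditioned sampling frame, not the whole genome — because
unexpressed genes cannot enter any query set.

## Time course

Two-channel intensities are normalized on the MA scale: M = log₂ ratio,
A = mean log₂ intensity, with a LOWESS fit of M on A subtracted
(tri-cube weights; span 0.4 and 2 robustness iterations by default — the
usual two-colour microarray choice; at least 10 probes required).
Concentrations are rescaled so each miRNA's royal-jelly day-4 replicate
mean is 1; scaling is idempotent and zero references are excluded and
flagged. Day pairs (4–5, 5–6, 4–6) are compared with two-sided paired
t-tests, pairing by replicate index. Zero-variance differences degenerate
to p = 1 (all-equal) or p = 0 (constant nonzero shift — certainty below
numerical resolution).

Trend rules, evaluated in order on the day means and day-pair p-values:
persistent_increase (d5>d4, d6≥d5, 4→6 significant), transient_increase
(significant up then significant down), dip (significant down then
significant up), drop_then_stable (significant down, then 5→6 *not*
significant), persistent_fall (d5<d4, d6≤d5, 4→6 significant), else none.
drop_then_stable is tested before persistent_fall because the two overlap
whenever a stable tail samples slightly below day 5; the 5→6 significance
test is the discriminator. Calls use α = 0.05 for small qRT-PCR-style
panels and α = 0.01 for microarray-style panels (the pipeline default,
matching the default generator population).

The generated time course plants, per worker-jelly miRNA, one of the
classes in `timecourse_trends` (default 28/15/25/9 persistent-increase /
transient / dip / fall, the microarray-scale population) as multiplicative
day effects — transient: ×1.4–4.5 then ÷1.7–2.1; persistent increase:
×1.4–1.6 then ×1.05–1.15; persistent fall: ÷1.4–1.6 then ÷1.3–1.5 (no
published magnitude; chosen steep enough that a continued fall is
statistically distinguishable from a stable tail) — while every
royal-jelly series is drop-then-stable with a day-4→5 factor log-uniform
on 2.6–64. Replicate noise is multiplicative log-normal (σ = 0.05) over
6 replicates per cell; a pre-hoc power analysis at these settings puts
every planted effect at ≥ 0.999 paired-t power with a ~1% stable-tail
false-call rate, so ≥ 95% trend-call accuracy has a comfortable margin.

## Morphometrics

The summary-statistics t-test implements the classical pooled Student test
(s_p² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2), df = n₁+n₂−2; Welch available)
— the pooled form reproduces the published queen-morphometry p-values to
the printed four decimals for body length (0.0237) and wing area (0.0251),
and to within 0.0005 for birth weight (whose published SD, 0.02, is
rounded). The raw-data route computes (mean, SD, n) and delegates to the
summary route, so the two agree to machine precision by construction.
One-way ANOVA uses explicit SSB/SSW with df (k−1, N−k) and degenerate
handling (zero within-variance ⇒ p ∈ {0, 1}); Tukey HSD uses
q = |mᵢ−mⱼ|/√(MSW/2·(1/nᵢ+1/nⱼ)) with the studentized-range tail at
(k, N−k), computed by numerical integration (scipy's implementation;
agreement with its reference Tukey to 1e-8 is tested, as is the k = 2
reduction to the pooled t-test). A q-statistic-only path is exposed for
Monte-Carlo studies, where rejection via a single precomputed critical
value is equivalent to per-pair p thresholds.

The generated feeding experiment uses three groups (untreated, solvent
control, miRNA-treated; n = 57/57/64) with normal traits; control means
and SDs default to the published queen summaries where available (birth
weight 0.2355 ± 0.02 g, body length 18.07 ± 1.04 mm, wing area
20.40 ± 1.05 mm²) and realistic queen values otherwise, and the treated
group is shifted multiplicatively by the per-trait effects (−8% weight,
−5% body length, −5% wing width, −3% wing length, −7% wing area,
+3% proboscis). Note the published *summary-table* weight difference is
≈4.4%, while the 8% figure refers to a separate measured cohort whose raw
data are unavailable; the generator plants the larger per-cohort effect.

## Larval expression replay

`gen_larval_expression` plants repression of the targets of the first
planted module's miRNA group at a 3-fold factor (1/3), then draws counts
multinomially per condition. Because multinomial sampling only exposes
*relative* changes, repressing a large fraction of the transcriptome would
compress every observed ratio toward 1; restricting the repressed set to
one module's targets (~20% of genes at default sizes) and planting 3-fold
keeps the observed folds clear of the ratio > 2 rule after compositional
renormalization. This is a property of closed (library-size-normalized)
count data generally, not an artefact of the generator.

## Pipeline, determinism and problem sizes

One integer seed drives an explicit, operation-keyed RNG stream per
generator (catalog, libraries, time course, expression, morphometrics,
targets, UTRs, terms), so artifacts regenerate independently and byte
identically. The pipeline (`run_pipeline`) chains
simulate → profile → diff → network → modules → enrich → timecourse →
morpho, validates its configuration (unknown keys rejected, thresholds
range-checked), embeds the resolved configuration and seed in
`report.json`, and aborts with a stage-named error while retaining partial
outputs. Default replay sizes (2×10⁶ tags/library, 2000 mRNAs, 77 miRNA
genes) run in a few seconds; the statistical checks in
`scripts/acceptance.py` use the scaled problem sizes documented above and
complete in well under a minute.

## Known limitations

* Exact-match classification cannot express mismatch-tolerant mapping or
  genome-coordinate reasoning; novel-miRNA discovery (hairpin folding,
  conservation) is out of scope.
* The co-targeting and concordance analyses treat the target map as given;
  no attempt is made to model target-prediction error.
* The studied quantities printed by the original study that depend on the
  deposited raw libraries (absolute read totals, specific detected-gene
  counts, exact network size) are emulated structurally, not numerically.
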