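# Methods

## The analysis in one paragraph

Two case–control contrasts (obesity vs control, CRC vs control) are run
over the same whole-blood CpG methylation calls; the differentially
methylated CpGs (DMCs) and regions (DMRs) from each contrast are
intersected; overlapping features are cross-classified by direction
(hyper/hypo in each contrast) and the resulting 2×2 quadrant table is
tested for independence by χ². Overlapping DMRs are then profiled by
genomic context, filtered by subject-level rank tests, enriched against
gene sets, and spot-checked against expression in a demethylated-vs-
wild-type count matrix.

## Per-site model

Each CpG is modelled as binomial: methylated reads out of coverage, with

    logit(pi_s) = b0 + b1 * I(sample s is case) + b2 * age_s

The group term is tested by a likelihood-ratio χ² with 1 df (preferred
over Wald for small groups). Age is continuous; adding a constant to all
ages is absorbed by the intercept and provably leaves p unchanged. The
methylation difference reported is the unweighted mean of per-sample β
(case minus control, percentage points) — robust to coverage imbalance; a
coverage-weighted variant is available (`weighted_diff=True`).

The solver is a Newton/IRLS iteration vectorized across sites: all sites
share one design matrix, so thousands of 3-parameter fits reduce to a few
batched `einsum`/`solve` calls. Convergence is judged on the deviance
(relative change < 1e-8), not the coefficients: under complete separation
the coefficients diverge while the deviance — and hence the LRT statistic
— converges, so separated sites get their (tiny) LRT p rather than being
dropped; only fits whose deviance fails to stabilize are flagged and
assigned p = 1. Linear predictors are capped at ±30 and a 1e-10 ridge
stabilizes the Hessian. Agreement with an independent per-site GLM fit
(statsmodels) is 1e-6 relative or better across random fixtures.

Thresholds: a site is a DMC at |Δmeth| ≥ 10 pp and Benjamini–Hochberg
q < 0.05 over all tested sites; sites with coverage in fewer than 3
individuals in either group are not tested. BH is the multiplicity
correction throughout (the adjustment is pluggable).

Known model limitation: the binomial likelihood ignores biological
overdispersion. On beta-binomial data (the generator's default,
φ = 0.05) the caller is mildly anticonservative at the site level; the
effect-size and region-level filters absorb most of it (empirical DMR
FDR ≈ 0.05–0.10 at the standard recovery conditions), but single-site
q-values on strongly overdispersed data should be read accordingly.

## Preprocessing

* Coverage floor 5×; per-sample cap at the 99.9th percentile (linear
  interpolation, strictly-above dropped); sex chromosomes and the
  mitochondrion excluded. The percentile cap is recomputed from whatever
  data it is given, so a second application can shave at most its nominal
  0.1% tail again — the floor and chromosome filters are exactly
  idempotent.
* Between-sample coverage normalization scales each sample's coverages by
  (median of per-sample median coverages)/(own median), re-deriving
  methylated counts from the original β so methylation levels move by at
  most one read's worth of rounding.
* Histogram transformation: each case sample's β values are mapped by
  monotone quantile matching (average ranks, midpoint plotting positions)
  onto the pooled control β distribution. This equalizes marginal
  distributions to the control group by construction, preserves
  within-sample rank order exactly at the mapping level (integer count
  rounding can swap near-ties), and is applied before differential
  testing. Whether the original study transformed β or counts, per sample
  or pooled, is not documented; this choice is the package's own.

## Regions

Consecutive tested CpGs merge while gaps stay at or below a data-driven
cutoff: pooled log₁₀ nearest-neighbour distances are fit with a
two-component Gaussian mixture (inputs sorted first, so the fit is
invariant to chromosome or row order) and the cutoff is the density
crossing between the two means, falling back to 100 bp when fewer than
100 sites are available or the means sit closer than 0.2 log₁₀ units.
Region significance combines member p-values by signed Stouffer,
z = Φ⁻¹(1 − p/2)·sign(Δmeth), Z = Σz/√k — direction-inconsistent members
cancel — without a correlation correction (a documented simplification;
neighbouring CpGs are positively correlated, so region p-values are
optimistic and the printed filters, not region q, carry the inference).
Filters: ≥ 3 CpGs, ≥ 1 DMC, |mean Δmeth| > 5 pp.

## Overlap and association

DMCs overlap by exact (chrom, pos) key; DMRs by ≥ 1 bp interval
intersection with greedy one-to-one pairing (largest intersection first,
ties to the leftmost partner) — the simplest reproducible rule, with the
minimum overlap configurable. Directions are taken independently per
contrast. The χ² test of independence on the 2×2 quadrant table is
computed from the textbook Σ(O−E)²/E with 1 df, no continuity correction
by default (counts are large in the motivating use; a Yates flag exists);
a zero margin yields NaN with a warning rather than a fabricated p.

## Annotation

Promoter = [TSS − 2000, TSS) on the gene's strand; precedence
promoter > exon > intron > intergenic for spanning features; ties between
genes go to the larger intersection. Island context: island on any
overlap, shore within 2 kb, open sea otherwise (shelves are not
distinguished; UTRs collapse into exon because the toy gene models carry
no UTR boundaries). Profile similarity between feature sets is the
total-variation distance between normalized direction-by-category count
vectors — a quantitative stand-in for "which distribution the overlap set
is closer to".

## Selection and enrichment

Per subject and DMR, the methylation level is the coverage-weighted mean
Σmeth/Σcov over member CpGs (missing if none covered; a row needs ≥ 3
non-missing subjects per group to be testable). A DMR is selected when
the Kruskal–Wallis p across control/obesity/CRC and both case-vs-control
Mann–Whitney p-values are ≤ 0.1 — the marginal-significance threshold;
the phrase "at least 0.1 or less" in the source material is read as
p ≤ 0.1, and requiring both case-vs-control comparisons is the package's
reading of an unstated rule (configurable). No multiplicity correction is
applied at this stage (raw nonparametric p-values are reported). The
Mann–Whitney p is exact for groups of ≤ 8: scipy's exact distribution
when the pooled values are tie-free, an in-package permutation
enumeration (U with half-credit for ties, two-sided by symmetric
extremeness) when ties are present; larger groups use the tie-corrected
normal approximation. A second-stage filter keeps promoter/gene-body
(promoter, exon, intron) DMRs.

Enrichment uses the EASE score: with background N, term size K, query
size n and overlap k, p = P(X ≥ k − 1) for X ~ Hypergeom(N, K, n) —
Fisher's one-sided test with one overlap gene removed, so k = 1 can never
be significant. Gene-set databases are user-supplied GMT files (term
databases are version-dependent and deliberately not bundled); the
background defaults to the union of term members or the supplied
annotation's gene universe.

## Expression verification

TMM scaling factors follow the published trimmed-mean-of-M-values recipe:
reference = sample whose 75th count-proportion percentile is closest to
the mean; per sample, genes expressed in both sample and reference give
M = log₂ ratio of proportions and A = mean log₂ abundance; double trim
(30% on M, 5% on A, rank-based); factor = 2^(weighted mean M) with
inverse asymptotic binomial variances as weights; factors rescaled to
geometric mean 1. log-CPM is log₂(count/(lib·factor + 1)·10⁶ + 0.5): the
pseudocount sits on the CPM scale, which makes the transform exactly
invariant to joint count/library rescaling (a count-scale prior shifts
zero-count genes by a full log₂ unit under rescaling) and maps a zero
count in a 10⁶-read library to exactly −1. Concordance flags compare the
sign of the row-centered condition-mean difference against the direction
methylation predicts: promoter hypermethylation silences, so
demethylation should raise expression; gene-body hypermethylation tracks
expression, so demethylation should lower it. Differential-expression
testing and heteroscedasticity weighting are out of scope — row-centered
log-CPM fully determines the verification heatmap.

## Synthetic data: what it emulates, what it does not

The generator draws, per sample: coverage ~ NB(mean 30, size 8, floored
at 1); methylated counts ~ beta-binomial around a per-site level built
from a bimodal Beta mixture (45% low ~Beta(1,8), 45% high ~Beta(8,1),
10% intermediate ~Beta(5,5) — the typical RRBS shape; the motivating
study reports no per-group distribution summaries, so these defaults are
documented here, not claimed to match it), overdispersion φ = 0.05,
plus planted Δβ effects (clipped to [0.01, 0.99]) inside designated
regions and an optional age effect on the logit scale (0.002/yr, so the
caller's covariate is exercised). Group sizes and age distributions
default to the motivating cohort: 15 controls (40 ± 15 y), 10 obese
(36 ± 10 y), 15 CRC (53 ± 9 y). CpGs are laid out in clusters (~30 bp
within, ~2 kb between) so inter-CpG distances are bimodal, which is what
the DMR cutoff estimator expects. Planted regions carry a class label
(obesity-only, CRC-only, concordant hyper/hypo, discordant) that the
truth table exposes for recovery scoring, and the annotation generator
places each planted region in a known subregion and island context by
construction. One RNG stream per output (master seed + fixed offsets)
keeps artifacts individually reproducible.

Not emulated: read-level bisulfite error, sequence context, CpH
methylation, SNP interference, batch effects, and cell-composition
heterogeneity of whole blood. Passing recovery benchmarks on this
generator therefore demonstrates the statistical machinery under its
stated assumptions, not robustness to those real-data complications.

Expression counts are NB (dispersion 0.05) with per-gene log₂ fold
changes and ±20% library-size spread, emulating a two-condition,
two-replicate design.

## Problem sizes and numerical choices

Default benchmark scales, chosen to make every property measurable with
stable margins: null calibration at 5,000 sites (5 vs 5, 30×, binomial
sampling — the calibration claim concerns the GLM itself, so
overdispersion is switched off there); DMR recovery with 50 planted
regions (Δβ = 0.3, 10 per group) over 4,000 background CpGs; concordance
recovery at 1,500 overlapping sites; the smoke pipeline at 3 chromosomes
× 400 CpGs with 8 subjects per group. p-values are clipped at 1e-300
before Stouffer inversion; quantiles use linear interpolation unless
stated; BH is applied over whatever set was actually tested.

## Known limitations

Binomial (not beta-binomial) site model; Stouffer without correlation
correction; one-to-one greedy DMR pairing is order-stable but not
globally optimal; the histogram transformation assumes the control pool
is non-degenerate; EASE p-values are conservative by design; TMM factors
on fewer than ~50 expressed genes are unstable (warned).
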