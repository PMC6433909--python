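# methcrossover

Cross-contrast differential-methylation analysis for whole-blood RRBS
(reduced representation bisulfite sequencing) studies that ask whether two
conditions — here obesity and colorectal cancer (CRC) — share the same
epigenetic alterations. The package is for epigenomics analysts who have
per-sample CpG methylation calls for two case groups and a common control
group and want to quantify, test, and follow up the *overlap* between the
two case–control contrasts.

## What it computes

**Per-site calls.** For each CpG with coverage in at least 3 individuals per
group, a binomial logistic regression

&nbsp;&nbsp;&nbsp;&nbsp;logit(π) = β₀ + β₁·I(case) + β₂·age

is fit to the (methylated, unmethylated) read counts; the group effect is
tested by a likelihood-ratio χ²₁. A differentially methylated CpG (DMC)
needs |Δmeth| ≥ 10 percentage points and Benjamini–Hochberg q < 0.05.
Before testing, sites are filtered (coverage ≥ 5×, below the per-sample
99.9th percentile, autosomes only), coverage is normalized between samples,
and case β-distributions are quantile-matched to the pooled control
distribution (histogram transformation).

**Regions.** Tested CpGs are merged into differentially methylated regions
(DMRs) wherever consecutive gaps fall under a cutoff learned from the
bimodal inter-CpG distance profile (two-component Gaussian mixture on log₁₀
distances, crossing point between the modes). A DMR needs ≥ 3 CpGs, ≥ 1 DMC,
and |mean Δmeth| > 5 pp; region significance combines member p-values by a
direction-signed Stouffer z.

**Overlap and concordance.** DMCs overlapping by exact site, and DMRs by
interval intersection (greedy one-to-one pairing), are cross-classified by
direction into a 2×2 hyper/hypo quadrant table; a χ² test of independence
measures whether the two contrasts' directions are associated.

**Follow-up.** Overlapping DMRs are annotated to gene subregions
(promoter = 2 kb upstream of the TSS > exon > intron > intergenic) and
CpG-island context (island / ≤ 2 kb shore / open sea); candidate DMRs are
selected by Kruskal–Wallis across the three groups plus pairwise
Mann–Whitney U (all p ≤ 0.1, exact enumeration for small groups); their
genes are tested against gene sets with the EASE score (Fisher's exact test
with the overlap decremented by one); and expression consequences are
checked on a two-condition RNA-seq count matrix via TMM normalization and
row-centered log-CPM.

A first-class synthetic-data module generates full cohorts with
beta-binomial methylation counts, planted regions of controlled direction
concordance, toy gene models/islands, and negative-binomial expression
matrices, so every stage is exercisable and benchmarkable without access to
protected patient data.

## Worked example

`examples/03_overlap_concordance.py` re-derives the headline association
from a published study's printed counts (40,605 overlapping DMCs out of
91,809 obesity and 186,511 CRC DMCs; 36.7% hyper- and 45.2% hypomethylated
in both contrasts), then runs the same machinery end-to-end on simulated
data:

```
overlapping DMCs: 40605 = 44% of obesity DMCs
concordant fraction: 0.819
chi-square: 16391, p = 0  (association of directions)

simulated overlap: 54 sites, concordant 0.83
quadrant table (rows: obesity, cols: CRC):
B      hyper  hypo
A
hyper     25     9
hypo       0    20
```

The first block says 44% of the obesity contrast's DMCs recur in the CRC
contrast and 81.9% of those move in the same direction — a χ² of ~16,000 on
1 df, i.e. the directions are overwhelmingly associated. The second block
shows the same quadrant structure recovered from a synthetic cohort with
planted concordant regions.

The full pipeline (`examples/07_full_pipeline.py`, or
`methcrossover run-all --outdir out/`) prints, for the default smoke-scale
cohort:

```
obesity DMCs: 115, CRC DMCs: 99
overlapping DMCs: 74 (64% of obesity DMCs), concordant 91%, chi2 p = 1.1e-12
overlapping DMRs: 20, selected after rank tests: 20
expression concordance: {'agree': 15, 'disagree': 0, 'neutral': 0}
```

and writes every stage table (DMC/DMR TSVs, Venn and quadrant counts,
annotation profiles, subject-level DMR means, selection and enrichment
tables, row-centered log-CPM) plus `summary.json` to the output directory.
The other scripts in `examples/` each demonstrate one capability:
simulation, DMC/DMR calling, annotation profiles, selection + enrichment,
and expression concordance.

## Command line

A thin CLI wraps the library: `methcrossover simulate | preprocess | dmc |
dmr | overlap | annotate | select | enrich | expression | run-all`, with
`--seed`, `--config` (YAML) and per-stage options. `run-all` executes the
stages in order and is byte-reproducible for a fixed config.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator's assumptions, numerical choices, and known limitations.
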