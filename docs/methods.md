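# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Coordinates and units

All genomic intervals are 1-based inclusive; BED output converts to
0-based half-open at the file boundary (both directions are tested).
Reported positions use Mb rounded **half-up** to two decimals
(`to_mb`); interval sizes are `(end − start)/10⁶`, the convention of
published CSSL QTL tables (a zero-length interval is a single grid point).

## CSSL population model

A line is fully homozygous: the genome is recurrent-parent except for 1–3
donor segments, so dosage at any site is 0/1. Heterozygous residuals are
not modelled — substitution lines are BC₃/BC₄-derived inbreds and the
downstream statistics (half-difference additive effects, pool allele
frequencies) assume fixed genotypes.

Generator defaults: 20 chromosomes × 50 Mb with the standard soybean
Gm01–Gm20 ↔ linkage-group letter map; 208 lines; segments placed
uniformly (chromosome chosen ∝ length), lengths uniform on 8–30 Mb.
Two segments of ~19 Mb on a 1-Gb genome put ~3.8% donor genome in each
line — the introgression level of a BC₃/BC₄ program — and give every locus
an expected 7–8 carrier lines, which is what makes a single-marker scan
informative at n = 208.

## Phenotype model

`value = grand_mean + Σ_q 2·a_q·dosage + u_year + e`, with
`u_year ~ N(0, year_sd²)` drawn once per year and `e ~ N(0, resid_sd²)`
per plot. `a` is the **additive effect in the linkage-mapping
convention**: half the difference between homozygous classes, so a carrier
is shifted by 2a and the scan's `(mean₁ − mean₀)/2` estimates `a` itself.
Defaults emulate a four-year, three-replicate field trial: PH (cm)
grand mean 80, year SD 3, residual SD 5; NNMS (nodes) grand mean 15,
year SD 0.8, residual SD 1.2. Genotype-by-environment interaction is not
modelled (the year effect is a common shift).

## BLUE and heritability

The year-integration model has a single random intercept, so REML is
solved exactly by profiling the variance ratio λ = σ²_year/σ²_e: for fixed
λ the covariance is block diagonal by year and the GLS estimate and
restricted likelihood are closed-form; λ is then found by bounded scalar
search with the λ = 0 boundary checked explicitly. This avoids the
boundary non-convergence a general mixed-model optimizer can hit when the
year variance is ~0, and reduces exactly to per-line means for balanced
data. Negative variance components are clamped at zero. statsmodels
MixedLM is used in the test suite as an independent oracle (agreement
~1e-12 balanced, ~1e-5 unbalanced).

Heritability uses one-way ANOVA expected mean squares with the replicate
count r supplied by the caller (r = 3 by default in the pipeline, matching
the trial design); H² is clamped to [0, 1] and is invariant to affine
rescaling of the trait. Descriptive statistics report the n−1 SD, sample
skewness g₁ and sample excess kurtosis g₂.

## Linkage scan

Per marker, least squares for `y = μ + 2a·x + e` gives
LOD = (n/2)·log₁₀(RSS₀/RSS₁) and PVE = 100·(1 − RSS₁/RSS₀). Markers with
fewer than two lines in either dosage class are skipped. The significance
rule is LOD ≥ 2.5. Because two markers carried by the identical line set
have identical statistics, a hit's interval is the maximal run of markers
sharing the peak's carrier set. This is a single-marker likelihood-ratio
scan, not inclusive composite interval mapping: with a strong background
QTL elsewhere in the genome, markers whose carrier set happens to include
background-QTL carriers can reach nominal significance. The scan is exact
under its model (the null per-marker LOD ≥ 2.5 rate tracks the F-tail,
~0.1% at n = 208), and the pipeline's consensus stage is what filters
scan hits against the independent BSA route.

## BSA-seq / Euclidean distance

Pools: at each SNP the alt-frequency parameter of a pool equals the mean
donor dosage of its 30 member lines; total depth is Poisson(30) and the
read split multinomial. An optional symmetric sequencing-error rate
(default 0) moves reads to random bases; such reads surface as extra
observed alleles and are then caught by the multiallelic filter. Bulk
size 30 (>10% of the panel) and depth 30 are the study conditions; SNP
spacing 100 kb gives ~10⁴ sites per genome. Read-level artifacts
(alignment, duplicates, base quality) are upstream of this package and
not emulated.

Filter stack, in order: (1) multiallelic SNPs (> 2 alleles with reads);
(2) SNPs with identical pool frequency vectors (compared as exact
rationals, so depth scaling cannot break ties); (3) total depth < 5 in
either pool ("support > 4" read as total depth per pool); (4) both
members of any SNP pair < 5 bp apart; (5) SNPs < 5 bp from any indel;
(6) indels < 10 bp from another indel. Indels never enter ED. The
reported tallies partition the input exactly and the filter is
idempotent.

ED is computed on base-frequency vectors (√Σ(Δf)², range [0, √2]) and
smoothed per chromosome by LOESS — local **linear** regression with
tricube weights fitted at every SNP, span 0.1 of the chromosome's SNPs
(span is configurable; per-chromosome fitting matches how genome-scan
tracks are drawn). Chromosomes with < 10 SNPs are skipped with a warning,
and the window is widened to ≥ 3 points where the span would underflow.
The threshold is median + 3·SD (n−1) of the **fitted** values over all
chromosomes jointly — one threshold per trait, computed on the smoothed
track the intervals are called from. Candidate intervals are maximal runs
of SNPs at or above the threshold, endpoints snapped outward to a 10-kb
grid (floor/ceiling), matching the grid resolution of published BSA
tables.

**Known property: bulk-composition noise.** With 30-line bulks drawn from
208 lines carrying ~19-Mb segments, the two pools' frequency difference
under the null contains segment-scale bumps (SD ≈ 0.05) from random bulk
membership alone; these survive smoothing because they are wider than the
LOESS window. The median+3SD rule therefore calls a handful of intervals
per genome even with no causal locus (the acceptance script reports this
null rate, ~6 at depth 30, barely lower at unbounded depth). This is a
property of the design, not of the implementation; published BSA interval
tables at comparable designs show similar numbers of regions. Planted
QTLs at realistic effect sizes stand well above this background (100%
coverage for the PH-scale effect, ~80% for the weaker NNMS-scale QTL in
the acceptance runs).

## Consensus

Within a trait, linkage hits closer than 1 kb are union-merged first —
repeat detections of one substitution event across environments can be
separated by a few hundred base pairs — then intersected with every
overlapping BSA interval; the intersection (not the union) is reported,
as the tightest region consistent with both routes. Cross-trait regions
are co-location annotations: each trait's evidence is single-linkage
clustered with a 1-Mb gap, and overlapping clusters of two traits yield a
both-trait region at the intersection of the cluster spans, listing only
the evidence that overlaps it. Every consensus region carries ≥ 2
supporting intervals and each listed piece of evidence overlaps the
region (asserted invariants).

## Haplotype association and LD

Accessions of an inbred germplasm panel are grouped by exact call string
over a gene region's SNPs; any missing or heterozygous call excludes the
accession (inbred assumption — phasing is out of scope), and frequencies
are over assigned accessions. "Excellent" haplotypes are those carried by
**strictly more than** 5% of the assigned panel. Group comparison is
one-way ANOVA plus Tukey HSD at α = 0.05; compact letters are built by
insert-and-absorb, which represents the non-significance relation exactly
(two groups share a letter iff their pairwise test does not reject — this
is asserted on every call). SNPs are named by signed offset from the ATG
on the coding strand (SNP-190 = 190 bp upstream; SNP754 = 754 bp
downstream). LD uses haplotype frequencies directly: D = p₁₁ − pq,
r² = D²/(p(1−p)q(1−q)), D' = |D|/D_max with the standard case split;
monomorphic sites yield undefined (NaN) pairs and missing calls are
dropped pairwise.

## Pipeline and reproducibility

One top-level seed; each stage derives its own seed as
`(seed·1000003 + crc32(stage)) mod 2³¹`, so stage outputs do not depend on
which other stages run. Reruns are byte-identical (tested). Pooled
variants are written as VCF 4.2 with two samples (high pool first) and
GT:AD:DP fields; the BSA stage re-reads that VCF through cyvcf2, so
external pooled VCFs with AD fields are a drop-in entry point. All tables
are TSV/CSV; intervals are additionally written as BED.

Problem sizes used by the test suite and acceptance script — 50 (tests)
or 25 (script) seeded replicates at 208 lines and ~10⁴ SNPs, 8–10 null
replicates, 2000 ANOVA null replicates — were chosen to keep Monte-Carlo
error comfortably inside the asserted tolerances.

## Limitations

- Single-marker scan, no cofactor adjustment (see scan section); no
  epistasis, no genotype-by-environment interaction.
- The generator does not simulate reads, recombination/pedigree history,
  heterozygosity or functional annotation; passing tests demonstrate
  statistical correctness of the pipeline, not robustness to alignment or
  variant-calling artifacts in real pooled data.
- The published-table workflow reproduces interval arithmetic and
  consensus regions; sequencing-derived quantities of the original study
  (genome-wide SNP counts, absolute ED thresholds) depend on raw data
  that is not modelled here.
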