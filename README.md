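# soyqtl

QTL discovery for quantitative traits in **chromosome segment substitution
line (CSSL)** populations, combining two independent mapping routes:

1. a **single-segment linkage scan** over the whole panel (additive effect,
   LOD, PVE per marker), and
2. **bulked-segregant analysis by resequencing (BSA-seq)** of the two
   phenotypic extremes, scored with the per-SNP **Euclidean-distance (ED)**
   statistic,

followed by **consensus-QTL determination** (interval intersection of the
two routes) and downstream **gene-region haplotype association** with
linkage-disequilibrium analysis. The package targets plant geneticists
working with substitution-line libraries (the bundled example tables come
from a soybean study of plant height, PH, and number of nodes on the main
stem, NNMS, in a 208-line panel), but every stage is genome-agnostic.

A first-class synthetic-data generator reproduces the statistical structure
of such a study — donor segments, multi-year replicated phenotypes, extreme
bulks, pooled read depths, a 92-accession germplasm panel — so the whole
pipeline runs and is tested end to end without any external data.

## The statistics

**Phenotypes.** Line values are integrated across years with the mixed
model *y = Xβ + Zu + e* (line effects β fixed, year effects u random),
fitted by exact profile REML; the per-line fixed-effect estimates are the
BLUEs. Broad-sense heritability uses the one-way ANOVA decomposition
*H² = rσ²_g / (σ²_e + rσ²_g)* for *r* replicates, with
σ²_g = max(0, (MS_g − MS_e)/r).

**Linkage scan.** CSSLs are homozygous, so each marker is tested with
*y = μ + 2a·x + e*, x ∈ {0, 1} donor dosage. The additive effect *a* is
half the difference of the homozygous class means,
LOD = (n/2)·log₁₀(RSS₀/RSS₁) and PVE = 100·(1 − RSS₁/RSS₀); markers with
LOD ≥ 2.5 are significant, and adjacent significant markers carried by the
identical set of lines are merged into one named hit
(q + trait + linkage-group letter + serial, e.g. `qPH-j-1`).

**BSA-seq.** After a filter stack (multiallelic sites; identical pool
frequencies; total depth < 5 in either pool; SNP pairs < 5 bp apart; SNPs
< 5 bp from an indel; indel pairs < 10 bp apart), each SNP is scored with

ED = √( Σ_b (f_b,high − f_b,low)² ),  b ∈ {A, C, G, T},

where f_b is the base frequency in a pool; ED ∈ [0, √2]. Raw values are
LOESS-smoothed per chromosome (local linear, tricube weights, span 0.1)
and regions whose fitted value reaches the genome-wide threshold
**median + 3·SD** are called as candidate intervals, endpoints snapped
outward to a 10-kb grid.

**Consensus.** Within a trait, gap-merged linkage hits are intersected
with overlapping BSA intervals; regions where evidence from two traits
co-locates are additionally reported under both trait tags.

## Worked example

Consensus determination on the bundled PH/NNMS tables (linkage QTLs and
BSA intervals from the example soybean study):

```python
from soyqtl import datasets
from soyqtl.consensus import consensus, consensus_table

link = {t: datasets.load_linkage_hits(t) for t in ("PH", "NNMS")}
bsa = {t: datasets.load_bsa_candidates(t) for t in ("PH", "NNMS")}
regions = [r for r in consensus(link, bsa) if len(r.traits) == 1]
print(consensus_table(regions)[["chrom", "start_mb", "end_mb",
                                "traits", "n_support"]].to_string(index=False))
```

prints

```
chrom  start_mb  end_mb traits  n_support
 Gm04     51.17   51.25     PH          3
 Gm09     39.48   39.81     PH          2
 Gm16      3.26    3.56   NNMS          2
```

three within-trait consensus QTLs: two for plant height (the Gm04 region
supported by two merged linkage hits plus a BSA interval, the Gm09 region
by one of each) and one for node number on Gm16. An ED value by hand —
pool A 60% A / 40% G reads, pool B 30% A / 70% G:

```python
>>> from soyqtl.ed import ed
>>> round(ed((60, 0, 40, 0), (30, 0, 70, 0)), 5)   # sqrt(0.18)
0.42426
```

The full simulated pipeline, from the shell:

```bash
soyqtl run --seed 1 --out run
```

simulates a 208-line population with one planted QTL per trait
(`Gm16:32760000` at a = −7.65 for PH; `Gm09:39600000` at a = +2.0 for
NNMS), writes phenotypes, the two-pool VCFs, ED tracks, interval and
consensus tables plus a JSON manifest into `run/`, and logs the per-trait
ED thresholds (0.267 for PH, 0.175 for NNMS at this seed) and filter
tallies.

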