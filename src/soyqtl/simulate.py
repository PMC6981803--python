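"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the study design the package targets: a biparental
CSSL panel (recurrent-parent background, 1-3 homozygous donor segments per
line), multi-year replicated phenotypes under an additive genetic model with
a random year effect, two phenotypically extreme bulks, pooled sequencing
with per-base read depths, and a germplasm-panel SNP matrix for haplotype
association. Everything is deterministic for a fixed seed.

Phenotype model
---------------
``value = grand_mean + sum_q 2 * a_q * dosage(line, q) + u_year + e`` with
``u_year ~ N(0, year_sd^2)`` drawn once per year and ``e ~ N(0, resid_sd^2)``
i.i.d. per plot. ``a_q`` is the additive effect in the linkage-mapping
convention (half the difference between homozygous classes), so a carrier
line's genetic value is shifted by ``2 a_q``.

Pool model
----------
At each SNP the alt-allele frequency parameter of a pool equals the mean
donor dosage over the bulk's member lines; total depth is Poisson and the
read split binomial (a 4-way multinomial once an optional symmetric
sequencing-error rate is folded in).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import (ConfigError, CsslPopulation, DonorSegment, GenomeSpec,
                     PlantedQtl)
from .variants import BASES, PooledVariant

PHENO_COLUMNS = ("line_id", "year", "replicate", "trait", "value")


def simulate_population(genome: GenomeSpec, n_lines: int,
                        segments_per_line: Tuple[int, int] = (1, 3),
                        segment_length: Tuple[int, int] = (8_000_000,
                                                           30_000_000),
                        seed: int = 0) -> CsslPopulation:
    """Draw a CSSL panel with uniformly placed homozygous donor segments.

    Chromosomes are chosen with probability proportional to length and the
    segment start uniformly on the chromosome. Default segment sizes give
    each line roughly 2-4% donor genome, the introgression level of a
    BC3/BC4-derived substitution line.
    """
    if n_lines < 2:
        raise ConfigError("need at least 2 lines")
    lo_k, hi_k = segments_per_line
    if not (1 <= lo_k <= hi_k):
        raise ConfigError("invalid segments_per_line range")
    lo_len, hi_len = segment_length
    min_chrom = min(length for _, length in genome.chromosomes)
    if not (1 <= lo_len <= hi_len):
        raise ConfigError("invalid segment_length range")
    if hi_len >= min_chrom:
        raise ConfigError("segment length bound exceeds chromosome length")

    rng = np.random.default_rng(seed)
    lengths = np.array([length for _, length in genome.chromosomes],
                       dtype=float)
    probs = lengths / lengths.sum()
    width = max(3, len(str(n_lines)))
    lines = []
    for i in range(n_lines):
        k = int(rng.integers(lo_k, hi_k + 1))
        segs = []
        for _ in range(k):
            ci = int(rng.choice(len(lengths), p=probs))
            chrom, chrom_len = genome.chromosomes[ci]
            seg_len = int(rng.integers(lo_len, hi_len + 1))
            start = int(rng.integers(1, chrom_len - seg_len + 2))
            segs.append(DonorSegment(chrom, start, start + seg_len - 1))
        segs.sort(key=lambda s: (genome.index(s.chrom), s.start))
        lines.append((f"L{i + 1:0{width}d}", segs))
    return CsslPopulation(genome, lines)


def simulate_phenotypes(pop: CsslPopulation, qtls: Sequence[PlantedQtl],
                        years: int = 4, reps: int = 3,
                        year_sd: float = 0.0, resid_sd: float = 0.0,
                        grand_mean: float = 0.0, seed: int = 0,
                        trait: Optional[str] = None) -> pd.DataFrame:
    """Replicated multi-year phenotype records for one trait.

    Returns a long table with columns ``line_id, year, replicate, trait,
    value``. Years are labelled 1..years.
    """
    if year_sd < 0 or resid_sd < 0:
        raise ConfigError("standard deviations must be >= 0")
    if years < 1 or reps < 1:
        raise ConfigError("years and reps must be >= 1")
    traits = {q.trait for q in qtls}
    if trait is None:
        if len(traits) > 1:
            raise ConfigError("qtls span several traits; pass trait=")
        trait = next(iter(traits)) if traits else "trait"
    for q in qtls:
        if not (1 <= q.pos <= pop.genome.length(q.chrom)):
            raise ConfigError(f"QTL position {q.chrom}:{q.pos} off chromosome")

    rng = np.random.default_rng(seed)
    genetic = np.zeros(pop.n_lines)
    for q in qtls:
        dos = np.array([pop.dosage(line_id, q.chrom, q.pos)
                        for line_id in pop.line_ids], dtype=float)
        genetic += 2.0 * q.additive_effect * dos
    year_eff = rng.normal(0.0, year_sd, size=years) if year_sd > 0 \
        else np.zeros(years)
    resid = rng.normal(0.0, resid_sd, size=(pop.n_lines, years, reps)) \
        if resid_sd > 0 else np.zeros((pop.n_lines, years, reps))
    values = (grand_mean + genetic[:, None, None]
              + year_eff[None, :, None] + resid)

    line_idx, year_idx, rep_idx = np.meshgrid(
        np.arange(pop.n_lines), np.arange(years), np.arange(reps),
        indexing="ij")
    return pd.DataFrame({
        "line_id": np.asarray(pop.line_ids)[line_idx.ravel()],
        "year": year_idx.ravel() + 1,
        "replicate": rep_idx.ravel() + 1,
        "trait": trait,
        "value": values.ravel(),
    })


def select_bulks(pheno: pd.DataFrame, trait: str,
                 n_extreme: int) -> Tuple[Tuple[str, ...], Tuple[str, ...]]:
    """High and low bulks of ``n_extreme`` lines each.

    Lines are ranked by their mean phenotype across all years and
    replicates; ties are broken by line order of first appearance. The two
    bulks are disjoint by construction (requires 2*n_extreme <= lines).
    """
    sub = pheno[pheno["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    order = list(dict.fromkeys(sub["line_id"]))
    if n_extreme < 1 or 2 * n_extreme > len(order):
        raise ValueError(
            f"n_extreme={n_extreme} infeasible for {len(order)} lines")
    means = sub.groupby("line_id")["value"].mean()
    ranked = pd.DataFrame({
        "line_id": order,
        "mean": means.reindex(order).to_numpy(),
        "tiebreak": np.arange(len(order)),
    })
    high = ranked.sort_values(["mean", "tiebreak"], ascending=[False, True],
                              kind="mergesort")["line_id"].head(n_extreme)
    low = ranked.sort_values(["mean", "tiebreak"], ascending=[True, True],
                             kind="mergesort")["line_id"].head(n_extreme)
    return tuple(high), tuple(low)


@dataclass
class PoolSim:
    """Simulated pooled variants plus the generating truth.

    ``truth`` has one row per site: chrom, pos, variant_type and the
    alt-frequency parameters ``p_high``/``p_low`` (bulk-mean donor dosage)
    actually used for the read draws.
    """

    variants: List[PooledVariant]
    truth: pd.DataFrame


def _pool_depths(rng: np.random.Generator, ref_i: int, alt_i: int, p: float,
                 depth_mean: float, error_rate: float) -> np.ndarray:
    n = int(rng.poisson(depth_mean))
    probs = np.full(4, error_rate / 4.0)
    probs[ref_i] += (1.0 - p) * (1.0 - error_rate)
    probs[alt_i] += p * (1.0 - error_rate)
    return rng.multinomial(n, probs)


def simulate_pools(pop: CsslPopulation, high: Sequence[str],
                   low: Sequence[str], snp_spacing: int = 100_000,
                   depth_mean: float = 30.0, inject_clusters: int = 0,
                   inject_indels: int = 0, error_rate: float = 0.0,
                   seed: int = 0) -> PoolSim:
    """Pooled resequencing of two bulks over a genome-wide SNP grid.

    SNPs sit every ``snp_spacing`` bp. ``inject_clusters`` adds partner
    SNPs 3 bp downstream of randomly chosen grid SNPs (exercising the
    SNP-cluster filter) and ``inject_indels`` adds 2-bp deletions 4 bp
    downstream of randomly chosen grid SNPs (exercising the indel-proximity
    filter). Injected sites reuse the frequency parameter of their anchor
    grid SNP, which is 3-4 bp away and therefore inside the same segments.
    """
    if not high or not low:
        raise ValueError("bulks must be non-empty")
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    positions = {chrom: np.arange(snp_spacing, length + 1, snp_spacing,
                                  dtype=np.int64)
                 for chrom, length in pop.genome.chromosomes}
    dm = pop.dosage_matrix(positions)
    p_high = dm.loc[list(high)].mean(axis=0).to_numpy()
    p_low = dm.loc[list(low)].mean(axis=0).to_numpy()
    site_chrom = [c.split(":")[0] for c in dm.columns]
    site_pos = np.array([int(c.split(":")[1]) for c in dm.columns])

    # (chrom, pos, is_indel, p_high, p_low)
    sites: List[Tuple[str, int, bool, float, float]] = [
        (c, int(p), False, float(ph), float(pl))
        for c, p, ph, pl in zip(site_chrom, site_pos, p_high, p_low)]
    n_grid = len(sites)
    if inject_clusters + inject_indels > n_grid:
        raise ValueError("more injections than grid SNPs")
    anchor = rng.choice(n_grid, size=inject_clusters + inject_indels,
                        replace=False)
    for i in anchor[:inject_clusters]:
        c, p, _, ph, pl = sites[i]
        sites.append((c, p + 3, False, ph, pl))
    for i in anchor[inject_clusters:]:
        c, p, _, ph, pl = sites[i]
        sites.append((c, p + 4, True, ph, pl))

    key = {c: i for i, c in enumerate(pop.genome.names)}
    sites.sort(key=lambda s: (key[s[0]], s[1]))

    variants: List[PooledVariant] = []
    rows = []
    for chrom, pos, is_indel, ph, pl in sites:
        if is_indel:
            base = BASES[int(rng.integers(4))]
            ref, alt = base + "TA", base
            nh = int(rng.poisson(depth_mean))
            nl = int(rng.poisson(depth_mean))
            ah = int(rng.binomial(nh, ph))
            al = int(rng.binomial(nl, pl))
            variants.append(PooledVariant(
                chrom, pos, ref, (alt,), (nh - ah, ah), (nl - al, al)))
        else:
            ref_i = int(rng.integers(4))
            alt_i = int((ref_i + 1 + rng.integers(3)) % 4)
            dh = _pool_depths(rng, ref_i, alt_i, ph, depth_mean, error_rate)
            dl = _pool_depths(rng, ref_i, alt_i, pl, depth_mean, error_rate)
            observed = [i for i in range(4)
                        if i != ref_i and dh[i] + dl[i] > 0]
            # keep the designed alt first so biallelic sites stay (ref, alt)
            alts_i = [alt_i] + [i for i in observed if i != alt_i]
            alts = tuple(BASES[i] for i in alts_i)
            variants.append(PooledVariant(
                chrom, pos, BASES[ref_i], alts,
                tuple(int(dh[i]) for i in [ref_i] + alts_i),
                tuple(int(dl[i]) for i in [ref_i] + alts_i)))
        rows.append((chrom, pos, "indel" if is_indel else "snp", ph, pl))

    truth = pd.DataFrame(rows, columns=["chrom", "pos", "variant_type",
                                        "p_high", "p_low"])
    return PoolSim(variants, truth)


# ---------------------------------------------------------------------------
# Germplasm panel for haplotype association


@dataclass
class GermplasmSim:
    """A gene-region SNP matrix over a germplasm panel plus phenotypes.

    ``calls``: accessions x sites, values 0 (ref), 1 (alt), -1 (missing).
    ``sites``: per-site metadata (name, offset from ATG, ref, alt).
    ``trait``: per-accession phenotype; the causal site contributes
    ``effect`` per alt allele.
    """

    calls: pd.DataFrame
    sites: pd.DataFrame
    trait: pd.Series
    causal_site: str


def simulate_germplasm(n_accessions: int = 92, n_sites: int = 12,
                       n_haplotypes: int = 6, causal_index: int = 0,
                       effect: float = 6.0, trait_mean: float = 100.0,
                       trait_sd: float = 5.0, missing_rate: float = 0.02,
                       seed: int = 0) -> GermplasmSim:
    """Inbred germplasm accessions drawn from a few founder haplotypes."""
    if n_haplotypes < 2 or n_sites < 1:
        raise ConfigError("need >=2 haplotypes and >=1 site")
    rng = np.random.default_rng(seed)

    while True:
        haps = rng.integers(0, 2, size=(n_haplotypes, n_sites))
        if len({tuple(h) for h in haps}) == n_haplotypes and \
                haps[:, causal_index].min() != haps[:, causal_index].max():
            break
    freqs = rng.dirichlet(np.full(n_haplotypes, 1.5))
    assignment = rng.choice(n_haplotypes, size=n_accessions, p=freqs)
    calls = haps[assignment].astype(np.int8)
    missing = rng.random(calls.shape) < missing_rate
    calls = np.where(missing, -1, calls)

    offsets = np.sort(rng.choice(
        np.concatenate([np.arange(-3000, 0), np.arange(1, 2001)]),
        size=n_sites, replace=False))
    site_names = [f"SNP{o}" for o in offsets]
    ref_alt = []
    for _ in range(n_sites):
        i = int(rng.integers(4))
        j = int((i + 1 + rng.integers(3)) % 4)
        ref_alt.append((BASES[i], BASES[j]))
    sites = pd.DataFrame({
        "site": site_names,
        "offset": offsets,
        "ref": [r for r, _ in ref_alt],
        "alt": [a for _, a in ref_alt],
    })

    acc = [f"GP{i + 1:03d}" for i in range(n_accessions)]
    causal = haps[assignment, causal_index].astype(float)
    trait = pd.Series(trait_mean + effect * causal
                      + rng.normal(0.0, trait_sd, n_accessions),
                      index=acc, name="trait")
    calls_df = pd.DataFrame(calls, index=acc, columns=site_names)
    return GermplasmSim(calls_df, sites, trait, site_names[causal_index])
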