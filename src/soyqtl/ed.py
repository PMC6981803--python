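"""BSA-seq Euclidean-distance stage: filtering, ED, LOESS, intervals.

The per-SNP statistic is the Euclidean distance between the two pools'
base-frequency vectors,

``ED = sqrt(sum_b (f_b,high - f_b,low)^2)``, b in {A, C, G, T},

which ranges from 0 (identical pools) to sqrt(2) (fixed opposite alleles).
Raw ED values are smoothed per chromosome by LOESS (local linear
regression, tricube weights) and candidate regions are maximal runs of
SNPs whose fitted value reaches the genome-wide threshold
``median + 3 * SD`` of the fitted values, with endpoints snapped outward to
a 10-kb grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import GenomeSpec
from .variants import PooledVariant


@dataclass
class FilterReport:
    """Per-rule tallies of the variant filter stack.

    ``retained`` counts SNPs entering the ED statistic; ``indel_not_scored``
    counts indels that survive the adjacent-indel rule but (being indels)
    never enter ED. All categories sum to the input count.
    """

    n_input: int = 0
    multiallelic: int = 0
    identical_genotype: int = 0
    low_depth: int = 0
    snp_cluster: int = 0
    near_indel: int = 0
    adjacent_indel: int = 0
    indel_not_scored: int = 0
    retained: int = 0

    @property
    def removed(self) -> int:
        return (self.multiallelic + self.identical_genotype + self.low_depth
                + self.snp_cluster + self.near_indel + self.adjacent_indel
                + self.indel_not_scored)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_input", "multiallelic", "identical_genotype", "low_depth",
            "snp_cluster", "near_indel", "adjacent_indel",
            "indel_not_scored", "retained")}


def _check_sorted(variants: Sequence[PooledVariant]) -> None:
    seen: List[str] = []
    last_pos = None
    for v in variants:
        if not seen or v.chrom != seen[-1]:
            if v.chrom in seen:
                raise ValueError("variants not sorted: chromosome blocks "
                                 f"interleaved at {v.chrom}:{v.pos}")
            seen.append(v.chrom)
            last_pos = v.pos
        elif last_pos is not None and v.pos < last_pos:
            raise ValueError(f"variants not sorted at {v.chrom}:{v.pos}")
        else:
            last_pos = v.pos


def _identical_pools(v: PooledVariant) -> bool:
    th, tl = v.depth_high, v.depth_low
    if th == 0 or tl == 0:
        return False  # undefined frequencies; the depth rule handles these
    return all(h * tl == l * th
               for h, l in zip(v.allele_depths_high, v.allele_depths_low))


def filter_variants(variants: Sequence[PooledVariant], min_depth: int = 5,
                    cluster_bp: int = 5, indel_prox_bp: int = 5,
                    indel_pair_bp: int = 10
                    ) -> Tuple[List[PooledVariant], FilterReport]:
    """Apply the SNP quality-filter stack in its documented order.

    Rules, applied sequentially to position-sorted input:

    1. SNPs with more than two observed alleles are removed (multiallelic).
    2. SNPs whose pool frequency vectors are identical are removed
       (uninformative for a bulk contrast).
    3. SNPs with total depth < ``min_depth`` in either pool are removed.
    4. Both members of any surviving SNP pair closer than ``cluster_bp``
       are removed (SNP clusters are alignment-artifact prone).
    5. SNPs closer than ``indel_prox_bp`` to any input indel are removed.
    6. Indels closer than ``indel_pair_bp`` to another indel are removed;
       the remaining indels are reported but never scored by ED.

    Returns the retained SNPs and a per-rule :class:`FilterReport`.
    """
    variants = list(variants)
    _check_sorted(variants)
    report = FilterReport(n_input=len(variants))

    snps = [v for v in variants if v.variant_type == "snp"]
    indels = [v for v in variants if v.variant_type == "indel"]

    kept = []
    for v in snps:
        if v.n_observed_alleles() > 2:
            report.multiallelic += 1
        else:
            kept.append(v)
    snps = kept

    kept = []
    for v in snps:
        if _identical_pools(v):
            report.identical_genotype += 1
        else:
            kept.append(v)
    snps = kept

    kept = []
    for v in snps:
        if v.depth_high < min_depth or v.depth_low < min_depth:
            report.low_depth += 1
        else:
            kept.append(v)
    snps = kept

    in_cluster = set()
    for a, b in zip(snps, snps[1:]):
        if a.chrom == b.chrom and b.pos - a.pos < cluster_bp:
            in_cluster.add(id(a))
            in_cluster.add(id(b))
    report.snp_cluster = len([v for v in snps if id(v) in in_cluster])
    snps = [v for v in snps if id(v) not in in_cluster]

    indel_pos = {}
    for v in indels:
        indel_pos.setdefault(v.chrom, []).append(v.pos)
    kept = []
    for v in snps:
        near = any(abs(v.pos - p) < indel_prox_bp
                   for p in indel_pos.get(v.chrom, ()))
        if near:
            report.near_indel += 1
        else:
            kept.append(v)
    snps = kept

    for v in indels:
        others = [p for p in indel_pos[v.chrom] if p != v.pos]
        if any(abs(v.pos - p) < indel_pair_bp for p in others):
            report.adjacent_indel += 1
        else:
            report.indel_not_scored += 1

    report.retained = len(snps)
    assert report.removed + report.retained == report.n_input
    return snps, report


def ed(depths_a: Sequence[int], depths_b: Sequence[int]) -> float:
    """Euclidean distance between two pools' base-frequency vectors."""
    a = np.asarray(depths_a, dtype=float)
    b = np.asarray(depths_b, dtype=float)
    if a.shape != (4,) or b.shape != (4,):
        raise ValueError("expected (A, C, G, T) count vectors")
    ta, tb = a.sum(), b.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("zero pool depth (filter before scoring)")
    return float(np.sqrt(((a / ta - b / tb) ** 2).sum()))


def ed_frame(snps: Sequence[PooledVariant],
             genome: Optional[GenomeSpec] = None) -> pd.DataFrame:
    """Per-SNP raw ED values as a (chrom, pos, ed_raw) table."""
    rows = [(v.chrom, v.pos, ed(v.base_depths_high, v.base_depths_low))
            for v in snps]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ed_raw"])
    if genome is not None:
        order = {c: i for i, c in enumerate(genome.names)}
        df = df.sort_values(["chrom", "pos"],
                            key=lambda s: s.map(order) if s.name == "chrom"
                            else s).reset_index(drop=True)
    return df


def fit_loess(frame: pd.DataFrame, span: float = 0.1,
              min_points: int = 10) -> pd.DataFrame:
    """LOESS-smooth raw ED along each chromosome.

    Local linear regression with tricube weights (span = fraction of the
    chromosome's SNPs per window), fitted at every SNP position.
    Chromosomes with fewer than ``min_points`` SNPs are skipped with a
    warning (fitted value NaN).
    """
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    out = frame.copy()
    out["ed_fitted"] = np.nan
    for chrom, grp in frame.groupby("chrom", sort=False):
        n = len(grp)
        if n < min_points:
            warnings.warn(f"chromosome {chrom}: only {n} SNPs, "
                          "skipped by LOESS", stacklevel=2)
            continue
        frac = max(span, 3.0 / n)  # a local line needs >= 3 points
        fitted = lowess(grp["ed_raw"].to_numpy(),
                        grp["pos"].to_numpy(dtype=float),
                        frac=frac, it=0, delta=0.0, return_sorted=False)
        out.loc[grp.index, "ed_fitted"] = fitted
    return out


def ed_threshold(fitted: Iterable[float], n_sd: float = 3.0) -> float:
    """Genome-wide significance threshold: median + n_sd * SD (ddof=1)."""
    x = np.asarray(list(fitted), dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need >= 2 fitted values")
    return float(np.median(x) + n_sd * x.std(ddof=1))


@dataclass(frozen=True)
class CandidateInterval:
    """A BSA candidate region (1-based inclusive, grid-snapped)."""

    chrom: str
    start: int
    end: int
    peak_fitted: float
    n_snps: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start > end")


def call_intervals(frame: pd.DataFrame, threshold: float,
                   grid_bp: int = 10_000) -> List[CandidateInterval]:
    """Maximal runs of SNPs with fitted ED >= threshold, snapped to a grid.

    Run endpoints are snapped outward: start floored and end ceiled to the
    ``grid_bp`` grid (a single-SNP run on a grid point degenerates to a
    zero-length interval, as published BSA tables occasionally show).
    """
    out: List[CandidateInterval] = []
    for chrom, grp in frame.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        fit = grp["ed_fitted"].to_numpy()
        above = np.isfinite(fit) & (fit >= threshold)
        j = 0
        while j < len(pos):
            if not above[j]:
                j += 1
                continue
            k = j
            while k + 1 < len(pos) and above[k + 1]:
                k += 1
            start = max(1, int(pos[j] // grid_bp) * grid_bp)
            end = int(-(-pos[k] // grid_bp) * grid_bp)
            out.append(CandidateInterval(
                chrom=chrom, start=start, end=end,
                peak_fitted=float(np.nanmax(fit[j:k + 1])),
                n_snps=int(k - j + 1)))
            j = k + 1
    return out


def intervals_table(intervals: Sequence[CandidateInterval]) -> pd.DataFrame:
    from .intervals import interval_size_mb
    return pd.DataFrame([{
        "name": iv.name or "",
        "chrom": iv.chrom,
        "start_bp": iv.start,
        "end_bp": iv.end,
        "size_mb": interval_size_mb(iv),
        "peak_fitted": iv.peak_fitted,
        "n_snps": iv.n_snps,
    } for iv in intervals])
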