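"""Pooled-variant container and VCF I/O.

A :class:`PooledVariant` holds per-allele read depths for two sequenced
bulks (the "high" and "low" phenotype pools of a bulked-segregant design).
For SNPs the allele depths map onto (A, C, G, T) base-depth vectors, which
is the input of the Euclidean-distance statistic.

VCF 4.2 is written with two pool samples and GT:AD:DP genotype fields and
read back with cyvcf2; base depths are reconstructed from the AD field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genome import GenomeSpec

BASES: Tuple[str, ...] = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PooledVariant:
    """One variant site with per-pool allele depths.

    ``allele_depths_*`` are read counts aligned to ``(ref,) + alts``.
    """

    chrom: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    allele_depths_high: Tuple[int, ...]
    allele_depths_low: Tuple[int, ...]

    def __post_init__(self) -> None:
        n_alleles = 1 + len(self.alts)
        for depths in (self.allele_depths_high, self.allele_depths_low):
            if len(depths) != n_alleles:
                raise ValueError("allele depths do not match allele count")
            if any(d < 0 for d in depths):
                raise ValueError("negative read depth")

    @property
    def alleles(self) -> Tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def variant_type(self) -> str:
        if len(self.ref) == 1 and all(len(a) == 1 for a in self.alts):
            return "snp"
        return "indel"

    @property
    def depth_high(self) -> int:
        return int(sum(self.allele_depths_high))

    @property
    def depth_low(self) -> int:
        return int(sum(self.allele_depths_low))

    def n_observed_alleles(self) -> int:
        """Alleles with at least one read in either pool."""
        return sum(1 for h, l in zip(self.allele_depths_high,
                                     self.allele_depths_low) if h + l > 0)

    def _base_depths(self, depths: Tuple[int, ...]) -> Tuple[int, int, int, int]:
        if self.variant_type != "snp":
            raise ValueError("base depths are defined for SNPs only")
        out = [0, 0, 0, 0]
        for allele, d in zip(self.alleles, depths):
            out[BASES.index(allele)] += d
        return tuple(out)  # type: ignore[return-value]

    @property
    def base_depths_high(self) -> Tuple[int, int, int, int]:
        """(A, C, G, T) read counts in the high pool."""
        return self._base_depths(self.allele_depths_high)

    @property
    def base_depths_low(self) -> Tuple[int, int, int, int]:
        return self._base_depths(self.allele_depths_low)


def sort_variants(variants: Iterable[PooledVariant],
                  genome: Optional[GenomeSpec] = None) -> List[PooledVariant]:
    """Sort by (chromosome, position); genome order if a genome is given."""
    variants = list(variants)
    if genome is not None:
        key = {c: i for i, c in enumerate(genome.names)}
    else:
        order: List[str] = []
        for v in variants:
            if v.chrom not in order:
                order.append(v.chrom)
        key = {c: i for i, c in enumerate(sorted(order))}
    return sorted(variants, key=lambda v: (key[v.chrom], v.pos))


# ---------------------------------------------------------------------------
# VCF I/O

_HEADER = """\
##fileformat=VCFv4.2
##source=soyqtl
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
"""


def write_vcf(variants: Sequence[PooledVariant], path,
              genome: Optional[GenomeSpec] = None,
              sample_high: str = "HIGH_BULK",
              sample_low: str = "LOW_BULK") -> None:
    """Write a two-sample VCF 4.2; the first sample is the high pool."""
    with open(path, "w") as fh:
        fh.write(_HEADER)
        if genome is not None:
            for name, length in genome.chromosomes:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_high}\t{sample_low}\n")
        for v in variants:
            alt = ",".join(v.alts) if v.alts else "."
            sh = "./.:{}:{}".format(
                ",".join(str(d) for d in v.allele_depths_high), v.depth_high)
            sl = "./.:{}:{}".format(
                ",".join(str(d) for d in v.allele_depths_low), v.depth_low)
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{alt}\t.\tPASS\t.\t"
                     f"GT:AD:DP\t{sh}\t{sl}\n")


def read_vcf(path) -> List[PooledVariant]:
    """Read a two-sample pooled VCF (high pool first) written by this package
    or any caller providing per-sample AD fields."""
    from cyvcf2 import VCF

    out: List[PooledVariant] = []
    vcf = VCF(str(path))
    try:
        if len(vcf.samples) != 2:
            raise ValueError(
                f"expected 2 pool samples, found {len(vcf.samples)}")
        for rec in vcf:
            ad = rec.format("AD")
            if ad is None:
                raise ValueError(f"missing AD at {rec.CHROM}:{rec.POS}")
            ad = np.clip(np.asarray(ad, dtype=np.int64), 0, None)
            out.append(PooledVariant(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF,
                alts=tuple(rec.ALT),
                allele_depths_high=tuple(int(x) for x in ad[0]),
                allele_depths_low=tuple(int(x) for x in ad[1])))
    finally:
        vcf.close()
    return out
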