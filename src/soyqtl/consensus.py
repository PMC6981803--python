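"""Consensus QTL determination from linkage-scan and BSA evidence.

A within-trait consensus region is the intersection of a (gap-merged)
linkage-QTL region with an overlapping BSA candidate interval: the locus is
supported by two independent mapping routes, and the intersection is the
tightest interval consistent with both.

Cross-trait regions are co-location annotations: per chromosome, each
trait's evidence is clustered with a generous gap, and wherever clusters of
two traits overlap the intersection of the cluster spans is reported with
both trait tags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .ed import CandidateInterval
from .intervals import (Interval, as_interval, intersect, interval_size_mb,
                        merge_with_members, to_bed_interval, to_mb)
from .scan import QtlHit


@dataclass(frozen=True)
class ConsensusQtl:
    """A region supported by >= 2 pieces of mapping evidence.

    ``evidence`` is a tuple of ``(identifier, method)`` pairs with method
    "linkage" or "bsa"; every evidence interval overlaps [start, end].
    """

    chrom: str
    start: int
    end: int
    traits: Tuple[str, ...]
    evidence: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("consensus interval start > end")
        if len(self.evidence) < 2:
            raise ValueError("consensus needs >= 2 supporting intervals")

    @property
    def n_support(self) -> int:
        return len(self.evidence)


def _ident(obj) -> str:
    name = getattr(obj, "name", None)
    if name:
        return str(name)
    iv = as_interval(obj)
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def consensus(linkage: Mapping[str, Sequence[QtlHit]],
              bsa: Mapping[str, Sequence[CandidateInterval]],
              gap_bp: int = 1000, cross_trait: bool = True,
              cross_gap_bp: int = 1_000_000) -> List[ConsensusQtl]:
    """Combine linkage hits and BSA intervals into consensus QTLs.

    Within each trait, linkage hits closer than ``gap_bp`` are first merged
    (repeat detections of one substitution event across environments), then
    intersected with every overlapping BSA interval. With ``cross_trait``,
    co-locating evidence clusters (single-linkage, ``cross_gap_bp``) from
    two traits are additionally reported under both trait tags.
    """
    out: List[ConsensusQtl] = []
    traits = sorted(set(linkage) | set(bsa))

    for trait in traits:
        hits = list(linkage.get(trait, ()))
        cands = list(bsa.get(trait, ()))
        for region, members in merge_with_members(hits, gap_bp=gap_bp):
            for cand in cands:
                inter = intersect(region, cand)
                if inter is None:
                    continue
                evidence = tuple([(_ident(h), "linkage") for h in members]
                                 + [(_ident(cand), "bsa")])
                out.append(ConsensusQtl(inter.chrom, inter.start, inter.end,
                                        (trait,), evidence))

    if cross_trait:
        clusters: Dict[str, List[Tuple[Interval, list]]] = {}
        for trait in traits:
            items = list(linkage.get(trait, ())) + list(bsa.get(trait, ()))
            clusters[trait] = merge_with_members(items, gap_bp=cross_gap_bp)
        for i, t1 in enumerate(traits):
            for t2 in traits[i + 1:]:
                for span1, mem1 in clusters[t1]:
                    for span2, mem2 in clusters[t2]:
                        inter = intersect(span1, span2)
                        if inter is None:
                            continue
                        # only evidence overlapping the co-located region
                        keep1 = [m for m in mem1
                                 if intersect(m, inter) is not None]
                        keep2 = [m for m in mem2
                                 if intersect(m, inter) is not None]
                        if not keep1 or not keep2:
                            continue
                        evidence = tuple(
                            [(_ident(m), _method(m)) for m in keep1]
                            + [(_ident(m), _method(m)) for m in keep2])
                        out.append(ConsensusQtl(
                            inter.chrom, inter.start, inter.end,
                            (t1, t2), evidence))

    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.traits))
    return out


def _method(obj) -> str:
    return "bsa" if isinstance(obj, CandidateInterval) else "linkage"


def consensus_table(regions: Sequence[ConsensusQtl]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": c.chrom,
        "start_bp": c.start,
        "end_bp": c.end,
        "start_mb": to_mb(c.start),
        "end_mb": to_mb(c.end),
        "size_mb": interval_size_mb(c),
        "traits": "+".join(c.traits),
        "n_support": c.n_support,
        "evidence": ";".join(f"{i}({m})" for i, m in c.evidence),
    } for c in regions])


def consensus_bed(regions: Sequence[ConsensusQtl], path) -> None:
    """Write consensus regions as BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for c in regions:
            chrom, start, end = to_bed_interval(c)
            fh.write(f"{chrom}\t{start}\t{end}\t"
                     f"{'+'.join(c.traits)}\t{c.n_support}\n")
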