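"""Genomic interval algebra.

All intervals carried by the library are 1-based inclusive. BED output is
0-based half-open; :func:`to_bed_interval` / :func:`from_bed_interval`
convert at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import List, Optional, Sequence, Tuple


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"empty interval {self.chrom}:"
                             f"{self.start}-{self.end}")

    @property
    def span_bp(self) -> int:
        """end - start, the convention behind published "Size (Mb)" columns."""
        return self.end - self.start


def as_interval(obj) -> Interval:
    """Coerce anything with chrom/start/end attributes to an Interval."""
    if isinstance(obj, Interval):
        return obj
    return Interval(obj.chrom, int(obj.start), int(obj.end))


def intersect(a, b) -> Optional[Interval]:
    """Intersection of two 1-based inclusive intervals, or None.

    Intervals on different chromosomes never intersect.
    """
    a, b = as_interval(a), as_interval(b)
    if a.chrom != b.chrom:
        return None
    lo, hi = max(a.start, b.start), min(a.end, b.end)
    if lo > hi:
        return None
    return Interval(a.chrom, lo, hi)


def merge_with_members(items: Sequence, gap_bp: int = 1000
                       ) -> List[Tuple[Interval, list]]:
    """Union-merge intervals whose gap is <= gap_bp, keeping member lists.

    The gap between ``[.., e]`` and ``[s, ..]`` is ``s - e`` (adjacent
    intervals have gap 1, so gap_bp=0 merges only true overlaps). Input may
    be unsorted; output is sorted by (chrom, start) with chromosomes in
    lexical order, so the result is independent of input order.
    """
    ordered = sorted(items, key=lambda it: (as_interval(it).chrom,
                                            as_interval(it).start,
                                            as_interval(it).end))
    merged: List[Tuple[Interval, list]] = []
    for it in ordered:
        iv = as_interval(it)
        if merged:
            cur, members = merged[-1]
            if cur.chrom == iv.chrom and iv.start - cur.end <= gap_bp:
                merged[-1] = (Interval(cur.chrom, cur.start,
                                       max(cur.end, iv.end)),
                              members + [it])
                continue
        merged.append((iv, [it]))
    return merged


def merge(intervals: Sequence, gap_bp: int = 1000) -> List[Interval]:
    """As :func:`merge_with_members`, returning intervals only."""
    return [iv for iv, _ in merge_with_members(intervals, gap_bp)]


def _round2(x: Decimal) -> float:
    return float(x.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def to_mb(pos: int) -> float:
    """Position in Mb, rounded half-up to 2 decimals (reporting convention)."""
    if pos < 0:
        raise ValueError("position must be >= 0")
    return _round2(Decimal(int(pos)) / Decimal(1_000_000))


def interval_size_mb(obj) -> float:
    """(end - start) / 1e6 rounded half-up to 2 decimals."""
    iv = as_interval(obj)
    return _round2(Decimal(int(iv.span_bp)) / Decimal(1_000_000))


def interval_size_kb(obj) -> float:
    """(end - start) / 1e3 rounded half-up to 2 decimals."""
    iv = as_interval(obj)
    return _round2(Decimal(int(iv.span_bp)) / Decimal(1_000))


def to_bed_interval(obj) -> Tuple[str, int, int]:
    """1-based inclusive -> BED 0-based half-open."""
    iv = as_interval(obj)
    return (iv.chrom, iv.start - 1, iv.end)


def from_bed_interval(chrom: str, start: int, end: int) -> Interval:
    """BED 0-based half-open -> 1-based inclusive."""
    if start < 0 or end <= start:
        raise ValueError(f"invalid BED interval {chrom}:{start}-{end}")
    return Interval(chrom, start + 1, end)
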