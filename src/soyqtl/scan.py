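"""Single-segment QTL scan for homozygous CSSL panels.

Each marker is tested with the least-squares model ``y = mu + 2 a x + e``
(x = donor dosage in {0, 1}), so the additive effect ``a`` is half the
difference between the homozygous class means. The test statistic is

``LOD = (n/2) * log10(RSS0 / RSS1)``,   ``PVE = 100 * (1 - RSS1 / RSS0)``

with RSS0 the null (mean-only) and RSS1 the full-model residual sum of
squares. Adjacent significant markers carried by the identical set of lines
are one physical substitution event and are merged into a single hit whose
interval spans the shared marker run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import ConfigError, CsslPopulation
from .intervals import interval_size_mb as _interval_size_mb

logger = logging.getLogger(__name__)


@dataclass
class QtlHit:
    """One scan hit: named interval with LOD, PVE and additive effect."""

    trait: str
    chrom: str
    start: int
    end: int
    lod: float
    pve: float
    additive: float
    peak_pos: int
    n_carriers: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("hit interval start > end")
        if self.lod < 0 or not (0.0 <= self.pve <= 100.0):
            raise ValueError("invalid LOD/PVE")


def interval_size_mb(hit) -> float:
    """(end - start)/1e6, half-up to 2 dp (published table convention)."""
    return _interval_size_mb(hit)


def genotype_matrix(pop: CsslPopulation,
                    marker_positions: Mapping[str, Sequence[int]]
                    ) -> pd.DataFrame:
    """Lines x markers donor-dosage matrix (columns ``chrom:pos``)."""
    return pop.dosage_matrix(marker_positions)


def marker_grid(pop: CsslPopulation,
                spacing: int = 1_000_000) -> Dict[str, np.ndarray]:
    """Evenly spaced marker positions over every chromosome."""
    return {chrom: np.arange(spacing, length + 1, spacing, dtype=np.int64)
            for chrom, length in pop.genome.chromosomes}


def marker_stats(geno: np.ndarray, y: np.ndarray,
                 min_class: int = 2) -> pd.DataFrame:
    """Vectorized per-marker least-squares statistics.

    Returns one row per marker: class counts, additive effect, RSS0/RSS1,
    LOD, PVE and a ``testable`` flag (>= min_class lines in each dosage
    class and non-degenerate phenotype).
    """
    G = np.asarray(geno, dtype=float)
    y = np.asarray(y, dtype=float)
    if G.ndim != 2 or G.shape[0] != len(y):
        raise ValueError("genotype matrix and phenotype vector misaligned")
    n = len(y)
    sy, syy = y.sum(), (y ** 2).sum()
    n1 = G.sum(axis=0)
    n0 = n - n1
    s1 = G.T @ y
    s0 = sy - s1
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = np.where(n1 > 0, s1 / np.maximum(n1, 1), np.nan)
        m0 = np.where(n0 > 0, s0 / np.maximum(n0, 1), np.nan)
    rss0 = syy - sy ** 2 / n
    rss1 = (syy - np.where(n1 > 0, s1 ** 2 / np.maximum(n1, 1), 0.0)
            - np.where(n0 > 0, s0 ** 2 / np.maximum(n0, 1), 0.0))
    rss1 = np.maximum(rss1, 0.0)
    testable = (n1 >= min_class) & (n0 >= min_class) & (rss0 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = np.where(rss1 > 0, (n / 2.0) * np.log10(rss0 / rss1), np.inf)
        pve = 100.0 * (1.0 - rss1 / rss0)
    lod = np.where(testable, np.maximum(lod, 0.0), np.nan)
    pve = np.where(testable, np.clip(pve, 0.0, 100.0), np.nan)
    return pd.DataFrame({
        "n1": n1.astype(int), "n0": n0.astype(int),
        "additive": (m1 - m0) / 2.0,
        "rss0": rss0, "rss1": rss1, "lod": lod, "pve": pve,
        "testable": testable,
    })


def _parse_columns(columns) -> Tuple[List[str], np.ndarray]:
    chroms, pos = [], []
    for c in columns:
        chrom, p = c.rsplit(":", 1)
        chroms.append(chrom)
        pos.append(int(p))
    return chroms, np.asarray(pos, dtype=np.int64)


def scan(geno: pd.DataFrame, y: pd.Series, lod_threshold: float = 2.5,
         min_class: int = 2, trait: str = "trait") -> List[QtlHit]:
    """Genome scan over a dosage matrix; returns unnamed hits in genome order.

    Markers with fewer than ``min_class`` lines in either dosage class
    (including monomorphic markers) are skipped. Consecutive significant
    markers with the identical carrier-line set are merged into one hit;
    the hit interval spans the run and its statistics are those of the
    shared (identical) marker model.
    """
    y = y.reindex(geno.index)
    if y.isna().any():
        raise ValueError("phenotype missing for some lines in the matrix")
    stats = marker_stats(geno.to_numpy(), y.to_numpy(), min_class=min_class)
    chroms, pos = _parse_columns(geno.columns)
    n_skipped = int((~stats["testable"]).sum())
    if n_skipped:
        logger.debug("skipped %d untestable/monomorphic markers", n_skipped)

    G = geno.to_numpy(dtype=np.int8)
    keys = [G[:, j].tobytes() for j in range(G.shape[1])]
    sig = stats["testable"].to_numpy() & (
        stats["lod"].to_numpy() >= lod_threshold)

    hits: List[QtlHit] = []
    j = 0
    m = len(keys)
    while j < m:
        if not sig[j]:
            j += 1
            continue
        k = j
        while (k + 1 < m and sig[k + 1] and chroms[k + 1] == chroms[j]
               and keys[k + 1] == keys[j]):
            k += 1
        row = stats.iloc[j]
        hits.append(QtlHit(
            trait=trait, chrom=chroms[j],
            start=int(pos[j]), end=int(pos[k]),
            lod=float(row["lod"]), pve=float(row["pve"]),
            additive=float(row["additive"]),
            peak_pos=int(pos[j + int(np.argmax(stats["lod"].to_numpy()
                                               [j:k + 1]))]),
            n_carriers=int(row["n1"])))
        j = k + 1
    return hits


def name_qtl(trait: str, chrom: str, serial: int,
             lg_map: Mapping[str, str]) -> str:
    """Published-style QTL name: q + trait + "-" + LG letter + "-" + serial."""
    if chrom not in lg_map:
        raise ConfigError(f"no linkage group for chromosome {chrom!r}")
    return f"q{trait}-{lg_map[chrom].lower()}-{serial}"


def name_hits(hits: Sequence[QtlHit], lg_map: Mapping[str, str],
              trait_abbrev: Optional[Mapping[str, str]] = None
              ) -> List[QtlHit]:
    """Assign names in place; serials run per trait x LG in genomic order."""
    counter: Dict[Tuple[str, str], int] = {}
    for hit in hits:
        abbrev = (trait_abbrev or {}).get(hit.trait, hit.trait)
        lg = lg_map[hit.chrom] if hit.chrom in lg_map else None
        if lg is None:
            raise ConfigError(f"no linkage group for {hit.chrom!r}")
        key = (abbrev, lg)
        counter[key] = counter.get(key, 0) + 1
        hit.name = name_qtl(abbrev, hit.chrom, counter[key], lg_map)
    return list(hits)


def hits_table(hits: Sequence[QtlHit]) -> pd.DataFrame:
    """Result table mirroring published linkage-QTL columns."""
    return pd.DataFrame([{
        "name": h.name or "",
        "trait": h.trait,
        "chrom": h.chrom,
        "additive": h.additive,
        "lod": h.lod,
        "pve": h.pve,
        "start_bp": h.start,
        "end_bp": h.end,
        "size_mb": interval_size_mb(h),
    } for h in hits])
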