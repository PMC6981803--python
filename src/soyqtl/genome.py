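"""Genome model and CSSL population containers.

Coordinates are 1-based and inclusive throughout the library; they are
converted to BED's 0-based half-open convention only at file boundaries
(see :mod:`soyqtl.intervals`).

A chromosome segment substitution line (CSSL) is an inbred line whose genome
is the recurrent parent's except for one or a few homozygous donor segments.
Genotype at any position is therefore a dosage in {0, 1}: 1 inside a donor
segment (homozygous donor), 0 elsewhere (homozygous recurrent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

#: Soybean chromosome -> classical linkage-group letter, used for QTL naming
#: ("q" + trait + LG letter + serial).
SOYBEAN_LG_MAP: Dict[str, str] = {
    "Gm01": "D1a", "Gm02": "D1b", "Gm03": "N", "Gm04": "C1", "Gm05": "A1",
    "Gm06": "C2", "Gm07": "M", "Gm08": "A2", "Gm09": "K", "Gm10": "O",
    "Gm11": "B1", "Gm12": "H", "Gm13": "F", "Gm14": "B2", "Gm15": "E",
    "Gm16": "J", "Gm17": "D2", "Gm18": "G", "Gm19": "L", "Gm20": "I",
}


class ConfigError(ValueError):
    """Inconsistent genome, population or simulation configuration."""


@dataclass(frozen=True)
class GenomeSpec:
    """An ordered set of chromosomes with a linkage-group letter map.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    lg_map
        Chromosome name -> linkage-group letter; must cover every chromosome.
    """

    chromosomes: Tuple[Tuple[str, int], ...]
    lg_map: Mapping[str, str]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigError(f"chromosome {name} has non-positive length")
            if name not in self.lg_map:
                raise ConfigError(f"lg_map does not cover chromosome {name}")

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise ConfigError(f"unknown chromosome {chrom!r}")

    def lg(self, chrom: str) -> str:
        if chrom not in self.lg_map:
            raise ConfigError(f"no linkage group for chromosome {chrom!r}")
        return self.lg_map[chrom]

    def index(self, chrom: str) -> int:
        return self.names.index(chrom)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


def default_genome(n_chromosomes: int = 20,
                   chrom_length: int = 50_000_000) -> GenomeSpec:
    """The default simulated soybean genome: Gm01-Gm20, 50 Mb each."""
    names = [f"Gm{i + 1:02d}" for i in range(n_chromosomes)]
    lg = {n: SOYBEAN_LG_MAP.get(n, n) for n in names}
    return GenomeSpec(tuple((n, chrom_length) for n in names), lg)


@dataclass(frozen=True)
class DonorSegment:
    """A homozygous donor-parent segment, 1-based inclusive."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ConfigError(
                f"invalid segment {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class PlantedQtl:
    """A simulated causal locus.

    ``additive_effect`` follows the linkage-mapping convention: half the
    trait difference between the homozygous donor and homozygous recurrent
    classes, so a carrier line's genetic value is shifted by
    ``2 * additive_effect``.
    """

    chrom: str
    pos: int
    additive_effect: float
    trait: str


class CsslPopulation:
    """A CSSL panel: lines, each with >=1 homozygous donor segment."""

    def __init__(self, genome: GenomeSpec,
                 lines: Sequence[Tuple[str, Sequence[DonorSegment]]]):
        self.genome = genome
        self.lines: Tuple[Tuple[str, Tuple[DonorSegment, ...]], ...] = tuple(
            (line_id, tuple(segs)) for line_id, segs in lines)
        seen = set()
        for line_id, segs in self.lines:
            if line_id in seen:
                raise ConfigError(f"duplicate line id {line_id!r}")
            seen.add(line_id)
            if not segs:
                raise ConfigError(f"line {line_id} has no donor segment")
            for seg in segs:
                if seg.end > genome.length(seg.chrom):
                    raise ConfigError(
                        f"segment {seg} exceeds chromosome length")
        self._segments = {line_id: segs for line_id, segs in self.lines}

    @property
    def line_ids(self) -> Tuple[str, ...]:
        return tuple(line_id for line_id, _ in self.lines)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def segments(self, line_id: str) -> Tuple[DonorSegment, ...]:
        return self._segments[line_id]

    def dosage(self, line_id: str, chrom: str, pos: int) -> int:
        """Donor dosage in {0, 1} for one line at one position."""
        if not (1 <= pos <= self.genome.length(chrom)):
            raise ConfigError(f"position {chrom}:{pos} outside chromosome")
        return int(any(s.contains(chrom, pos)
                       for s in self._segments[line_id]))

    def dosage_matrix(
            self, positions: Mapping[str, Sequence[int]]) -> pd.DataFrame:
        """Lines x markers dosage matrix.

        Columns are labelled ``chrom:pos`` and ordered by genome chromosome
        order, then position.
        """
        cols: list[str] = []
        blocks: list[np.ndarray] = []
        for chrom in self.genome.names:
            if chrom not in positions:
                continue
            pos = np.asarray(sorted(positions[chrom]), dtype=np.int64)
            if len(pos) == 0:
                continue
            if pos[0] < 1 or pos[-1] > self.genome.length(chrom):
                raise ConfigError(
                    f"marker position outside chromosome {chrom}")
            block = np.zeros((self.n_lines, len(pos)), dtype=np.int8)
            for i, (_, segs) in enumerate(self.lines):
                for seg in segs:
                    if seg.chrom != chrom:
                        continue
                    lo = np.searchsorted(pos, seg.start, side="left")
                    hi = np.searchsorted(pos, seg.end, side="right")
                    block[i, lo:hi] = 1
            blocks.append(block)
            cols.extend(f"{chrom}:{p}" for p in pos)
        unknown = set(positions) - set(self.genome.names)
        if unknown:
            raise ConfigError(f"unknown chromosomes in marker map: {unknown}")
        data = np.hstack(blocks) if blocks else np.zeros((self.n_lines, 0))
        return pd.DataFrame(data, index=list(self.line_ids), columns=cols)

    # -- serialization (truth files, manifests) ---------------------------
    def to_dict(self) -> dict:
        return {
            "genome": {
                "chromosomes": [list(c) for c in self.genome.chromosomes],
                "lg_map": dict(self.genome.lg_map),
            },
            "lines": [
                {"line_id": line_id,
                 "segments": [[s.chrom, s.start, s.end] for s in segs]}
                for line_id, segs in self.lines
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CsslPopulation":
        genome = GenomeSpec(
            tuple((c, int(l)) for c, l in d["genome"]["chromosomes"]),
            dict(d["genome"]["lg_map"]))
        lines = [
            (rec["line_id"],
             [DonorSegment(c, int(s), int(e)) for c, s, e in rec["segments"]])
            for rec in d["lines"]
        ]
        return cls(genome, lines)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CsslPopulation":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
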