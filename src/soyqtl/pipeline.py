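"""End-to-end orchestration of the mapping pipeline.

Stages (any contiguous-from-the-front subset selectable):

``simulate -> traits -> scan -> bsa -> consensus -> haplotype``

Each stage writes its tabular outputs into the configured output directory
and records them in a JSON manifest. All randomness derives from the single
top-level seed: per-stage seeds are the CRC32 of the stage name folded into
the seed, so stage outputs are reproducible independently of which other
stages run.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import consensus as cons
from . import ed as edmod
from . import haplotype as hap
from . import scan as scanmod
from . import simulate as sim
from . import traits as traitsmod
from .genome import CsslPopulation, GenomeSpec, PlantedQtl, default_genome
from .variants import read_vcf, write_vcf

STAGES = ("simulate", "traits", "scan", "bsa", "consensus", "haplotype")

#: trait label -> abbreviation used in QTL names
TRAIT_ABBREV = {"PH": "PH", "NNMS": "MS"}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; JSON round-trip stable."""

    seed: int = 1
    out_dir: str = "soyqtl_run"
    # population
    n_lines: int = 208
    segments_per_line: Tuple[int, int] = (1, 3)
    segment_length: Tuple[int, int] = (8_000_000, 30_000_000)
    # phenotypes: per-trait (grand_mean, year_sd, resid_sd)
    years: int = 4
    reps: int = 3
    trait_params: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {"PH": (80.0, 3.0, 5.0),
                                 "NNMS": (15.0, 0.8, 1.2)})
    # planted QTLs: trait -> list of (chrom, pos, additive effect)
    qtls: Dict[str, List[Tuple[str, int, float]]] = field(
        default_factory=lambda: {"PH": [("Gm16", 32_760_000, -7.65)],
                                 "NNMS": [("Gm09", 39_600_000, 2.0)]})
    # linkage scan
    marker_spacing: int = 1_000_000
    lod_threshold: float = 2.5
    # BSA
    n_extreme: int = 30
    snp_spacing: int = 100_000
    depth_mean: float = 30.0
    min_depth: int = 5
    span: float = 0.1
    grid_bp: int = 10_000
    inject_clusters: int = 5
    inject_indels: int = 5
    # consensus
    gap_bp: int = 1000
    cross_trait: bool = True
    # haplotype
    n_accessions: int = 92
    min_frac: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.span <= 1):
            raise ValueError("span must be in (0, 1]")
        if self.lod_threshold < 0 or self.min_depth < 1 or self.grid_bp < 1:
            raise ValueError("threshold parameters out of range")
        if not (0 <= self.min_frac < 1):
            raise ValueError("min_frac must be in [0, 1)")
        self.segments_per_line = tuple(self.segments_per_line)
        self.segment_length = tuple(self.segment_length)
        self.qtls = {t: [tuple(q) for q in qs] for t, qs in self.qtls.items()}
        self.trait_params = {t: tuple(p)
                             for t, p in self.trait_params.items()}

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 1_000_003
                + zlib.crc32(stage.encode())) % (2 ** 31)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["trait_params"] = {t: tuple(p)
                             for t, p in d.get("trait_params", {}).items()}
        d["qtls"] = {t: [tuple(q) for q in qs]
                     for t, qs in d.get("qtls", {}).items()}
        for k in ("segments_per_line", "segment_length"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig,
                 stages: Sequence[str] = STAGES,
                 genome: Optional[GenomeSpec] = None) -> dict:
    """Run the selected stages and return the manifest.

    Later stages consume the in-memory products of earlier ones; asking for
    a stage whose upstream stage was not run raises :class:`PipelineError`
    naming the missing stage.
    """
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}")
    stages = [s for s in STAGES if s in stages]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = genome or default_genome()

    manifest: dict = {"seed": config.seed, "stages": list(stages),
                      "parameters": dataclasses.asdict(config),
                      "outputs": {}, "counts": {}, "log": []}

    def _require(stage: str, product, upstream: str):
        if product is None:
            raise PipelineError(
                f"stage {stage!r} requires output of stage {upstream!r}")
        return product

    pop: Optional[CsslPopulation] = None
    pheno: Optional[pd.DataFrame] = None
    hits_by_trait: Optional[Dict[str, list]] = None
    bsa_by_trait: Optional[Dict[str, list]] = None

    if "simulate" in stages:
        pop = sim.simulate_population(
            genome, config.n_lines, config.segments_per_line,
            config.segment_length, seed=config.stage_seed("simulate"))
        frames = []
        truth = {"qtls": {}}
        for i, (trait, qtl_list) in enumerate(sorted(config.qtls.items())):
            gm, ysd, rsd = config.trait_params[trait]
            qtls = [PlantedQtl(c, p, a, trait) for c, p, a in qtl_list]
            frames.append(sim.simulate_phenotypes(
                pop, qtls, years=config.years, reps=config.reps,
                year_sd=ysd, resid_sd=rsd, grand_mean=gm,
                seed=config.stage_seed(f"phenotypes:{trait}"), trait=trait))
            truth["qtls"][trait] = [list(q) for q in qtl_list]
        pheno = pd.concat(frames, ignore_index=True)
        pop.to_json(out / "population.json")
        pheno.to_csv(out / "phenotypes.csv", index=False,
                     float_format="%.6g")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        manifest["outputs"]["population"] = "population.json"
        manifest["outputs"]["phenotypes"] = "phenotypes.csv"
        manifest["outputs"]["truth"] = "truth.json"
        manifest["counts"]["n_lines"] = pop.n_lines

    if "traits" in stages:
        pheno = _require("traits", pheno, "simulate")
        tables = [traitsmod.trait_summary_table(pheno, t, r=config.reps)
                  for t in sorted(config.qtls)]
        summary = pd.concat(tables, ignore_index=True)
        _write_tsv(summary, out / "trait_summary.tsv")
        manifest["outputs"]["trait_summary"] = "trait_summary.tsv"

    blues: Dict[str, pd.Series] = {}
    if "scan" in stages:
        pop = _require("scan", pop, "simulate")
        pheno = _require("scan", pheno, "simulate")
        geno = scanmod.genotype_matrix(
            pop, scanmod.marker_grid(pop, config.marker_spacing))
        _write_tsv(geno.reset_index(names="line_id"),
                   out / "genotype_matrix.csv")
        hits_by_trait = {}
        all_hits = []
        for trait in sorted(config.qtls):
            blues[trait] = traitsmod.compute_blue(pheno, trait).blue
            hits = scanmod.scan(geno, blues[trait],
                                lod_threshold=config.lod_threshold,
                                trait=trait)
            scanmod.name_hits(hits, genome.lg_map, TRAIT_ABBREV)
            hits_by_trait[trait] = hits
            all_hits.extend(hits)
        _write_tsv(scanmod.hits_table(all_hits), out / "linkage_qtls.tsv")
        manifest["outputs"]["linkage_qtls"] = "linkage_qtls.tsv"
        manifest["counts"]["linkage_hits"] = len(all_hits)

    if "bsa" in stages:
        pop = _require("bsa", pop, "simulate")
        pheno = _require("bsa", pheno, "simulate")
        bsa_by_trait = {}
        ed_frames = []
        iv_rows = []
        for trait in sorted(config.qtls):
            high, low = sim.select_bulks(pheno, trait, config.n_extreme)
            pools = sim.simulate_pools(
                pop, high, low, snp_spacing=config.snp_spacing,
                depth_mean=config.depth_mean,
                inject_clusters=config.inject_clusters,
                inject_indels=config.inject_indels,
                seed=config.stage_seed(f"pools:{trait}"))
            vcf_path = out / f"pools_{trait}.vcf"
            write_vcf(pools.variants, vcf_path, genome=genome)
            variants = read_vcf(vcf_path)  # exercised real-data entry point
            snps, report = edmod.filter_variants(
                variants, min_depth=config.min_depth)
            frame = edmod.ed_frame(snps, genome=genome)
            frame = edmod.fit_loess(frame, span=config.span)
            thr = edmod.ed_threshold(frame["ed_fitted"])
            intervals = edmod.call_intervals(frame, thr,
                                             grid_bp=config.grid_bp)
            bsa_by_trait[trait] = intervals
            frame.insert(0, "trait", trait)
            ed_frames.append(frame)
            tab = edmod.intervals_table(intervals)
            tab.insert(0, "trait", trait)
            iv_rows.append(tab)
            manifest["outputs"][f"pools_{trait}"] = vcf_path.name
            manifest["counts"][f"filter_{trait}"] = report.as_dict()
            manifest["counts"][f"ed_threshold_{trait}"] = thr
            manifest["log"].append(
                f"{trait}: {report.retained} SNPs scored, threshold "
                f"{thr:.4f}, {len(intervals)} candidate interval(s)")
        ed_all = pd.concat(ed_frames, ignore_index=True)
        track = ed_all.assign(start=ed_all["pos"] - 1, end=ed_all["pos"])
        _write_tsv(track[["trait", "chrom", "start", "end",
                          "ed_raw", "ed_fitted"]], out / "ed_track.tsv")
        _write_tsv(pd.concat(iv_rows, ignore_index=True),
                   out / "bsa_intervals.tsv")
        manifest["outputs"]["ed_track"] = "ed_track.tsv"
        manifest["outputs"]["bsa_intervals"] = "bsa_intervals.tsv"

    if "consensus" in stages:
        hits_by_trait = _require("consensus", hits_by_trait, "scan")
        bsa_by_trait = _require("consensus", bsa_by_trait, "bsa")
        regions = cons.consensus(hits_by_trait, bsa_by_trait,
                                 gap_bp=config.gap_bp,
                                 cross_trait=config.cross_trait)
        _write_tsv(cons.consensus_table(regions), out / "consensus.tsv")
        cons.consensus_bed(regions, out / "consensus.bed")
        manifest["outputs"]["consensus"] = "consensus.tsv"
        manifest["outputs"]["consensus_bed"] = "consensus.bed"
        manifest["counts"]["consensus_regions"] = len(regions)

    if "haplotype" in stages:
        panel = sim.simulate_germplasm(
            n_accessions=config.n_accessions,
            seed=config.stage_seed("haplotype"))
        groups, excluded = hap.assign_haplotypes(panel.calls)
        top = hap.excellent(groups, len(panel.calls) - len(excluded),
                            min_frac=config.min_frac)
        rows = pd.DataFrame([{
            "group": g.name, "haplotype": g.haplotype, "n": g.size,
            "frequency": g.frequency, "excellent": g in top,
        } for g in groups])
        result = hap.haplotype_anova(top, panel.trait.to_dict())
        ld_res = hap.ld(panel.calls)
        _write_tsv(rows, out / "haplotype_groups.tsv")
        _write_tsv(result.group_stats, out / "haplotype_anova.tsv")
        ld_res.r2.to_csv(out / "ld_r2.tsv", sep="\t", float_format="%.6g")
        manifest["outputs"]["haplotype_groups"] = "haplotype_groups.tsv"
        manifest["outputs"]["haplotype_anova"] = "haplotype_anova.tsv"
        manifest["outputs"]["ld_r2"] = "ld_r2.tsv"
        manifest["counts"]["haplotype_excluded"] = len(excluded)
        manifest["counts"]["excellent_haplotypes"] = len(top)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
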