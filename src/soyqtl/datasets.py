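"""Bundled example QTL tables.

Published mapping results for two soybean plant-architecture traits —
plant height (PH) and number of nodes on the main stem (NNMS) — in a
208-line CSSL panel: linkage-scan QTLs (additive effect, LOD, PVE and
physical interval per environment) and BSA-seq candidate intervals. They
serve as worked inputs for interval arithmetic and consensus-QTL
determination.
"""

from __future__ import annotations

from importlib import resources
from typing import List, Optional

import pandas as pd

from .ed import CandidateInterval
from .scan import QtlHit


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("soyqtl.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_linkage_table() -> pd.DataFrame:
    """Linkage-scan QTLs for PH and NNMS, one row per QTL x environment."""
    return _read("linkage_qtls.tsv")


def load_bsa_table() -> pd.DataFrame:
    """BSA-seq candidate intervals for PH and NNMS."""
    return _read("bsa_intervals.tsv")


def load_linkage_hits(trait: Optional[str] = None) -> List[QtlHit]:
    df = load_linkage_table()
    if trait is not None:
        df = df[df["trait"] == trait]
    return [QtlHit(trait=r["trait"], chrom=r["chrom"],
                   start=int(r["start_bp"]), end=int(r["end_bp"]),
                   lod=float(r["lod"]), pve=float(r["pve"]),
                   additive=float(r["additive"]), peak_pos=int(r["start_bp"]),
                   n_carriers=0, name=r["name"])
            for r in df.to_dict("records")]


def load_bsa_candidates(trait: Optional[str] = None
                        ) -> List[CandidateInterval]:
    df = load_bsa_table()
    if trait is not None:
        df = df[df["trait"] == trait]
    return [CandidateInterval(chrom=r["chrom"], start=int(r["start_bp"]),
                              end=int(r["end_bp"]), peak_fitted=float("nan"),
                              n_snps=0, name=r["name"])
            for r in df.to_dict("records")]
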