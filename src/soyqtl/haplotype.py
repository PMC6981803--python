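"""Gene-region haplotype association and linkage disequilibrium.

Accessions of an inbred germplasm panel are grouped by their call string
over the SNP sites of a gene region (3-kb upstream promoter + UTRs + CDS +
introns). Haplotypes carried by more than 5% of the assigned panel
("excellent haplotypes") are compared by one-way ANOVA with Tukey-HSD
pairwise tests; groups sharing a compact-display letter are not
significantly different at the chosen level.

Calls are coded 0 (ref), 1 (alt), 2 (heterozygous), -1 (missing);
accessions with any heterozygous or missing call are excluded from
haplotype assignment (inbred-panel assumption).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ConfigError


@dataclass(frozen=True)
class GeneRegion:
    """A gene with its analyzed sequence features.

    ``atg_pos`` anchors SNP naming: offsets are negative upstream of the
    ATG (promoter) and positive downstream, strand-aware.
    """

    gene_id: str
    chrom: str
    strand: str
    atg_pos: int
    features: Tuple[Tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigError("strand must be '+' or '-'")
        ivs = sorted((s, e) for _, s, e in self.features)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ConfigError("gene features overlap")

    def snp_name(self, pos: int) -> str:
        """Site name by signed offset from the ATG (e.g. SNP-190, SNP754)."""
        offset = pos - self.atg_pos if self.strand == "+" \
            else self.atg_pos - pos
        return f"SNP{offset}"


@dataclass
class HaplotypeGroup:
    """One haplotype: call string, members and panel frequency."""

    name: str
    haplotype: str
    members: Tuple[str, ...]
    frequency: float

    @property
    def size(self) -> int:
        return len(self.members)


def assign_haplotypes(calls: pd.DataFrame
                      ) -> Tuple[List[HaplotypeGroup], List[str]]:
    """Group accessions by identical call strings.

    Returns the groups sorted by descending frequency (ties by haplotype
    string) and the list of excluded accessions (any missing or
    heterozygous call). Frequencies are over assigned accessions.
    """
    if calls.shape[1] < 1:
        raise ValueError("need >= 1 SNP site")
    arr = calls.to_numpy()
    ok = ~((arr == -1) | (arr == 2)).any(axis=1)
    excluded = [str(a) for a in calls.index[~ok]]
    assigned = calls.loc[ok]
    if assigned.empty:
        raise ValueError("all accessions have missing/heterozygous calls")
    total = len(assigned)
    groups: Dict[str, List[str]] = {}
    for acc, row in zip(assigned.index, assigned.to_numpy()):
        key = "".join(str(int(c)) for c in row)
        groups.setdefault(key, []).append(str(acc))
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return ([HaplotypeGroup(f"Hap-{i + 1}", hap, tuple(members),
                            len(members) / total)
             for i, (hap, members) in enumerate(ordered)], excluded)


def excellent(groups: Sequence[HaplotypeGroup], total_assigned: int,
              min_frac: float = 0.05) -> List[HaplotypeGroup]:
    """Haplotypes carried by strictly more than min_frac of the panel."""
    if total_assigned < 1:
        raise ValueError("total_assigned must be >= 1")
    return [g for g in groups if g.size > min_frac * total_assigned]


def _letter_classes(names: Sequence[str],
                    significant: Mapping[Tuple[str, str], bool]
                    ) -> List[set]:
    """Insert-and-absorb compact letter display.

    Starts from one class holding every group and splits a class for each
    significant pair it contains; subsets are absorbed. The result
    represents the non-significance relation exactly: two groups share a
    class iff their pairwise test is not significant.
    """
    classes: List[set] = [set(names)]
    for (i, j), sig in significant.items():
        if not sig:
            continue
        new: List[set] = []
        for c in classes:
            if i in c and j in c:
                new.extend([c - {i}, c - {j}])
            else:
                new.append(c)
        uniq: List[set] = []
        for c in new:
            if c and c not in uniq:
                uniq.append(c)
        classes = [c for c in uniq if not any(c < d for d in uniq)]
    return classes


@dataclass
class HaplotypeAnova:
    """One-way ANOVA across haplotype groups with grouping letters."""

    f_statistic: float
    p_value: float
    letters: Dict[str, str]
    group_stats: pd.DataFrame
    pairwise: pd.DataFrame
    alpha: float


def haplotype_anova(groups: Sequence[HaplotypeGroup],
                    trait: Mapping[str, float],
                    alpha: float = 0.05) -> HaplotypeAnova:
    """Compare trait means across haplotype groups.

    One-way ANOVA F-test plus Tukey-HSD pairwise comparisons; letters are
    assigned so that groups sharing a letter are not significantly
    different at ``alpha``.
    """
    trait = pd.Series(dict(trait), dtype=float)
    samples: Dict[str, np.ndarray] = {}
    for g in groups:
        vals = trait.reindex(list(g.members)).dropna().to_numpy()
        if len(vals) >= 2:
            samples[g.name] = vals
    if len(samples) < 2:
        raise ValueError("need >= 2 groups with >= 2 phenotyped members")

    names = list(samples)
    f_stat, p_val = stats.f_oneway(*samples.values())

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    endog = np.concatenate([samples[n] for n in names])
    labels = np.concatenate([[n] * len(samples[n]) for n in names])
    tk = pairwise_tukeyhsd(endog, labels, alpha=alpha)
    pairwise = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0])
    significant = {(str(r["group1"]), str(r["group2"])): bool(r["reject"])
                   for _, r in pairwise.iterrows()}

    classes = _letter_classes(names, significant)
    means = {n: samples[n].mean() for n in names}
    # letters ordered by the highest group mean each class contains
    classes.sort(key=lambda c: -max(means[n] for n in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {n: "" for n in names}
    for letter, c in zip(alphabet, classes):
        for n in c:
            letters[n] += letter
    letters = {n: "".join(sorted(s)) for n, s in letters.items()}

    # invariant: sharing a letter <=> pairwise test not significant
    for (i, j), sig in significant.items():
        share = bool(set(letters[i]) & set(letters[j]))
        assert share != sig, f"letter display inconsistent for {i}/{j}"

    group_stats = pd.DataFrame([{
        "group": n,
        "n": len(samples[n]),
        "mean": float(samples[n].mean()),
        "sd": float(samples[n].std(ddof=1)),
        "letters": letters[n],
    } for n in names])
    return HaplotypeAnova(float(f_stat), float(p_val), letters,
                          group_stats, pairwise, alpha)


@dataclass
class LdResult:
    """Pairwise LD matrices; NaN where a site is monomorphic."""

    r2: pd.DataFrame
    d_prime: pd.DataFrame


def ld(calls: pd.DataFrame) -> LdResult:
    """Pairwise r^2 and D' between sites of an inbred-panel call matrix.

    Accessions missing or heterozygous at either site of a pair are
    dropped pairwise. For alt-allele frequencies p, q and joint frequency
    p11: ``D = p11 - p q``, ``r^2 = D^2 / (p(1-p)q(1-q))`` and
    ``D' = |D| / Dmax`` with the standard case split for Dmax.
    """
    sites = list(calls.columns)
    arr = calls.to_numpy(dtype=float)
    arr[(arr == -1) | (arr == 2)] = np.nan
    m = len(sites)
    r2 = np.full((m, m), np.nan)
    dp = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i, m):
            ok = ~np.isnan(arr[:, i]) & ~np.isnan(arr[:, j])
            if ok.sum() < 2:
                continue
            x, y = arr[ok, i], arr[ok, j]
            p, q = x.mean(), y.mean()
            if p in (0.0, 1.0) or q in (0.0, 1.0):
                continue
            p11 = float((x * y).mean())
            d = p11 - p * q
            r2[i, j] = r2[j, i] = d * d / (p * (1 - p) * q * (1 - q))
            if d > 0:
                dmax = min(p * (1 - q), (1 - p) * q)
            elif d < 0:
                dmax = min(p * q, (1 - p) * (1 - q))
            else:
                dmax = None
            dp[i, j] = dp[j, i] = 0.0 if dmax is None else abs(d) / dmax
    return LdResult(pd.DataFrame(r2, index=sites, columns=sites),
                    pd.DataFrame(dp, index=sites, columns=sites))
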