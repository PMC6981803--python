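"""Phenotype statistics: summaries, correlation, BLUE, heritability.

The mixed model behind the BLUE is ``y = X beta + Z u + e`` with the line
(genotype) effect fixed and the year effect random; it is fit by REML. With
a balanced design and a zero year-variance estimate the BLUE of each line
equals its grand mean.

Broad-sense heritability follows the one-way ANOVA expected-mean-squares
decomposition: ``sigma_g^2 = max(0, (MS_g - MS_e) / r)``, ``sigma_e^2 =
MS_e`` and ``H^2 = r sigma_g^2 / (sigma_e^2 + r sigma_g^2)`` for r
replicates, clamped to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TraitSummary:
    """Descriptive statistics of one trait (Table-1-style row)."""

    max: float
    min: float
    mean: float
    sd: float
    kurtosis: float   # sample excess kurtosis (g2)
    skewness: float   # sample skewness (g1)
    h2: Optional[float] = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("max", "min", "mean", "sd", "kurtosis",
                          "skewness", "h2")}


@dataclass
class BlueResult:
    """Per-line BLUEs and the variance components behind them.

    ``sigma_g2`` is the between-line variance of the estimated line effects
    (reported for context); ``sigma_year2`` and ``sigma_e2`` are the REML
    estimates of the year and residual variances, clamped at 0.
    """

    blue: pd.Series
    sigma_g2: float
    sigma_year2: float
    sigma_e2: float
    method: str = "reml"


def describe(values: Sequence[float]) -> TraitSummary:
    """Max/min/mean/SD/kurtosis/skewness of a sample.

    SD uses the n-1 denominator; skewness is sample g1 and kurtosis sample
    excess kurtosis g2 (both the biased moment estimators). Kurtosis is NaN
    for n < 4.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-d sample with n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    kurt = float(stats.kurtosis(x, fisher=True, bias=True)) \
        if len(x) >= 4 else float("nan")
    return TraitSummary(
        max=float(x.max()), min=float(x.min()), mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        kurtosis=kurt,
        skewness=float(stats.skew(x, bias=True)))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two paired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y)[0])


def compute_blue(pheno: pd.DataFrame, trait: str) -> BlueResult:
    """REML BLUE of each line under fixed line + random year effects.

    With a single year the model is degenerate; the per-line mean is
    returned with a warning.
    """
    sub = pheno[pheno["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    lines = list(dict.fromkeys(sub["line_id"]))
    if len(lines) < 2:
        raise ValueError("need >= 2 lines")
    years = sub["year"].unique()

    means = sub.groupby("line_id")["value"].mean().reindex(lines)
    if len(years) < 2:
        warnings.warn("single year: BLUE degenerates to per-line means",
                      stacklevel=2)
        resid = sub.groupby("line_id")["value"].transform("mean")
        sigma_e2 = float(((sub["value"] - resid) ** 2).sum()
                         / max(len(sub) - len(lines), 1))
        return BlueResult(means, float(means.var(ddof=1)), 0.0, sigma_e2,
                          method="line-means")

    if np.isclose(sub["value"].var(ddof=0), 0.0):
        # constant phenotype: all components zero, BLUE = the constant
        return BlueResult(means, 0.0, 0.0, 0.0, method="constant")

    y = sub["value"].to_numpy(dtype=float)
    line_codes = pd.Categorical(sub["line_id"], categories=lines).codes
    year_codes = pd.Categorical(sub["year"]).codes
    beta, sigma_year2, sigma_e2 = _profile_reml(
        y, line_codes, year_codes, len(lines))
    blue = pd.Series(beta, index=lines, name="blue")
    return BlueResult(blue, float(blue.var(ddof=1)), sigma_year2, sigma_e2)


def _profile_reml(y: np.ndarray, line: np.ndarray, year: np.ndarray,
                  p: int) -> tuple:
    """Exact REML for the one-random-intercept (year) model.

    The variance ratio lambda = sigma_year^2 / sigma_e^2 is profiled: for
    fixed lambda the covariance ``V = sigma_e^2 (I + lambda Z Z')`` is block
    diagonal by year, so the GLS solve and the restricted log-likelihood
    have closed forms; lambda is then optimized by bounded scalar search
    (deterministic, boundary at 0 handled explicitly).
    """
    from scipy.optimize import minimize_scalar

    n = len(y)
    q = int(year.max()) + 1
    m = np.bincount(year, minlength=q).astype(float)          # obs per year
    s = np.bincount(year, weights=y, minlength=q)             # y sums
    # N[i, j] = observations of line i in year j
    N = np.zeros((p, q))
    np.add.at(N, (line, year), 1.0)
    xty = np.bincount(line, weights=y, minlength=p)
    xtx = np.bincount(line, minlength=p).astype(float)
    yty = float(y @ y)

    def _fit(lam: float):
        w = lam / (1.0 + lam * m)                             # per-year
        a = np.diag(xtx) - (N * w) @ N.T                      # X'V*^-1 X
        b = xty - (N * w) @ s                                 # X'V*^-1 y
        beta = np.linalg.solve(a, b)
        yvy = yty - float(w @ s ** 2)
        rss = max(yvy - float(beta @ b), 1e-300)
        sign, logdet_a = np.linalg.slogdet(a)
        logdet_v = float(np.log1p(lam * m).sum())
        # restricted log-likelihood up to constants, sigma_e^2 profiled out
        ll = -0.5 * ((n - p) * np.log(rss) + logdet_v + logdet_a)
        return beta, rss, ll

    def _negll(u: float) -> float:
        return -_fit(np.exp(u))[2]

    res = minimize_scalar(_negll, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    beta, rss, ll = _fit(lam)
    beta0, rss0, ll0 = _fit(0.0)
    if ll0 >= ll:                                             # boundary
        lam, beta, rss = 0.0, beta0, rss0
    sigma_e2 = rss / (n - p)
    return beta, lam * sigma_e2, sigma_e2


def heritability_from_components(sigma_g2: float, sigma_e2: float,
                                 r: int) -> float:
    """Broad-sense heritability from variance components and r replicates."""
    if r < 2:
        raise ValueError("need r >= 2 replicates")
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be >= 0")
    denom = sigma_e2 + r * sigma_g2
    return 0.0 if denom == 0 else r * sigma_g2 / denom


def heritability(pheno: pd.DataFrame, trait: str,
                 r: Optional[int] = None) -> float:
    """Broad-sense heritability from a one-way ANOVA over lines.

    ``r`` is the replicate count entering the expected-mean-squares
    formula; by default the mean number of observations per line. Negative
    genetic-variance estimates are clamped to 0 (h2 = 0).
    """
    sub = pheno[pheno["trait"] == trait]
    groups = [g["value"].to_numpy() for _, g in sub.groupby("line_id")]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 lines with >= 2 replicates")
    if r is None:
        r = int(round(np.mean([len(g) for g in groups])))
    if r < 2:
        raise ValueError("need r >= 2 replicates")
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_g = ss_between / (k - 1)
    ms_e = ss_within / (n - k)
    sigma_g2 = max(0.0, (ms_g - ms_e) / r)
    return heritability_from_components(sigma_g2, ms_e, r)


def relative_expression(ct_reference: float, ct_target: float) -> float:
    """Relative expression 2**dCt with dCt = Ct(reference) - Ct(target)."""
    if not (np.isfinite(ct_reference) and np.isfinite(ct_target)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (ct_reference - ct_target))


def trait_summary_table(pheno: pd.DataFrame, trait: str,
                        r: Optional[int] = None) -> pd.DataFrame:
    """Per-year descriptive rows plus a BLUE row, mirroring a phenotype
    summary table (max, min, mean, SD, kurtosis, skewness, H2)."""
    sub = pheno[pheno["trait"] == trait]
    rows = []
    for year, g in sub.groupby("year"):
        s = describe(g["value"].to_numpy())
        s.h2 = heritability(g.assign(trait=trait), trait, r=r)
        rows.append({"trait": trait, "year": str(year), **s.as_dict()})
    blue = compute_blue(pheno, trait).blue
    s = describe(blue.to_numpy())
    rows.append({"trait": trait, "year": "BLUE", **s.as_dict()})
    return pd.DataFrame(rows)
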