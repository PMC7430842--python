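"""Injury-index phenotypes: descriptive statistics, heritability, bulks.

A phenotype table is a tidy DataFrame with columns ``hybrid_id``, ``year``,
``trait`` and ``value``; values are injury indices in [0, 1] (SID, AID,
SAID for salt, alkali and combined salt–alkali stress).  Tolerance is
negatively oriented: a *lower* injury index means a *more* tolerant hybrid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError

PHENO_COLUMNS = ("hybrid_id", "year", "trait", "value")


@dataclass
class TraitSummary:
    """Per-trait, per-year descriptive statistics (Table-1 shape)."""

    trait: str
    year: Optional[int]
    mean: float
    sd: float
    cv_pct: float
    h2_pct: Optional[float] = None


def injury_index(counts: Sequence[float], max_class: Optional[int] = None) -> float:
    """Weighted ordinal injury index from per-class plant counts.

    ``counts[c]`` is the number of plants scored in injury class ``c``
    (0 = undamaged .. C_max = dead).  The index is
    ``sum(c * n_c) / (C_max * sum(n_c))``, in [0, 1].  By default five
    classes 0–4 are assumed when ``counts`` has five entries; ``max_class``
    overrides the top class for panels where the worst class was not
    observed.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise DataError("injury_index: empty score panel")
    if np.any(counts < 0):
        raise DataError("injury_index: negative class count")
    cmax = (counts.size - 1) if max_class is None else int(max_class)
    if cmax <= 0:
        raise DataError("injury_index: need at least two injury classes")
    classes = np.arange(counts.size)
    return float((classes * counts).sum() / (cmax * counts.sum()))


def _subset(pheno: pd.DataFrame, trait: str, year: Optional[int] = None) -> pd.DataFrame:
    sub = pheno[pheno["trait"] == trait]
    if year is not None:
        sub = sub[sub["year"] == year]
    return sub


def trait_summary(pheno: pd.DataFrame, trait: str, year: Optional[int] = None) -> TraitSummary:
    """Sample mean, SD (n−1) and CV% of one trait (optionally one year)."""
    values = _subset(pheno, trait, year)["value"].to_numpy(dtype=float)
    if values.size < 2:
        raise DataError(f"trait_summary: need >= 2 observations for {trait!r}, year={year}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    cv = (sd / mean * 100.0) if mean > 0 else 0.0
    return TraitSummary(trait=trait, year=year, mean=mean, sd=sd, cv_pct=cv)


def hybrid_means(pheno: pd.DataFrame, trait: str) -> pd.Series:
    """Per-hybrid mean injury index across years (and replicates)."""
    sub = _subset(pheno, trait)
    if sub.empty:
        raise DataError(f"no observations for trait {trait!r}")
    return sub.groupby("hybrid_id")["value"].mean().sort_index()


def broad_sense_heritability(pheno: pd.DataFrame, trait: str) -> float:
    """Broad-sense heritability H² (%) from a one-way random-effects ANOVA.

    Hybrids are the random groups, year observations the replicates:
    ``sigma2_g = (MS_hybrid − MS_residual) / r`` with ``r`` the harmonic
    mean of per-hybrid replicate counts (robust to mild unbalance), and
    ``H² = sigma2_g / (sigma2_g + MS_residual) * 100``.  Negative variance
    estimates are truncated at zero.
    """
    sub = _subset(pheno, trait)
    if sub["year"].nunique() < 2:
        raise DataError("broad_sense_heritability: need observations from >= 2 years")
    groups = sub.groupby("hybrid_id")["value"]
    counts = groups.count()
    counts = counts[counts >= 2]
    if len(counts) < 2:
        raise DataError("broad_sense_heritability: need >= 2 hybrids with repeated records")
    sub = sub[sub["hybrid_id"].isin(counts.index)]
    groups = sub.groupby("hybrid_id")["value"]

    n_i = groups.count().to_numpy(dtype=float)
    means_i = groups.mean().to_numpy(dtype=float)
    grand = sub["value"].mean()
    k = len(n_i)
    n_total = n_i.sum()

    ss_between = float((n_i * (means_i - grand) ** 2).sum())
    ss_total = float(((sub["value"] - grand) ** 2).sum())
    ss_within = ss_total - ss_between
    ms_g = ss_between / (k - 1)
    ms_e = ss_within / (n_total - k)

    r = stats.hmean(n_i)
    sigma2_g = max(0.0, (ms_g - ms_e) / r)
    if sigma2_g == 0.0 and ms_e == 0.0:
        return 0.0
    return float(sigma2_g / (sigma2_g + ms_e) * 100.0)


def trait_correlation(pheno: pd.DataFrame, trait_a: str, trait_b: str) -> tuple[float, float]:
    """Pearson r and two-sided p between per-hybrid mean values of two traits."""
    a = hybrid_means(pheno, trait_a)
    b = hybrid_means(pheno, trait_b)
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise DataError("trait_correlation: need >= 3 hybrids scored for both traits")
    x, y = a.loc[common].to_numpy(), b.loc[common].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("trait_correlation: zero variance in one of the traits")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def select_bulks(pheno: pd.DataFrame, trait: str, bulk_size: int) -> tuple[list[str], list[str]]:
    """Extreme-phenotype bulks: (tolerant ids, sensitive ids).

    Hybrids are ranked by per-hybrid mean injury index; the lowest
    ``bulk_size`` form the tolerant bulk, the highest the sensitive bulk.
    Ties are broken deterministically by hybrid_id.
    """
    means = hybrid_means(pheno, trait)
    n = len(means)
    if not (1 <= bulk_size <= n // 2):
        raise DataError(f"select_bulks: bulk_size must be in [1, {n // 2}], got {bulk_size}")
    order = means.reset_index().sort_values(["value", "hybrid_id"], kind="mergesort")
    ids = order["hybrid_id"].tolist()
    return ids[:bulk_size], ids[-bulk_size:]


def summarize(pheno: pd.DataFrame) -> pd.DataFrame:
    """Table-1-like report: per trait/year mean, SD, CV%, per-trait H²%."""
    rows = []
    for trait in pd.unique(pheno["trait"]):
        years = sorted(pd.unique(_subset(pheno, trait)["year"]))
        try:
            h2 = broad_sense_heritability(pheno, trait)
        except DataError:
            h2 = np.nan
        for i, year in enumerate(years):
            s = trait_summary(pheno, trait, year)
            rows.append(
                {"trait": trait, "year": year, "mean": s.mean, "sd": s.sd,
                 "cv_pct": s.cv_pct, "h2_pct": h2 if i == 0 else np.nan}
            )
    return pd.DataFrame(rows)
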