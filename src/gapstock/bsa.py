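"""Bulked-segregant QTL scanning with a smoothed G′ statistic.

For every variant the allele depths of the tolerant and sensitive bulks
form a 2x2 table; the log-likelihood-ratio statistic G measures allele-
frequency divergence between bulks.  G is tricube-smoothed over physical
position into G′, a log-normal null is fitted to the outlier-trimmed G′
distribution, and QTL intervals are called where the Benjamini–Hochberg
q-value clears a chosen FDR.  Variants are scanned separately per parental
origin class (maternal / paternal / both), mirroring the three segregation
tracks of a pseudo-testcross, and each class gets its own threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError

ORIGIN_CODES = {"maternal": "BC", "paternal": "M", "both": "H"}


def g_statistic(n1, n2, n3, n4):
    """Log-likelihood-ratio G over the 2x2 bulk-by-allele depth table.

    ``n1, n2`` are ref/alt depths in one bulk, ``n3, n4`` in the other.
    G = 2 * sum(obs * ln(obs / exp)) with expectations from the row and
    column marginals; cells with zero observed count contribute zero.
    Accepts scalars or arrays; an all-zero table yields NaN (undefined).
    """
    n1, n2, n3, n4 = (np.asarray(x, dtype=float) for x in (n1, n2, n3, n4))
    obs = np.stack([n1, n2, n3, n4])
    if np.any(obs < 0):
        raise DataError("g_statistic: negative allele depth")
    total = obs.sum(axis=0)
    row1 = n1 + n2
    row2 = n3 + n4
    col1 = n1 + n3
    col2 = n2 + n4
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = np.stack([row1 * col1, row1 * col2, row2 * col1, row2 * col2]) / total
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
        g = 2.0 * terms.sum(axis=0)
    g = np.where(total > 0, g, np.nan)
    # guard against tiny negative round-off
    g = np.where(np.isnan(g), g, np.maximum(g, 0.0))
    return float(g) if g.ndim == 0 else g


def classify_origin(maternal_call: str, paternal_call: str) -> Optional[str]:
    """Parent-of-origin class of a variant from the parental genotypes.

    Genotypes are ``"X/Y"`` strings.  Heterozygous mother only → maternal;
    heterozygous father only → paternal; both heterozygous → both; both
    homozygous → None (uninformative, excluded from the scan).
    """

    def _is_het(call: str) -> bool:
        alleles = call.replace("|", "/").split("/")
        if len(alleles) != 2:
            raise DataError(f"cannot parse genotype call {call!r}")
        return alleles[0] != alleles[1]

    m, p = _is_het(maternal_call), _is_het(paternal_call)
    if m and p:
        return "both"
    if m:
        return "maternal"
    if p:
        return "paternal"
    return None


def tricube_smooth(track: pd.DataFrame, window_bp: float,
                   value_col: str = "G", out_col: str = "Gprime") -> pd.DataFrame:
    """Tricube-weighted moving average of G over physical position.

    For variant j, ``G'_j = sum_k w(d_jk) G_k / sum_k w(d_jk)`` over
    variants k on the same chromosome with |pos_k − pos_j| ≤ window_bp,
    using tricube weights ``w(d) = (1 − (|d|/h)^3)^3``.  The variant itself
    is included (weight 1), so an isolated variant keeps G′ = G.  NaN G
    values are ignored as neighbours and propagate only to themselves.
    """
    if window_bp <= 0:
        raise DataError("tricube_smooth: window_bp must be positive")
    track = track.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    gprime = np.full(len(track), np.nan)
    for _, idx in track.groupby("chrom").groups.items():
        idx = np.asarray(idx)
        pos = track.loc[idx, "pos"].to_numpy(dtype=float)
        g = track.loc[idx, value_col].to_numpy(dtype=float)
        ok = ~np.isnan(g)
        lo = np.searchsorted(pos, pos - window_bp, side="left")
        hi = np.searchsorted(pos, pos + window_bp, side="right")
        for j in range(len(idx)):
            if not ok[j]:
                continue
            sl = slice(lo[j], hi[j])
            d = np.abs(pos[sl] - pos[j]) / window_bp
            w = (1.0 - np.minimum(d, 1.0) ** 3) ** 3
            w = np.where(ok[sl], w, 0.0)
            wsum = w.sum()
            gprime[idx[j]] = (w * g[sl]).sum() / wsum if wsum > 0 else g[j]
    out = track.copy()
    out[out_col] = gprime
    return out


def gprime_threshold(gprime: np.ndarray, fdr_q: float = 0.05,
                     trim_mad: float = 5.0, min_variants: int = 50):
    """Significance threshold for G′ from a trimmed log-normal null.

    Upper outliers (G′ > median + ``trim_mad``·MAD, MAD unscaled) are
    removed, a log-normal is fitted to the remainder, per-variant p-values
    are the log-normal upper tail, and BH-FDR q-values are computed over
    all variants.  Returns ``(threshold, pvals, qvals)`` where the
    threshold is the smallest G′ with q ≤ fdr_q (None when nothing is
    significant or the null is degenerate).
    """
    gprime = np.asarray(gprime, dtype=float)
    ok = np.isfinite(gprime) & (gprime > 0)
    pvals = np.full(gprime.shape, np.nan)
    qvals = np.full(gprime.shape, np.nan)
    if ok.sum() < min_variants:
        raise DataError(f"gprime_threshold: need >= {min_variants} variants with G' > 0")
    vals = gprime[ok]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    if mad == 0:
        return None, pvals, qvals  # degenerate (near-constant) G'
    kept = vals[vals <= med + trim_mad * mad]
    logs = np.log(kept)
    mu, sigma = logs.mean(), logs.std(ddof=1)
    if sigma == 0:
        return None, pvals, qvals
    pvals[ok] = stats.lognorm.sf(gprime[ok], s=sigma, scale=math.exp(mu))
    qvals[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    sig = ok & (qvals <= fdr_q)
    threshold = float(gprime[sig].min()) if sig.any() else None
    return threshold, pvals, qvals


@dataclass
class QtlInterval:
    """A called QTL: closed 1-based interval with its G′ peak."""

    name: str
    chrom: object
    start: int
    end: int
    peak_pos: int
    peak_gprime: float
    origin: str
    n_variants: int


def call_qtl(track: pd.DataFrame, thresholds: dict, min_variants: int = 3,
             merge_gap_bp: float = 2_000_000, trait_prefix: str = "S") -> list[QtlInterval]:
    """Call QTL intervals from an origin-annotated G′ track.

    Within each origin class and chromosome, consecutive above-threshold
    variants whose successive positions lie within ``merge_gap_bp`` form a
    run; runs with at least ``min_variants`` variants become intervals
    spanning [first, last] variant position with the peak at the G′
    maximum.  Intervals are named ``<prefix>-<origin code><chrom>.<rank>``
    (origin codes BC / M / H for maternal / paternal / both), ranked by
    start position within each origin-chromosome track.
    """
    intervals: list[QtlInterval] = []
    for origin, sub in track.groupby("origin"):
        thr = thresholds.get(origin)
        if thr is None:
            continue
        for chrom, csub in sub.groupby("chrom"):
            csub = csub.sort_values("pos", kind="mergesort")
            above = csub[csub["Gprime"] >= thr]
            if above.empty:
                continue
            pos = above["pos"].to_numpy()
            g = above["Gprime"].to_numpy()
            breaks = np.where(np.diff(pos) > merge_gap_bp)[0]
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [len(pos) - 1]])
            rank = 0
            for s, e in zip(starts, ends):
                if e - s + 1 < min_variants:
                    continue
                rank += 1
                peak = s + int(np.argmax(g[s:e + 1]))
                chrom_label = f"{chrom:02d}" if isinstance(chrom, (int, np.integer)) else str(chrom)
                intervals.append(
                    QtlInterval(
                        name=f"{trait_prefix}-{ORIGIN_CODES[origin]}{chrom_label}.{rank}",
                        chrom=chrom, start=int(pos[s]), end=int(pos[e]),
                        peak_pos=int(pos[peak]), peak_gprime=float(g[peak]),
                        origin=origin, n_variants=int(e - s + 1),
                    )
                )
    return intervals


def gprime_scan(counts: pd.DataFrame, window_bp: float = 2_000_000,
                fdr_q: float = 0.05, trim_mad: float = 5.0,
                min_class_variants: int = 50, min_variants: int = 3,
                merge_gap_bp: float = 2_000_000, trait_prefix: str = "S"):
    """Full scan: G → G′ → per-origin thresholds → QTL intervals.

    ``counts`` is a bulk-count track (chrom, pos, ref_hi, alt_hi, ref_lo,
    alt_lo, origin).  Returns ``(track, thresholds, intervals)`` where the
    track carries G, Gprime, pval and qval per variant.
    """
    required = {"chrom", "pos", "ref_hi", "alt_hi", "ref_lo", "alt_lo", "origin"}
    missing = required - set(counts.columns)
    if missing:
        raise DataError(f"bulk-count track missing columns: {sorted(missing)}")
    track = counts.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    track["G"] = g_statistic(track["ref_hi"], track["alt_hi"],
                             track["ref_lo"], track["alt_lo"])
    pieces = []
    thresholds: dict = {}
    for origin, sub in track.groupby("origin"):
        smoothed = tricube_smooth(sub, window_bp)
        try:
            thr, pvals, qvals = gprime_threshold(
                smoothed["Gprime"].to_numpy(), fdr_q=fdr_q,
                trim_mad=trim_mad, min_variants=min_class_variants)
        except DataError:
            thr, pvals, qvals = None, np.nan, np.nan
        smoothed["pval"] = pvals
        smoothed["qval"] = qvals
        thresholds[origin] = thr
        pieces.append(smoothed)
    out = pd.concat(pieces, ignore_index=True)
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    intervals = call_qtl(out, thresholds, min_variants=min_variants,
                         merge_gap_bp=merge_gap_bp, trait_prefix=trait_prefix)
    return out, thresholds, intervals


def intervals_to_frame(intervals: list[QtlInterval]) -> pd.DataFrame:
    """BED-like table of called QTL intervals."""
    return pd.DataFrame(
        [{"chrom": q.chrom, "start": q.start, "end": q.end, "name": q.name,
          "peak_pos": q.peak_pos, "peak_gprime": q.peak_gprime,
          "origin": q.origin, "n_variants": q.n_variants} for q in intervals]
    )
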