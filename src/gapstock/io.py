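"""Table ingestion and emission; TSV is the canonical interchange format.

Coordinates are 1-based and intervals closed throughout (VCF convention).
Bulk allele counts may also be read from a VCF whose first two samples
(or two named samples) carry AD allele-depth fields for the tolerant and
sensitive pools; only biallelic sites are used.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DataError

BULK_COLUMNS = ("chrom", "pos", "ref_hi", "alt_hi", "ref_lo", "alt_lo", "origin")


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate a tidy phenotype table.

    Requires columns hybrid_id, year, trait, value (an optional
    ``replicate`` column is honoured); values must lie in [0, 1] and
    (hybrid_id, year, trait[, replicate]) must be unique.  Errors cite
    1-based data line numbers.
    """
    df = pd.read_csv(path, sep=_sep(path))
    required = {"hybrid_id", "year", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing phenotype columns {sorted(missing)}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[df["value"].isna() | (df["value"] < 0) | (df["value"] > 1)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise DataError(f"{path}: value outside [0, 1] or non-numeric at line(s) {lines}")
    key = ["hybrid_id", "year", "trait"] + (["replicate"] if "replicate" in df.columns else [])
    dup = df.duplicated(subset=key)
    if dup.any():
        lines = ", ".join(str(i + 2) for i in df.index[dup][:10])
        raise DataError(f"{path}: duplicate (hybrid, year, trait) records at line(s) {lines}")
    df["hybrid_id"] = df["hybrid_id"].astype(str)
    df["year"] = df["year"].astype(int)
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep=_sep(path), index=False)


def read_genotypes(path) -> pd.DataFrame:
    """Read a wide genotype table: hybrid_id column + one column per marker.

    Empty cells, 'NA' and './.' are treated as missing calls.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str,
                     na_values=["", "NA", "NaN", "./.", "-"], keep_default_na=True)
    if "hybrid_id" not in df.columns:
        raise DataError(f"{path}: genotype table must have a hybrid_id column")
    if df["hybrid_id"].duplicated().any():
        raise DataError(f"{path}: duplicate hybrid_id rows")
    return df.set_index("hybrid_id")


def write_genotypes(geno: pd.DataFrame, path) -> None:
    geno.to_csv(path, sep=_sep(path), index=True, index_label="hybrid_id")


def read_bulk_counts(path, fmt: Optional[str] = None,
                     sample_hi: Optional[str] = None,
                     sample_lo: Optional[str] = None) -> pd.DataFrame:
    """Read a per-variant bulk allele-count track from TSV or VCF.

    TSV columns: chrom, pos, ref_hi, alt_hi, ref_lo, alt_lo, origin
    (hi = tolerant bulk, lo = sensitive bulk).  For VCF, the two bulk
    samples must expose FORMAT/AD; multiallelic records are skipped with
    a warning and origin is taken from INFO/ORIGIN when present.  The
    returned track is sorted by (chrom, pos); unsorted input is sorted
    with a warning.
    """
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "tsv":
        try:
            df = pd.read_csv(path, sep=_sep(path))
        except pd.errors.EmptyDataError:
            return pd.DataFrame(columns=list(BULK_COLUMNS))
        missing = set(BULK_COLUMNS) - set(df.columns) - {"origin"}
        if missing:
            raise DataError(f"{path}: bulk-count table missing columns {sorted(missing)}")
        if "origin" not in df.columns:
            df["origin"] = "both"
    elif fmt == "vcf":
        df = _read_bulk_vcf(path, sample_hi, sample_lo)
    else:
        raise DataError(f"unknown bulk-count format {fmt!r}")
    for col in ("ref_hi", "alt_hi", "ref_lo", "alt_lo"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
        if (df[col] < 0).any():
            raise DataError(f"{path}: negative allele depth in column {col}")
    if not df.empty:
        sorted_df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if not (df.reset_index(drop=True)[["chrom", "pos"]]
                .equals(sorted_df[["chrom", "pos"]])):
            warnings.warn(f"{path}: variants not sorted by position; sorting", stacklevel=2)
        df = sorted_df
    return df.reset_index(drop=True)


def _read_bulk_vcf(path, sample_hi, sample_lo) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if sample_hi is None or sample_lo is None:
            if len(samples) < 2:
                raise DataError(f"{path}: VCF needs two bulk samples")
            sample_hi, sample_lo = samples[0], samples[1]
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                warnings.warn(f"{path}: skipping non-biallelic record at "
                              f"{rec.chrom}:{rec.pos}", stacklevel=2)
                continue
            try:
                ad_hi = rec.samples[sample_hi]["AD"]
                ad_lo = rec.samples[sample_lo]["AD"]
            except KeyError:
                raise DataError(f"{path}: record {rec.chrom}:{rec.pos} lacks FORMAT/AD")
            if ad_hi is None or ad_lo is None or None in ad_hi or None in ad_lo:
                raise DataError(f"{path}: record {rec.chrom}:{rec.pos} lacks AD depths")
            origin = rec.info.get("ORIGIN", "both")
            if isinstance(origin, tuple):
                origin = origin[0]
            rows.append({"chrom": rec.chrom, "pos": rec.pos,
                         "ref_hi": ad_hi[0], "alt_hi": ad_hi[1],
                         "ref_lo": ad_lo[0], "alt_lo": ad_lo[1], "origin": origin})
    return pd.DataFrame(rows, columns=list(BULK_COLUMNS))


def write_bulk_counts(track: pd.DataFrame, path) -> None:
    cols = [c for c in track.columns if c in BULK_COLUMNS or c == "marker_id"]
    track[cols].to_csv(path, sep=_sep(path), index=False)


def read_gene_table(path) -> pd.DataFrame:
    """Read a gene table for the candidate filter cascade."""
    df = pd.read_csv(path, sep=_sep(path))
    required = {"gene_id", "chrom", "start", "end", "expressed",
                "variant_origin", "annotation", "promoter_variant_only", "is_deg"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: gene table missing columns {sorted(missing)}")
    for col in ("expressed", "promoter_variant_only", "is_deg"):
        df[col] = df[col].map(_to_bool)
    return df


def _to_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise DataError(f"cannot interpret {x!r} as a boolean flag")


def read_keywords(path) -> list[str]:
    text = Path(path).read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def read_gap_table(path, opv_col: str = "OPV",
                   exclude: tuple = ("GPV",)) -> tuple[pd.DataFrame, pd.Series]:
    """Read a published-style marker-genotype + OPV table.

    Expected shape (the layout of published KASP panel tables): one row
    per hybrid with a ``hybrid_id`` column, one column per marker holding
    genotype calls, an ``OPV`` column with the observed phenotype, and
    optionally a precomputed ``GPV`` column (ignored for fitting).
    Returns (genotype table, OPV series).
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str,
                     na_values=["", "NA", "NaN", "./.", "-"])
    if "hybrid_id" not in df.columns or opv_col not in df.columns:
        raise DataError(f"{path}: need hybrid_id and {opv_col} columns")
    df = df.set_index("hybrid_id")
    opv = pd.to_numeric(df[opv_col], errors="raise")
    drop = [c for c in df.columns if c == opv_col or c in exclude]
    geno = df.drop(columns=drop)
    return geno, opv.rename("OPV")
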