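"""Candidate-gene filter cascade within QTL intervals.

Genes inside a QTL confidence interval are removed in four fixed stages:

1. ``not_expressed`` — no expression evidence;
2. ``origin_mismatch`` — the gene's parental variant origin is
   inconsistent with the parent the QTL was mapped from;
3. ``annotation_unrelated`` — functional annotation matches none of the
   trait keywords (case-insensitive substring);
4. ``promoter_nonDEG`` — the gene's only variants are promoter variants
   and it is not differentially expressed.

Every removal is tallied in a ledger with exact count conservation
(n_input = n_kept + sum of removals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

from .bsa import QtlInterval
from .exceptions import DataError

STAGES = ("not_expressed", "origin_mismatch", "annotation_unrelated", "promoter_nonDEG")

GENE_COLUMNS = ("gene_id", "chrom", "start", "end", "expressed",
                "variant_origin", "annotation", "promoter_variant_only", "is_deg")


def default_keywords() -> list[str]:
    """The shipped annotation keyword list (salt/alkali/ion transport etc.)."""
    text = resources.files("gapstock").joinpath("data/keywords.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


@dataclass
class FilterLedger:
    """Auditable per-stage removal counts for one filter run."""

    n_input: int = 0
    removed: dict = field(default_factory=lambda: {s: 0 for s in STAGES})
    n_kept: int = 0

    @property
    def conserved(self) -> bool:
        return self.n_input == self.n_kept + sum(self.removed.values())

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "removed": dict(self.removed), "n_kept": self.n_kept}


def _stage_mask(genes: pd.DataFrame, stage: str, qtl_origin: Optional[str],
                keywords: Sequence[str]) -> pd.Series:
    """True where a gene is removed by the given stage."""
    if stage == "not_expressed":
        return ~genes["expressed"].astype(bool)
    if stage == "origin_mismatch":
        allowed = {"both"} if qtl_origin is None else {qtl_origin, "both"}
        return ~genes["variant_origin"].isin(allowed)
    if stage == "annotation_unrelated":
        kws = [k.lower() for k in keywords]
        ann = genes["annotation"].fillna("").astype(str).str.lower()
        return ~ann.map(lambda a: any(k in a for k in kws))
    if stage == "promoter_nonDEG":
        return genes["promoter_variant_only"].astype(bool) & ~genes["is_deg"].astype(bool)
    raise DataError(f"unknown filter stage {stage!r}")


def filter_candidates(
    genes: pd.DataFrame,
    qtl: Optional[QtlInterval] = None,
    keywords: Optional[Sequence[str]] = None,
    stages: Sequence[str] = STAGES,
) -> tuple[pd.DataFrame, FilterLedger]:
    """Run the filter cascade; returns (kept genes, ledger).

    When ``qtl`` is given, only genes overlapping its interval on the same
    chromosome enter the cascade and stage 2 uses its parental origin;
    otherwise all genes enter and stage 2 only removes genes with no
    parental variant at all.  ``stages`` exists to demonstrate that the
    stage order matters; the default order is the canonical one.
    """
    if set(stages) != set(STAGES):
        raise DataError("stages must be a permutation of the four canonical stages")
    keywords = list(keywords) if keywords is not None else default_keywords()

    if qtl is not None:
        inside = (
            (genes["chrom"] == qtl.chrom)
            & (genes["end"] >= qtl.start)
            & (genes["start"] <= qtl.end)
        )
        pool = genes[inside].copy()
        origin = qtl.origin
    else:
        pool = genes.copy()
        origin = None

    ledger = FilterLedger(n_input=len(pool))
    for stage in stages:
        if pool.empty:
            ledger.removed[stage] = 0
            continue
        drop = _stage_mask(pool, stage, origin, keywords)
        ledger.removed[stage] = int(drop.sum())
        pool = pool[~drop]
    ledger.n_kept = len(pool)
    assert ledger.conserved
    return pool.reset_index(drop=True), ledger
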