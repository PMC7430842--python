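"""End-to-end driver: simulate-or-load → phenotype stats → G′ scan →
candidate filter → GAP model → simulative selection, with a run log."""

from __future__ import annotations

import json
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .bsa import gprime_scan, intervals_to_frame
from .candidates import default_keywords, filter_candidates
from .exceptions import ConfigError, GapstockError
from .gap import GapModel, kfold_cv, simulative_selection
from .phenotypes import hybrid_means, summarize
from .simulate import SimConfig, config_from_dict, config_to_dict, simulate_bulk_counts, simulate_population

TRAIT_PREFIXES = {"SID": "S", "AID": "A", "SAID": "SA"}


@dataclass
class PipelineConfig:
    """Run configuration; mirrors the YAML layout."""

    trait: str = "SID"
    simulate: Optional[SimConfig] = None
    phenotypes: Optional[str] = None
    genotypes: Optional[str] = None
    bulk_counts: Optional[str] = None
    genes: Optional[str] = None
    keywords: Optional[str] = None
    # bsascan knobs
    window_bp: float = 2_000_000
    fdr_q: float = 0.05
    trim_mad: float = 5.0
    min_variants: int = 3
    merge_gap_bp: float = 2_000_000
    # gap knobs
    k: int = 5
    seed: int = 0
    criteria: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    min_class_size: int = 2

    def validate(self) -> None:
        if self.simulate is None and self.phenotypes is None:
            raise ConfigError("phenotypes", "either a simulate block or a phenotype path is required")
        if self.simulate is None and self.genotypes is None:
            raise ConfigError("genotypes", "genotype table required for the GAP stage")
        if not (0 < self.fdr_q < 1):
            raise ConfigError("fdr_q", "must be in (0, 1)")
        if self.window_bp <= 0:
            raise ConfigError("window_bp", "must be positive")
        if self.k < 2:
            raise ConfigError("k", "must be >= 2")
        for p_name in ("phenotypes", "genotypes", "bulk_counts", "genes", "keywords"):
            p = getattr(self, p_name)
            if p is not None and not Path(p).exists():
                raise ConfigError(p_name, f"file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = config_from_dict(sim)
        cfg.validate()
        return cfg


def _float_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; write reports under ``outdir``; return artifacts.

    Reports are written deterministically (same config and seed → byte-
    identical files).  Any stage failure is re-raised with the stage name.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    prefix = TRAIT_PREFIXES.get(config.trait, config.trait[:1].upper())

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                return None

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, GapstockError):
                    raise GapstockError(f"pipeline stage '{name}' failed: {exc}") from exc
                if isinstance(exc, GapstockError):
                    raise GapstockError(f"pipeline stage '{name}' failed: {exc}") from exc
        return _Stage()

    truth = None
    with stage("input"):
        if config.simulate is not None:
            geno, pheno, truth = simulate_population(config.simulate)
            counts = simulate_bulk_counts(geno, pheno, truth, config.simulate)
            io.write_phenotypes(pheno, outdir / "phenotypes.tsv")
            io.write_genotypes(geno, outdir / "genotypes.tsv")
            io.write_bulk_counts(counts, outdir / "bulk_counts.tsv")
            truth.to_json(outdir / "truth.json")
        else:
            pheno = io.read_phenotypes(config.phenotypes)
            geno = io.read_genotypes(config.genotypes) if config.genotypes else None
            counts = io.read_bulk_counts(config.bulk_counts) if config.bulk_counts else None
    artifacts["phenotypes"], artifacts["genotypes"], artifacts["bulk_counts"] = pheno, geno, counts

    with stage("phenostats"):
        summary = summarize(pheno)
        _float_csv(summary, outdir / "trait_summary.tsv")
        artifacts["trait_summary"] = summary

    intervals = []
    if counts is not None and len(counts):
        with stage("bsascan"):
            track, thresholds, intervals = gprime_scan(
                counts, window_bp=config.window_bp, fdr_q=config.fdr_q,
                trim_mad=config.trim_mad, min_variants=config.min_variants,
                merge_gap_bp=config.merge_gap_bp, trait_prefix=prefix)
            _float_csv(track, outdir / "gprime_track.tsv")
            qtl_frame = intervals_to_frame(intervals)
            _float_csv(qtl_frame, outdir / "qtl_intervals.tsv")
            artifacts["gprime_track"] = track
            artifacts["thresholds"] = thresholds
            artifacts["qtl_intervals"] = intervals

    if config.genes is not None:
        with stage("candfilter"):
            genes = io.read_gene_table(config.genes)
            keywords = io.read_keywords(config.keywords) if config.keywords else default_keywords()
            kept_frames, ledgers = [], {}
            targets = intervals if intervals else [None]
            for qtl in targets:
                kept, ledger = filter_candidates(genes, qtl=qtl, keywords=keywords)
                kept_frames.append(kept)
                ledgers[qtl.name if qtl else "all"] = ledger.to_dict()
            kept_all = (pd.concat(kept_frames).drop_duplicates("gene_id")
                        .reset_index(drop=True)) if kept_frames else genes.iloc[0:0]
            _float_csv(kept_all, outdir / "candidate_genes.tsv")
            with open(outdir / "filter_ledger.json", "w") as fh:
                json.dump(ledgers, fh, indent=1, sort_keys=True)
            artifacts["candidates"] = kept_all
            artifacts["filter_ledgers"] = ledgers

    if geno is not None:
        with stage("gapmodel"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = GapModel.from_tables(pheno, geno, config.trait,
                                               min_class_size=config.min_class_size).fit()
                gpv = results.predict()
            opv = hybrid_means(pheno, config.trait)
            acc = results.accuracy()
            cv = kfold_cv(pheno, geno, config.trait, k=config.k, seed=config.seed,
                          min_class_size=config.min_class_size)
            sel = simulative_selection(gpv, opv, config.criteria)
            results.save(outdir / "gap_model.json")
            _float_csv(pd.DataFrame({"hybrid_id": gpv.index, "GPV": gpv.to_numpy(),
                                     "OPV": opv.loc[gpv.index].to_numpy()}),
                       outdir / "gpv_opv.tsv")
            _float_csv(sel, outdir / "selection_report.tsv")
            with open(outdir / "cv.json", "w") as fh:
                json.dump({"pooled_accuracy": cv.pooled_accuracy,
                           "fold_accuracies": cv.fold_accuracies,
                           "k": cv.k, "seed": cv.seed}, fh, indent=1)
            artifacts["gap_results"] = results
            artifacts["accuracy"] = acc
            artifacts["cv"] = cv
            artifacts["selection_report"] = sel

    with stage("runlog"):
        log = {
            "gapstock_version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "trait": config.trait,
            "seed": config.seed,
            "knobs": {
                "window_bp": config.window_bp, "fdr_q": config.fdr_q,
                "trim_mad": config.trim_mad, "min_variants": config.min_variants,
                "merge_gap_bp": config.merge_gap_bp, "k": config.k,
                "criteria": list(config.criteria), "min_class_size": config.min_class_size,
            },
            "simulate": config_to_dict(config.simulate) if config.simulate else None,
        }
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1, sort_keys=True)
    artifacts["truth"] = truth
    return artifacts
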