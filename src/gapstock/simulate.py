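"""Synthetic F1 apple-rootstock populations for salt/alkali tolerance studies.

Emulates a pseudo-testcross between a heterozygous tolerant mother
('Baleng Crab'-like) and a sensitive father ('M9'-like): every marker is
heterozygous in one or both parents and segregates 1:1 (one parent het) or
1:2:1 (both het).  Injury-index phenotypes (bounded in [0, 1], higher =
more damage) are additive over QTL allele dosages plus independent
per-year environmental noise; extreme phenotype tails form sequencing
bulks whose allele depths are Poisson/binomial sampled.

Markers are unlinked except those placed exactly at a QTL position, which
are fully linked to it — the downstream prediction model treats markers
independently, so no recombination map is simulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError

SEG_CLASSES = ("maternal_het", "paternal_het", "both_het")
ORIGINS = ("maternal", "paternal", "both")

#: segregation class implied by a QTL's parent of origin
_ORIGIN_TO_SEG = {
    "maternal": "maternal_het",
    "paternal": "paternal_het",
    "both": "both_het",
}
_SEG_TO_ORIGIN = {v: k for k, v in _ORIGIN_TO_SEG.items()}

# genotype call strings by alt-allele dosage
_CALL_11 = {0: "A/A", 1: "A/T"}           # 1:1 segregation (one parent het)
_CALL_121 = {0: "A/A", 1: "A/T", 2: "T/T"}  # 1:2:1 (both parents het)


@dataclass(frozen=True)
class QtlSpec:
    """One simulated QTL: location, additive effect, parent of origin.

    ``effect`` is the injury-index change per alt allele; negative effects
    confer tolerance (lower injury).  Each QTL is tagged by a cluster of
    ``n_linked`` markers fully linked to it (identical segregation),
    spread over ``linked_span_bp`` around the locus — the stand-in for
    tight local linkage, since no recombination map is simulated.  The
    marker nearest the locus carries the causal effect.
    """

    chrom: int
    pos: int
    effect: float
    origin: str = "maternal"
    n_linked: int = 5
    linked_span_bp: int = 1_000_000


def _default_qtls() -> tuple[QtlSpec, ...]:
    # Six moderate QTLs spread over the genome, mixed parental origins and
    # signs; together with the default env_sd this yields a broad-sense
    # heritability near the ~0.6 seen for injury indices in apple rootstock.
    return (
        QtlSpec(2, 11_000_000, -0.12, "maternal"),
        QtlSpec(7, 6_500_000, 0.10, "paternal"),
        QtlSpec(11, 18_000_000, -0.08, "maternal"),
        QtlSpec(14, 9_000_000, 0.11, "both"),
        QtlSpec(15, 22_000_000, -0.10, "paternal"),
        QtlSpec(16, 14_000_000, -0.09, "both"),
    )


@dataclass
class SimConfig:
    """Study design of the simulated cross.

    Defaults mirror the real experiment: 3258 F1 hybrids phenotyped over
    three years, sequencing bulks of ~25 extreme hybrids, mean injury index
    near 0.5 with environmental noise sized for H² ≈ 0.6, and ~60× pooled
    read depth.
    """

    n_hybrids: int = 3258
    n_markers: int = 2000
    n_chromosomes: int = 17
    chrom_length: int = 30_000_000
    qtl_specs: Sequence[QtlSpec] = field(default_factory=_default_qtls)
    trait: str = "SID"
    trait_mean: float = 0.56
    env_sd: float = 0.11
    n_years: int = 3
    first_year: int = 2015
    bulk_size: int = 25
    read_depth_mean: float = 60.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_hybrids <= 0:
            raise ConfigError("n_hybrids", "must be positive")
        if self.n_markers < 0:
            raise ConfigError("n_markers", "must be non-negative")
        if self.n_chromosomes <= 0:
            raise ConfigError("n_chromosomes", "must be positive")
        if self.chrom_length <= 0:
            raise ConfigError("chrom_length", "must be positive")
        if self.n_years <= 0:
            raise ConfigError("n_years", "must be positive")
        if self.env_sd < 0:
            raise ConfigError("env_sd", "must be non-negative")
        if not (1 <= self.bulk_size <= self.n_hybrids // 2):
            raise ConfigError("bulk_size", "must satisfy 1 <= bulk_size <= n_hybrids/2")
        if self.read_depth_mean < 0:
            raise ConfigError("read_depth_mean", "must be non-negative")
        for i, q in enumerate(self.qtl_specs):
            if not math.isfinite(q.effect):
                raise ConfigError("qtl_specs", f"QTL {i}: effect must be finite")
            if not (1 <= q.chrom <= self.n_chromosomes):
                raise ConfigError("qtl_specs", f"QTL {i}: chromosome {q.chrom} out of range")
            if not (1 <= q.pos <= self.chrom_length):
                raise ConfigError("qtl_specs", f"QTL {i}: position {q.pos} out of range")
            if q.origin not in ORIGINS:
                raise ConfigError("qtl_specs", f"QTL {i}: origin {q.origin!r} unknown")
            if q.n_linked < 1:
                raise ConfigError("qtl_specs", f"QTL {i}: n_linked must be >= 1")
            if q.linked_span_bp < 0:
                raise ConfigError("qtl_specs", f"QTL {i}: linked_span_bp must be >= 0")


@dataclass
class TruthSet:
    """Ground truth of a simulated population, for parameter-recovery tests.

    ``marker_map`` has one row per marker (marker_id, chrom, pos, seg_class,
    origin, is_qtl, effect); ``dosages`` is the hybrid x marker alt-allele
    dosage matrix; ``genetic_value`` is the per-hybrid sum of QTL effects.
    """

    marker_map: pd.DataFrame
    dosages: pd.DataFrame
    genetic_value: pd.Series
    qtls: list[dict]

    def to_json(self, path) -> None:
        payload = {
            "qtls": self.qtls,
            "markers": self.marker_map.to_dict(orient="records"),
            "genetic_value": {str(k): float(v) for k, v in self.genetic_value.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _hybrid_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"H{i:0{width}d}" for i in range(1, n + 1)]


def simulate_population(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Draw an F1 population: genotypes, multi-year phenotypes, and truth.

    Returns
    -------
    geno : DataFrame
        hybrid x marker genotype calls (``"A/A"``, ``"A/T"``, ``"T/T"``).
    pheno : DataFrame
        tidy records (hybrid_id, year, trait, value) with value in [0, 1].
    truth : TruthSet
    """
    config.validate()
    rng = np.random.default_rng([int(config.rng_seed), 0x5EED])
    hybrids = _hybrid_ids(config.n_hybrids)

    # marker map: background markers spread over chromosomes + one marker
    # fully linked to each QTL
    rows = []
    per_chrom = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per_chrom[: config.n_markers % config.n_chromosomes] += 1
    for chrom in range(1, config.n_chromosomes + 1):
        k = per_chrom[chrom - 1]
        pos = np.sort(rng.integers(1, config.chrom_length + 1, size=k))
        cls = rng.choice(SEG_CLASSES, size=k)
        for j in range(k):
            rows.append(
                {
                    "marker_id": f"M{chrom:02d}_{j + 1:05d}",
                    "chrom": chrom,
                    "pos": int(pos[j]),
                    "seg_class": cls[j],
                    "is_qtl": False,
                    "effect": 0.0,
                }
            )
    for row in rows:
        row["qtl_id"] = ""
        row["causal"] = False
    qtl_records = []
    for i, q in enumerate(config.qtl_specs, start=1):
        qtl_id = f"Q{i:02d}"
        if q.n_linked == 1:
            offsets = np.array([0.0])
        else:
            offsets = np.linspace(-q.linked_span_bp / 2, q.linked_span_bp / 2, q.n_linked)
        causal_j = int(np.argmin(np.abs(offsets)))
        for j, off in enumerate(offsets):
            pos_j = int(np.clip(q.pos + off, 1, config.chrom_length))
            rows.append(
                {
                    "marker_id": f"{qtl_id}_{j + 1}",
                    "chrom": q.chrom,
                    "pos": pos_j,
                    "seg_class": _ORIGIN_TO_SEG[q.origin],
                    "is_qtl": True,
                    "effect": float(q.effect) if j == causal_j else 0.0,
                    "qtl_id": qtl_id,
                    "causal": j == causal_j,
                }
            )
        qtl_records.append(
            {"qtl_id": qtl_id, "marker_id": f"{qtl_id}_{causal_j + 1}",
             "chrom": q.chrom, "pos": int(q.pos),
             "effect": float(q.effect), "origin": q.origin}
        )
    marker_map = pd.DataFrame(rows)
    marker_map["origin"] = marker_map["seg_class"].map(_SEG_TO_ORIGIN)
    marker_map = marker_map.sort_values(["chrom", "pos", "marker_id"]).reset_index(drop=True)

    # alt-allele dosages per hybrid: Bernoulli(1/2) for 1:1 markers,
    # Binomial(2, 1/2) for 1:2:1 markers
    n, m = config.n_hybrids, len(marker_map)
    dosage = np.zeros((n, m), dtype=np.int8)
    both = (marker_map["seg_class"] == "both_het").to_numpy()
    dosage[:, ~both] = rng.integers(0, 2, size=(n, (~both).sum()), dtype=np.int8)
    dosage[:, both] = rng.binomial(2, 0.5, size=(n, both.sum())).astype(np.int8)
    # markers in a QTL cluster are fully linked: one shared dosage vector
    for qtl_id in pd.unique(marker_map.loc[marker_map["qtl_id"] != "", "qtl_id"]):
        cols = np.flatnonzero((marker_map["qtl_id"] == qtl_id).to_numpy())
        if marker_map.loc[cols[0], "seg_class"] == "both_het":
            shared = rng.binomial(2, 0.5, size=n).astype(np.int8)
        else:
            shared = rng.integers(0, 2, size=n, dtype=np.int8)
        dosage[:, cols] = shared[:, None]
    dosages = pd.DataFrame(dosage, index=pd.Index(hybrids, name="hybrid_id"),
                           columns=marker_map["marker_id"].to_numpy())

    # genotype call strings
    geno = pd.DataFrame(index=dosages.index, columns=dosages.columns, dtype=object)
    calls_11 = np.array([_CALL_11[0], _CALL_11[1]], dtype=object)
    calls_121 = np.array([_CALL_121[0], _CALL_121[1], _CALL_121[2]], dtype=object)
    geno.loc[:, ~both] = calls_11[dosage[:, ~both]]
    geno.loc[:, both] = calls_121[dosage[:, both]]

    # genetic values and phenotypes
    effects = marker_map["effect"].to_numpy()
    gvalue = dosage @ effects
    genetic_value = pd.Series(gvalue, index=dosages.index, name="genetic_value")

    records = []
    for y in range(config.n_years):
        year = config.first_year + y
        noise = rng.normal(0.0, config.env_sd, size=n) if config.env_sd > 0 else np.zeros(n)
        values = np.clip(config.trait_mean + gvalue + noise, 0.0, 1.0)
        records.append(
            pd.DataFrame(
                {"hybrid_id": hybrids, "year": year, "trait": config.trait, "value": values}
            )
        )
    pheno = pd.concat(records, ignore_index=True)

    truth = TruthSet(marker_map=marker_map, dosages=dosages,
                     genetic_value=genetic_value, qtls=qtl_records)
    return geno, pheno, truth


def simulate_bulk_counts(
    geno: pd.DataFrame,
    pheno: pd.DataFrame,
    truth: TruthSet,
    config: SimConfig,
) -> pd.DataFrame:
    """Pooled-sequencing allele depths for the two extreme-phenotype bulks.

    The tolerant bulk is the ``bulk_size`` hybrids with the lowest mean
    injury index, the sensitive bulk the highest (injury is negatively
    oriented with respect to tolerance).  At each variant the per-bulk
    depth is Poisson(read_depth_mean) and alt reads are Binomial(depth, p)
    with p the bulk alt-allele frequency implied by member genotypes.
    Zero-depth variants are retained with zero counts (missing).

    Columns: chrom, pos, marker_id, ref_hi, alt_hi, ref_lo, alt_lo, origin,
    where *_hi is the tolerant (high-tolerance) bulk and *_lo the sensitive.
    """
    from .phenotypes import select_bulks

    config.validate()
    rng = np.random.default_rng([int(config.rng_seed), 0xB0B])
    tolerant, sensitive = select_bulks(pheno, config.trait, config.bulk_size)

    mm = truth.marker_map
    out = pd.DataFrame(
        {"chrom": mm["chrom"].to_numpy(), "pos": mm["pos"].to_numpy(),
         "marker_id": mm["marker_id"].to_numpy(), "origin": mm["origin"].to_numpy()}
    )
    d = truth.dosages
    for tag, members in (("hi", tolerant), ("lo", sensitive)):
        sub = d.loc[members, mm["marker_id"]]
        p = sub.sum(axis=0).to_numpy() / (2.0 * len(members))
        depth = rng.poisson(config.read_depth_mean, size=len(mm))
        alt = rng.binomial(depth, p)
        out[f"ref_{tag}"] = depth - alt
        out[f"alt_{tag}"] = alt
    out = out[["chrom", "pos", "marker_id", "ref_hi", "alt_hi", "ref_lo", "alt_lo", "origin"]]
    return out.sort_values(["chrom", "pos", "marker_id"]).reset_index(drop=True)


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain mapping (e.g. parsed YAML)."""
    d = dict(d)
    qtls = d.pop("qtl_specs", None)
    cfg = SimConfig(**d) if qtls is None else SimConfig(
        qtl_specs=tuple(QtlSpec(**q) for q in qtls), **d
    )
    cfg.validate()
    return cfg


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["qtl_specs"] = [asdict(q) for q in config.qtl_specs]
    return d
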