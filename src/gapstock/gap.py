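"""Additive genomics-assisted prediction (GAP) from marker genotype effects.

The model is deliberately simple and matches how KASP-marker panels are
used in rootstock breeding: for each marker ``m`` and genotype class
``g``, the genotype effect is

    e_{m,g} = mean(y | genotype g at m) − ybar,

the deviation of the class phenotype mean from the population mean
``ybar``.  The marker effect ``E_m = max_g |e_{m,g}|`` summarises a
marker's importance.  The genomics predicted value of hybrid ``i`` is

    GPV_i = ybar + sum_m e_{m, g_i(m)},

with missing or unseen genotype classes contributing zero.  Prediction
accuracy is the Pearson correlation between GPV and the observed
phenotype value (OPV); model quality is assessed by k-fold
cross-validation and by simulative selection (what fraction of hybrids
selected on GPV at a cutoff also meet the cutoff on OPV).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .phenotypes import hybrid_means


@dataclass
class Accuracy:
    """Pearson accuracy of GPV against OPV plus the regression line."""

    r: float
    p: float
    slope: float
    intercept: float
    n: int


def prediction_accuracy(gpv: pd.Series, opv: pd.Series) -> Accuracy:
    """Pearson r between predicted and observed values, with the OPV~GPV
    least-squares line (the regression drawn through a GPV/OPV scatter)."""
    common = gpv.index.intersection(opv.index)
    if len(common) < 3:
        raise DataError("prediction_accuracy: need >= 3 hybrids with GPV and OPV")
    x = gpv.loc[common].to_numpy(dtype=float)
    y = opv.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("prediction_accuracy: constant GPV or OPV vector")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return Accuracy(r=float(r), p=float(p), slope=float(slope),
                    intercept=float(intercept), n=len(common))


class GapModel:
    """Marker genotype-effect model for a single injury-index trait.

    Parameters
    ----------
    endog : Series
        Per-hybrid observed phenotype (OPV), indexed by hybrid_id.
    geno : DataFrame
        hybrid x marker categorical genotype calls; NaN = missing call.
    trait : str, optional
        Trait label carried into the results metadata.
    min_class_size : int
        Genotype classes observed in fewer hybrids get effect 0 (with a
        warning) — their class mean is too noisy to use.
    effect_summary : {"max_abs", "range"}
        How the scalar marker effect E_m summarises the genotype effects:
        largest absolute deviation (default) or max-minus-min range.
    """

    def __init__(self, endog: pd.Series, geno: pd.DataFrame, trait: Optional[str] = None,
                 min_class_size: int = 2, effect_summary: str = "max_abs"):
        if effect_summary not in ("max_abs", "range"):
            raise DataError(f"unknown effect_summary {effect_summary!r}")
        common = endog.index.intersection(geno.index)
        if len(common) == 0:
            raise DataError("GapModel: no hybrids shared between phenotype and genotype")
        self.endog = endog.loc[common].astype(float)
        self.geno = geno.loc[common]
        self.trait = trait
        self.min_class_size = int(min_class_size)
        self.effect_summary = effect_summary

    @classmethod
    def from_tables(cls, pheno: pd.DataFrame, geno: pd.DataFrame, trait: str,
                    **kwargs) -> "GapModel":
        """Build from a tidy phenotype table (per-hybrid means across years)
        and a wide genotype table."""
        return cls(hybrid_means(pheno, trait), geno, trait=trait, **kwargs)

    def fit(self) -> "GapResults":
        ybar = float(self.endog.mean())
        effects: dict[str, dict[str, float]] = {}
        for marker in self.geno.columns:
            calls = self.geno[marker]
            mask = calls.notna()
            classes = calls[mask].groupby(calls[mask]).groups
            marker_effects: dict[str, float] = {}
            if len(classes) <= 1:
                for g in classes:
                    marker_effects[str(g)] = 0.0
            else:
                for g, idx in classes.items():
                    if len(idx) < self.min_class_size:
                        warnings.warn(
                            f"marker {marker}: genotype class {g!r} has only "
                            f"{len(idx)} hybrids; effect set to 0", stacklevel=2)
                        marker_effects[str(g)] = 0.0
                    else:
                        marker_effects[str(g)] = float(self.endog.loc[idx].mean() - ybar)
            effects[str(marker)] = marker_effects
        return GapResults(mean_phenotype=ybar, genotype_effects=effects,
                          trait=self.trait, n_hybrids=len(self.endog),
                          effect_summary=self.effect_summary, model=self)


class GapResults:
    """Fitted GAP model: population mean, genotype effects, predictions."""

    def __init__(self, mean_phenotype: float, genotype_effects: dict,
                 trait: Optional[str] = None, n_hybrids: Optional[int] = None,
                 effect_summary: str = "max_abs", model: Optional[GapModel] = None):
        self.mean_phenotype = float(mean_phenotype)
        self.genotype_effects = genotype_effects
        self.trait = trait
        self.n_hybrids = n_hybrids
        self.effect_summary = effect_summary
        self.model = model

    @property
    def marker_effects(self) -> pd.Series:
        """Scalar effect E_m per marker (max |e| or range, per the model)."""
        out = {}
        for marker, eff in self.genotype_effects.items():
            vals = np.array(list(eff.values()), dtype=float)
            if vals.size == 0:
                out[marker] = 0.0
            elif self.effect_summary == "range":
                out[marker] = float(vals.max() - vals.min())
            else:
                out[marker] = float(np.abs(vals).max())
        return pd.Series(out, name="marker_effect").sort_values(ascending=False)

    def predict(self, geno: Optional[pd.DataFrame] = None) -> pd.Series:
        """GPV per hybrid: population mean plus summed genotype effects.

        Missing calls and genotype classes unseen in training contribute
        zero; a hybrid with no usable call at any marker gets GPV = ybar
        (flagged with a warning).
        """
        if geno is None:
            if self.model is None:
                raise DataError("predict: no genotype table given and none stored")
            geno = self.model.geno
        gpv = np.full(len(geno), self.mean_phenotype)
        used = np.zeros(len(geno), dtype=int)
        for marker in geno.columns:
            eff = self.genotype_effects.get(str(marker))
            if eff is None:
                continue
            contrib = geno[marker].map(lambda g: eff.get(str(g), 0.0) if pd.notna(g) else np.nan)
            seen = contrib.notna().to_numpy()
            gpv += np.where(seen, contrib.fillna(0.0).to_numpy(dtype=float), 0.0)
            used += seen
        if np.any(used == 0):
            warnings.warn(f"{int((used == 0).sum())} hybrid(s) had no usable genotype call; "
                          "GPV set to the population mean", stacklevel=2)
        return pd.Series(gpv, index=geno.index, name="GPV")

    @property
    def fittedvalues(self) -> pd.Series:
        return self.predict()

    def accuracy(self, geno: Optional[pd.DataFrame] = None,
                 opv: Optional[pd.Series] = None) -> Accuracy:
        """Pearson accuracy of GPV vs OPV (training data by default)."""
        if opv is None:
            if self.model is None:
                raise DataError("accuracy: no OPV given and none stored")
            opv = self.model.endog
        return prediction_accuracy(self.predict(geno), opv)

    def summary(self) -> str:
        lines = [
            "Genomics-assisted prediction (additive marker genotype effects)",
            "=" * 64,
            f"Trait: {self.trait or '-'}    hybrids: {self.n_hybrids or '-'}    "
            f"markers: {len(self.genotype_effects)}",
            f"Population mean phenotype (ybar): {self.mean_phenotype:.4f}",
            "",
            f"{'marker':<12}{'genotype':<10}{'n/a effect':>12}",
        ]
        me = self.marker_effects
        lines[-1] = f"{'marker':<14}{'E_m':>8}   genotype effects"
        for marker in me.index:
            eff = self.genotype_effects[marker]
            effs = ", ".join(f"{g}: {e:+.4f}" for g, e in sorted(eff.items()))
            lines.append(f"{marker:<14}{me[marker]:>8.4f}   {effs}")
        if self.model is not None:
            try:
                acc = self.accuracy()
                lines += ["", f"Training accuracy (Pearson r GPV~OPV): {acc.r:.4f}  "
                              f"(slope {acc.slope:.3f}, intercept {acc.intercept:.3f})"]
            except DataError:
                pass
        return "\n".join(lines)

    def plot_regression(self, geno=None, opv=None, ax=None):
        """GPV vs OPV scatter with the fitted regression line."""
        import matplotlib.pyplot as plt

        gpv = self.predict(geno)
        if opv is None:
            opv = self.model.endog
        acc = prediction_accuracy(gpv, opv)
        common = gpv.index.intersection(opv.index)
        if ax is None:
            _, ax = plt.subplots()
        x = gpv.loc[common]
        ax.scatter(x, opv.loc[common], s=8, alpha=0.5)
        xs = np.linspace(float(x.min()), float(x.max()), 50)
        ax.plot(xs, acc.slope * xs + acc.intercept, color="C3")
        ax.set_xlabel("GPV")
        ax.set_ylabel("OPV")
        ax.set_title(f"{self.trait or ''} r = {acc.r:.4f}")
        return ax

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "mean_phenotype": self.mean_phenotype,
            "n_hybrids": self.n_hybrids,
            "effect_summary": self.effect_summary,
            "genotype_effects": self.genotype_effects,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GapResults":
        with open(path) as fh:
            d = json.load(fh)
        return cls(mean_phenotype=d["mean_phenotype"], genotype_effects=d["genotype_effects"],
                   trait=d.get("trait"), n_hybrids=d.get("n_hybrids"),
                   effect_summary=d.get("effect_summary", "max_abs"))


@dataclass
class CvResult:
    """k-fold cross-validation outcome."""

    pooled_accuracy: float
    fold_accuracies: list
    gpv: pd.Series
    opv: pd.Series
    k: int
    seed: int

    @property
    def mean_fold_accuracy(self) -> float:
        vals = [r for r in self.fold_accuracies if r is not None]
        return float(np.mean(vals)) if vals else float("nan")


def kfold_cv(pheno: pd.DataFrame, geno: pd.DataFrame, trait: str, k: int = 5,
             seed: int = 0, min_class_size: int = 2) -> CvResult:
    """Seeded k-fold cross-validation of the GAP model.

    Hybrids are shuffled, split into k near-equal folds; each fold is
    predicted by a model fitted on the remaining hybrids (the population
    mean comes from the training fold only).  The headline number is the
    Pearson r of the pooled held-out GPVs against OPV; per-fold r values
    are also reported (a fold with constant OPV is skipped with a warning).
    """
    if k < 2:
        raise DataError("kfold_cv: k must be >= 2")
    opv = hybrid_means(pheno, trait)
    ids = opv.index.intersection(geno.index).to_numpy()
    if len(ids) < k:
        raise DataError("kfold_cv: fewer hybrids than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.array_split(perm, k)

    pooled = pd.Series(np.nan, index=pd.Index(ids, name="hybrid_id"))
    fold_rs: list = []
    for fold in folds:
        test_ids = ids[fold]
        train_ids = np.setdiff1d(ids, test_ids)
        model = GapModel(opv.loc[train_ids], geno.loc[train_ids], trait=trait,
                         min_class_size=min_class_size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
            gpv = res.predict(geno.loc[test_ids])
        pooled.loc[test_ids] = gpv
        y = opv.loc[test_ids]
        if np.ptp(y.to_numpy()) == 0 or np.ptp(gpv.to_numpy()) == 0 or len(test_ids) < 3:
            warnings.warn("fold with constant or tiny held-out vector: per-fold r skipped",
                          stacklevel=2)
            fold_rs.append(None)
        else:
            fold_rs.append(float(stats.pearsonr(gpv.to_numpy(), y.to_numpy())[0]))
    r = float(stats.pearsonr(pooled.to_numpy(), opv.loc[ids].to_numpy())[0])
    return CvResult(pooled_accuracy=r, fold_accuracies=fold_rs,
                    gpv=pooled, opv=opv.loc[ids], k=k, seed=seed)


def simulative_selection(gpv: pd.Series, opv: pd.Series,
                         criteria: Sequence[float]) -> pd.DataFrame:
    """Truncation selection on GPV at each cutoff, scored against OPV.

    For cutoff c: hybrids with GPV ≤ c are selected (lower injury =
    better); the selection rate is their share of the population and the
    efficiency is the share of selected hybrids whose OPV is also ≤ c.
    A per-individual variant (OPV_i ≤ GPV_i among selected) is reported
    alongside.  Empty selections get rate and efficiency 0.
    """
    common = gpv.index.intersection(opv.index)
    if len(common) == 0:
        raise DataError("simulative_selection: no hybrids with both GPV and OPV")
    g = gpv.loc[common]
    o = opv.loc[common]
    n = len(common)
    rows = []
    for c in criteria:
        sel = g[g <= c]
        n_sel = len(sel)
        consistent = int((o.loc[sel.index] <= c).sum())
        indiv = int((o.loc[sel.index] <= sel).sum())
        rows.append({
            "criterion": float(c),
            "n_selected": n_sel,
            "selection_rate_pct": n_sel / n * 100.0,
            "mean_gpv_selected": float(sel.mean()) if n_sel else 0.0,
            "n_consistent": consistent,
            "efficiency_pct": consistent / n_sel * 100.0 if n_sel else 0.0,
            "n_opv_le_gpv": indiv,
            "efficiency_opv_le_gpv_pct": indiv / n_sel * 100.0 if n_sel else 0.0,
        })
    return pd.DataFrame(rows)


@dataclass
class AssociationResult:
    """Two-group allele association (pooled-variance Student's t)."""

    mean_carrier: float
    mean_noncarrier: float
    n_carrier: int
    n_noncarrier: int
    t: float
    p: float

    @property
    def stars(self) -> str:
        for cut, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p < cut:
                return mark
        return ""


def allele_association(values: pd.Series, carrier: pd.Series) -> AssociationResult:
    """Compare phenotype of allele carriers vs non-carriers by Student's
    t-test (pooled variance, two-sided)."""
    common = values.index.intersection(carrier.index)
    v = values.loc[common].astype(float)
    c = carrier.loc[common].astype(bool)
    a, b = v[c].to_numpy(), v[~c].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise DataError("allele_association: each group needs >= 2 hybrids")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return AssociationResult(mean_carrier=float(a.mean()), mean_noncarrier=float(b.mean()),
                             n_carrier=len(a), n_noncarrier=len(b),
                             t=float(t), p=float(p))


def genotype_frequencies(geno: pd.DataFrame, marker: str) -> pd.DataFrame:
    """Genotype-class counts and percentages over non-missing calls."""
    if marker not in geno.columns:
        raise DataError(f"marker {marker!r} not in genotype table")
    calls = geno[marker].dropna()
    if calls.empty:
        raise DataError(f"marker {marker!r}: all calls missing")
    counts = calls.value_counts().sort_index()
    return pd.DataFrame({
        "genotype": counts.index,
        "count": counts.to_numpy(),
        "frequency_pct": counts.to_numpy() / counts.sum() * 100.0,
    }).reset_index(drop=True)
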