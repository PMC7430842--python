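"""Marker genotype-effect model, GPV prediction, CV, selection, association."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from gapstock import (
    DataError,
    GapModel,
    GapResults,
    allele_association,
    genotype_frequencies,
    kfold_cv,
    prediction_accuracy,
    simulative_selection,
)


def _model(values: dict, geno: dict, **kwargs) -> GapModel:
    endog = pd.Series(values, name="OPV")
    geno_df = pd.DataFrame(geno, index=list(values))
    return GapModel(endog, geno_df, **kwargs)


class TestFit:
    def test_forced_two_class_arithmetic(self):
        res = _model({"H1": 0.2, "H2": 0.4, "H3": 0.6, "H4": 0.8},
                     {"m1": ["A:A", "A:A", "A:T", "A:T"]}).fit()
        assert res.mean_phenotype == pytest.approx(0.5)
        assert res.genotype_effects["m1"]["A:A"] == pytest.approx(-0.2)
        assert res.genotype_effects["m1"]["A:T"] == pytest.approx(0.2)
        assert res.marker_effects["m1"] == pytest.approx(0.2)

    def test_monomorphic_marker_has_zero_effect(self):
        res = _model({"H1": 0.1, "H2": 0.9}, {"m1": ["A:A", "A:A"]}).fit()
        assert res.marker_effects["m1"] == 0.0

    def test_small_class_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="effect set to 0"):
            res = _model({"H1": 0.2, "H2": 0.4, "H3": 0.9},
                         {"m1": ["A:A", "A:A", "A:T"]}, min_class_size=2).fit()
        assert res.genotype_effects["m1"]["A:T"] == 0.0

    def test_effect_sum_weighted_by_class_size_is_zero(self):
        rng = np.random.default_rng(3)
        n = 200
        geno = {"m1": rng.choice(["A:A", "A:T", "T:T"], n)}
        values = dict(zip([f"H{i}" for i in range(n)], rng.uniform(0, 1, n)))
        res = _model(values, {k: list(v) for k, v in geno.items()}).fit()
        counts = pd.Series(geno["m1"]).value_counts()
        total = sum(counts[g] * e for g, e in res.genotype_effects["m1"].items())
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_range_effect_summary(self):
        res = _model({"H1": 0.2, "H2": 0.4, "H3": 0.6, "H4": 0.8},
                     {"m1": ["A:A", "A:A", "A:T", "A:T"]}, effect_summary="range").fit()
        assert res.marker_effects["m1"] == pytest.approx(0.4)


class TestPredict:
    def test_single_marker_gpvs(self):
        res = _model({"H1": 0.3, "H2": 0.3, "H3": 0.7, "H4": 0.7},
                     {"m1": ["a", "a", "b", "b"]}).fit()
        gpv = res.predict()
        assert gpv.loc["H1"] == pytest.approx(0.3)
        assert gpv.loc["H3"] == pytest.approx(0.7)

    def test_two_marker_additive_enumeration(self):
        """Effects (−0.1, +0.1) and (−0.05, +0.05) around ybar 0.5 give the
        four combination GPVs {0.35, 0.45, 0.55, 0.65}."""
        combos = list(itertools.product(["a", "b"], ["c", "d"]))
        effects = {"m1": {"a": -0.1, "b": 0.1}, "m2": {"c": -0.05, "d": 0.05}}
        res = GapResults(mean_phenotype=0.5, genotype_effects=effects)
        geno = pd.DataFrame(combos, columns=["m1", "m2"],
                            index=[f"H{i}" for i in range(4)])
        assert sorted(res.predict(geno).round(10)) == [0.35, 0.45, 0.55, 0.65]

    def test_missing_and_unseen_classes_contribute_zero(self):
        res = GapResults(0.5, {"m1": {"a": -0.1, "b": 0.1}})
        geno = pd.DataFrame({"m1": ["a", "z", None]}, index=["H1", "H2", "H3"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gpv = res.predict(geno)
        assert gpv.loc["H1"] == pytest.approx(0.4)
        assert gpv.loc["H2"] == pytest.approx(0.5)   # unseen class
        assert gpv.loc["H3"] == pytest.approx(0.5)   # missing call

    def test_all_missing_hybrid_flagged(self):
        res = GapResults(0.5, {"m1": {"a": -0.1}})
        geno = pd.DataFrame({"m1": [None]}, index=["H1"])
        with pytest.warns(UserWarning, match="no usable genotype call"):
            gpv = res.predict(geno)
        assert gpv.loc["H1"] == pytest.approx(0.5)

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        res = _model({"H1": 0.2, "H2": 0.4, "H3": 0.6, "H4": 0.8},
                     {"m1": ["a", "a", "b", "b"]}).fit()
        res.save(tmp_path / "model.json")
        loaded = GapResults.from_json(tmp_path / "model.json")
        geno = pd.DataFrame({"m1": ["a", "b"]}, index=["X1", "X2"])
        pd.testing.assert_series_equal(res.predict(geno), loaded.predict(geno))


class TestAccuracy:
    def test_perfect_prediction(self):
        v = pd.Series([0.1, 0.4, 0.9], index=["a", "b", "c"])
        acc = prediction_accuracy(v, v)
        assert acc.r == pytest.approx(1.0) and acc.slope == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        v = pd.Series([0.1, 0.4, 0.9], index=["a", "b", "c"])
        assert prediction_accuracy(v, 1 - v).r == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        v = pd.Series([0.5, 0.5, 0.5], index=["a", "b", "c"])
        with pytest.raises(DataError):
            prediction_accuracy(v, pd.Series([0.1, 0.2, 0.3], index=v.index))

    def test_shift_invariance_of_accuracy(self):
        """Adding a constant to all phenotypes shifts ybar and every GPV by
        that constant and leaves the accuracy unchanged."""
        rng = np.random.default_rng(1)
        n = 100
        geno = pd.DataFrame({"m1": rng.choice(["a", "b"], n),
                             "m2": rng.choice(["c", "d"], n)},
                            index=[f"H{i}" for i in range(n)])
        y = pd.Series(rng.uniform(0.2, 0.6, n), index=geno.index)
        r1 = GapModel(y, geno).fit()
        r2 = GapModel(y + 0.17, geno).fit()
        assert r2.mean_phenotype == pytest.approx(r1.mean_phenotype + 0.17)
        assert np.allclose(r2.predict(), r1.predict() + 0.17)
        assert r2.accuracy().r == pytest.approx(r1.accuracy().r)

    def test_fixed_point_on_balanced_design(self):
        """On a balanced full-factorial design, refitting on the predicted
        GPVs reproduces the genotype effects exactly."""
        combos = list(itertools.product(["a", "b"], ["c", "d"]))
        rows, y = [], []
        vals = {("a", "c"): 0.2, ("a", "d"): 0.35, ("b", "c"): 0.6, ("b", "d"): 0.9}
        for rep in range(5):
            for combo in combos:
                rows.append(combo)
                y.append(vals[combo])
        geno = pd.DataFrame(rows, columns=["m1", "m2"],
                            index=[f"H{i}" for i in range(len(rows))])
        first = GapModel(pd.Series(y, index=geno.index), geno).fit()
        second = GapModel(first.predict(), geno).fit()
        assert second.mean_phenotype == pytest.approx(first.mean_phenotype, abs=1e-9)
        for m in first.genotype_effects:
            for g, e in first.genotype_effects[m].items():
                assert second.genotype_effects[m][g] == pytest.approx(e, abs=1e-9)


def _pheno_from_series(values: pd.Series, trait="SID") -> pd.DataFrame:
    return pd.DataFrame({"hybrid_id": values.index, "year": 2015,
                         "trait": trait, "value": values.to_numpy()})


class TestCrossValidation:
    def test_noise_free_marker_determined_trait_has_perfect_folds(self):
        """A trait fully determined by three fully-linked markers is
        predicted perfectly within every fold."""
        rng = np.random.default_rng(7)
        n = 60
        calls = rng.choice(["a", "b", "c"], n)
        level = {"a": 0.2, "b": 0.5, "c": 0.8}
        geno = pd.DataFrame({"m1": calls, "m2": calls, "m3": calls},
                            index=[f"H{i}" for i in range(n)])
        y = pd.Series([level[c] for c in calls], index=geno.index)
        cv = kfold_cv(_pheno_from_series(y), geno, "SID", k=5, seed=0)
        assert cv.mean_fold_accuracy == pytest.approx(1.0, abs=1e-9)
        assert cv.pooled_accuracy > 0.99

    def test_folds_partition_all_hybrids(self):
        rng = np.random.default_rng(8)
        n = 53
        geno = pd.DataFrame({"m1": rng.choice(["a", "b"], n)},
                            index=[f"H{i}" for i in range(n)])
        y = pd.Series(rng.uniform(0, 1, n), index=geno.index)
        cv = kfold_cv(_pheno_from_series(y), geno, "SID", k=5, seed=1)
        assert cv.gpv.notna().all() and len(cv.gpv) == n

    def test_seed_changes_fold_assignment_deterministically(self):
        rng = np.random.default_rng(9)
        n = 40
        geno = pd.DataFrame({"m1": rng.choice(["a", "b"], n)},
                            index=[f"H{i}" for i in range(n)])
        y = pd.Series(rng.uniform(0, 1, n), index=geno.index)
        pheno = _pheno_from_series(y)
        a = kfold_cv(pheno, geno, "SID", k=4, seed=3)
        b = kfold_cv(pheno, geno, "SID", k=4, seed=3)
        assert a.pooled_accuracy == b.pooled_accuracy

    def test_training_accuracy_beats_heldout_on_average(self):
        """Apparent (training) accuracy exceeds pooled CV accuracy in
        expectation over simulated replicates."""
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 120
            geno = pd.DataFrame(
                {f"m{j}": rng.choice(["a", "b"], n) for j in range(5)},
                index=[f"H{i}" for i in range(n)])
            signal = sum((geno[f"m{j}"] == "a") * 0.05 for j in range(5))
            y = pd.Series(0.3 + signal + rng.normal(0, 0.1, n), index=geno.index)
            pheno = _pheno_from_series(y.clip(0, 1))
            res = GapModel(y, geno).fit()
            cv = kfold_cv(pheno, geno, "SID", k=5, seed=seed)
            diffs.append(res.accuracy().r - cv.pooled_accuracy)
        assert np.mean(diffs) > 0


class TestSimulativeSelection:
    def test_forced_example(self):
        gpv = pd.Series([0.1, 0.15, 0.3, 0.5], index=list("abcd"))
        opv = pd.Series([0.05, 0.4, 0.2, 0.1], index=list("abcd"))
        report = simulative_selection(gpv, opv, [0.2])
        row = report.iloc[0]
        assert row["n_selected"] == 2
        assert row["selection_rate_pct"] == pytest.approx(50.0)
        assert row["n_consistent"] == 1
        assert row["efficiency_pct"] == pytest.approx(50.0)

    def test_empty_selection_zeroed(self):
        gpv = pd.Series([0.5, 0.6], index=["a", "b"])
        opv = pd.Series([0.5, 0.6], index=["a", "b"])
        row = simulative_selection(gpv, opv, [0.1]).iloc[0]
        assert row["n_selected"] == 0
        assert row["selection_rate_pct"] == 0.0 and row["efficiency_pct"] == 0.0

    def test_selection_counts_monotone_in_criterion(self):
        rng = np.random.default_rng(2)
        idx = [f"H{i}" for i in range(200)]
        gpv = pd.Series(rng.uniform(0, 1, 200), index=idx)
        opv = pd.Series(rng.uniform(0, 1, 200), index=idx)
        report = simulative_selection(gpv, opv, np.linspace(0.1, 0.9, 9))
        assert report["n_selected"].is_monotonic_increasing

    def test_no_hybrids_rejected(self):
        with pytest.raises(DataError):
            simulative_selection(pd.Series(dtype=float), pd.Series(dtype=float), [0.2])


class TestAssociation:
    def test_identical_groups_give_zero_t_unit_p(self):
        v = pd.Series([0.1, 0.2, 0.3, 0.1, 0.2, 0.3], index=list("abcdef"))
        carrier = pd.Series([True] * 3 + [False] * 3, index=v.index)
        res = allele_association(v, carrier)
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)
        assert res.stars == ""

    def test_matches_textbook_pooled_t(self):
        a, b = [0.1, 0.2, 0.3], [0.4, 0.5, 0.6]
        v = pd.Series(a + b, index=list("abcdef"))
        carrier = pd.Series([True] * 3 + [False] * 3, index=v.index)
        res = allele_association(v, carrier)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_manual = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.t == pytest.approx(t_manual, abs=1e-9)

    def test_small_group_rejected(self):
        v = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        carrier = pd.Series([True, False, False], index=v.index)
        with pytest.raises(DataError):
            allele_association(v, carrier)

    def test_star_annotation_thresholds(self):
        rng = np.random.default_rng(0)
        v = pd.Series(np.r_[rng.normal(0.2, 0.01, 30), rng.normal(0.8, 0.01, 30)],
                      index=[f"H{i}" for i in range(60)])
        carrier = pd.Series([True] * 30 + [False] * 30, index=v.index)
        assert allele_association(v, carrier).stars == "***"


class TestGenotypeFrequencies:
    def test_counts_and_percentages(self):
        calls = ["G:G"] * 1 + ["G:T"] * 27 + ["T:T"] * 72
        geno = pd.DataFrame({"snp182": calls}, index=[f"A{i}" for i in range(100)])
        freq = genotype_frequencies(geno, "snp182").set_index("genotype")
        assert freq.loc["G:G", "frequency_pct"] == pytest.approx(1.0)
        assert freq.loc["G:T", "frequency_pct"] == pytest.approx(27.0)
        assert freq.loc["T:T", "frequency_pct"] == pytest.approx(72.0)
        assert freq["frequency_pct"].sum() == pytest.approx(100.0)

    def test_missing_calls_excluded_from_denominator(self):
        geno = pd.DataFrame({"m": ["a", "a", None, "b"]}, index=list("wxyz"))
        freq = genotype_frequencies(geno, "m").set_index("genotype")
        assert freq.loc["a", "frequency_pct"] == pytest.approx(200 / 3)

    def test_single_class_is_hundred_percent(self):
        geno = pd.DataFrame({"m": ["a", "a"]}, index=["w", "x"])
        assert genotype_frequencies(geno, "m")["frequency_pct"].iloc[0] == 100.0

    def test_all_missing_rejected(self):
        geno = pd.DataFrame({"m": [None, None]}, index=["w", "x"])
        with pytest.raises(DataError):
            genotype_frequencies(geno, "m")
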