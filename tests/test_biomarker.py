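"""mBV scoring, cutoff optimisation, ROC/AUC and the bootstrap model
comparison, checked against brute-force and concordance oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcmeth import biomarker, synthetic
from crcmeth.biomarker import ConfusionCounts, SiteSet
from crcmeth.errors import DataError, DegenerateInputError


def concordance_auc_oracle(scores, labels, polarity="hyper"):
    """AUC as explicit pairwise concordance with half credit for ties."""
    s = np.asarray(scores, dtype=float)
    if polarity == "hypo":
        s = -s
    pos = s[np.asarray(labels) == "disease"]
    neg = s[np.asarray(labels) == "normal"]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_min_errors(scores, labels, polarity="hyper"):
    """Minimal misclassification count over a dense threshold sweep."""
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == "disease"
    grid = np.concatenate([[s.min() - 1.0], np.unique(s), np.unique(s) - 1e-9,
                           np.unique(s) + 1e-9, [s.max() + 1.0]])
    best = len(s)
    for c in grid:
        pred = s >= c if polarity == "hyper" else s <= c
        best = min(best, int((pred != pos).sum()))
    return best


def _series(values, prefix="S"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestMbv:
    def test_unweighted_mean_and_missing_skip(self):
        idx = pd.Index(["cg0", "cg1", "cg2"], name="probe_id")
        betas = pd.DataFrame({"S1": [0.2, 0.4, 0.6], "S2": [0.2, np.nan, 0.6]}, index=idx)
        scores = biomarker.mbv(betas, SiteSet("set", ("cg0", "cg1", "cg2")))
        assert scores["S1"] == pytest.approx(0.4)
        assert scores["S2"] == pytest.approx(0.4)

    def test_singleton_set_equals_probe_beta(self):
        idx = pd.Index(["cg0", "cg1"], name="probe_id")
        betas = pd.DataFrame({"S1": [0.37, 0.9]}, index=idx)
        scores = biomarker.mbv(betas, SiteSet("one", ("cg0",)))
        assert scores["S1"] == 0.37

    def test_all_missing_sample_dropped_with_warning(self):
        idx = pd.Index(["cg0", "cg1"], name="probe_id")
        betas = pd.DataFrame({"S1": [0.2, 0.4], "S2": [np.nan, np.nan]}, index=idx)
        with pytest.warns(UserWarning, match="dropped"):
            scores = biomarker.mbv(betas, SiteSet("set", ("cg0", "cg1")))
        assert list(scores.index) == ["S1"]

    def test_absent_member_rejected(self):
        betas = pd.DataFrame({"S1": [0.2]}, index=pd.Index(["cg0"], name="probe_id"))
        with pytest.raises(DataError, match="absent"):
            biomarker.mbv(betas, SiteSet("set", ("cg0", "cgX")))

    def test_group_difference_recovers_injected_delta(self, small_cohort):
        truth = small_cohort["truth"]
        probes = tuple(
            truth.loc[
                (truth["stage"] == "cancer")
                & (truth["true_delta"] > 0)
                & ~truth["is_marker_promoter"],
                "probe_id",
            ].unique()
        )
        scores = biomarker.mbv(small_cohort["betas"], SiteSet("hyper", probes))
        groups = small_cohort["groups"].reindex(scores.index)
        delta = scores[groups == "cancer"].mean() - scores[groups == "normal"].mean()
        injected = truth.loc[
            (truth["stage"] == "cancer") & (truth["true_delta"] > 0), "true_delta"
        ].iloc[0]
        assert delta == pytest.approx(injected, abs=0.05)


class TestPromoterIslandSet:
    def test_island_restriction(self, tiny_annot):
        site_set = biomarker.promoter_island_set(tiny_annot, "GENE_A")
        # TSS200 island + 1stExon island; TSS1500 shore and Body excluded
        assert set(site_set.probe_ids) == {"cg00", "cg02"}

    def test_without_island_requirement(self, tiny_annot):
        site_set = biomarker.promoter_island_set(tiny_annot, "GENE_A", require_island=False)
        assert set(site_set.probe_ids) == {"cg00", "cg01", "cg02"}

    def test_unknown_gene_rejected(self, tiny_annot):
        with pytest.raises(DataError, match="not present"):
            biomarker.promoter_island_set(tiny_annot, "NOPE")

    def test_empty_result_names_constraint(self, tiny_annot):
        annot = tiny_annot.copy()
        annot.loc[annot["gene"] == "GENE_A", "island_relation"] = "shore"
        with pytest.raises(DataError, match="island"):
            biomarker.promoter_island_set(annot, "GENE_A")


class TestOptimalCutoff:
    def test_worked_example_tie_broken_low(self):
        scores = _series([0.8, 0.6, 0.3, 0.2, 0.4])
        labels = _series(["disease", "disease", "disease", "normal", "normal"])
        result = biomarker.optimal_cutoff(scores, labels, "hyper")
        assert result.n_errors == 1
        assert result.cutoff == pytest.approx(0.25)
        assert result.error_rate == 20.00

    def test_perfect_separation(self):
        scores = _series([0.9, 0.8, 0.1, 0.2])
        labels = _series(["disease", "disease", "normal", "normal"])
        result = biomarker.optimal_cutoff(scores, labels, "hyper")
        assert result.n_errors == 0
        assert result.error_rate == 0.0

    @pytest.mark.parametrize("polarity", ["hyper", "hypo"])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_scan(self, seed, polarity):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        scores = _series(np.round(rng.uniform(0, 1, n), 2))  # rounded -> ties occur
        labels = _series(rng.choice(["disease", "normal"], n))
        if len(set(labels)) < 2:
            labels.iloc[0] = "disease"
            labels.iloc[1] = "normal"
        result = biomarker.optimal_cutoff(scores, labels, polarity)
        assert result.n_errors == brute_force_min_errors(scores, labels, polarity)

    def test_polarity_duality(self):
        rng = np.random.default_rng(3)
        scores = _series(rng.uniform(0, 1, 30))
        labels = _series(rng.choice(["disease", "normal"], 30))
        labels.iloc[:2] = ["disease", "normal"]
        hyper = biomarker.optimal_cutoff(scores, labels, "hyper")
        hypo = biomarker.optimal_cutoff(1.0 - scores, labels, "hypo")
        assert hyper.n_errors == hypo.n_errors

    def test_single_unique_score_flagged_degenerate(self):
        scores = _series([0.5, 0.5, 0.5])
        labels = _series(["disease", "normal", "disease"])
        assert biomarker.optimal_cutoff(scores, labels).degenerate


class TestRoc:
    def test_perfect_separation(self):
        scores = _series([0.9, 0.8, 0.1, 0.2])
        labels = _series(["disease", "disease", "normal", "normal"])
        assert biomarker.roc(scores, labels).auc == 1.0

    def test_pairwise_concordance_worked_example(self):
        scores = _series([0.9, 0.4, 0.7, 0.5, 0.3])
        labels = _series(["disease", "disease", "disease", "normal", "normal"])
        assert biomarker.roc(scores, labels).auc == pytest.approx(5 / 6)

    def test_identical_score_multisets_give_half(self):
        scores = _series([0.3, 0.5, 0.3, 0.5])
        labels = _series(["disease", "disease", "normal", "normal"])
        assert biomarker.roc(scores, labels).auc == pytest.approx(0.5)

    @pytest.mark.parametrize("polarity", ["hyper", "hypo"])
    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_concordance_oracle(self, seed, polarity):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        scores = _series(np.round(rng.uniform(0, 1, n), 1))
        labels = _series(rng.choice(["disease", "normal"], n))
        labels.iloc[:2] = ["disease", "normal"]
        curve = biomarker.roc(scores, labels, polarity)
        assert curve.auc == pytest.approx(
            concordance_auc_oracle(scores, labels, polarity)
        )
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores = _series(rng.uniform(0, 1, 60))
        labels = _series(rng.choice(["disease", "normal"], 60))
        labels.iloc[:2] = ["disease", "normal"]
        expected = roc_auc_score((labels == "disease").astype(int), scores)
        assert biomarker.roc(scores, labels).auc == pytest.approx(expected)

    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-5.0, 5.0),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_strictly_monotone_transform(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        scores = _series(rng.uniform(0, 1, 20))
        labels = _series(rng.choice(["disease", "normal"], 20))
        labels.iloc[:2] = ["disease", "normal"]
        base = biomarker.roc(scores, labels).auc
        transformed = biomarker.roc(np.exp(scale * scores) + shift, labels).auc
        assert transformed == pytest.approx(base)

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            biomarker.roc(_series([0.1, 0.2]), _series(["disease", "disease"]))


class TestSensSpec:
    @pytest.mark.parametrize(
        "tp,fn,fp,tn,sens,spec",
        [
            (532, 23, 39, 239, 0.959, 0.860),
            (406, 149, 83, 195, 0.732, 0.701),
            (10, 0, 0, 10, 1.000, 1.000),
        ],
    )
    def test_confusion_to_metrics(self, tp, fn, fp, tn, sens, spec):
        metrics = biomarker.sens_spec(ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn))
        assert metrics.sensitivity == sens
        assert metrics.specificity == spec

    def test_error_rate_two_decimals(self):
        assert biomarker.error_rate_percent(39, 833) == 4.68

    def test_cutoff_classifier_metrics(self):
        scores = _series([0.9, 0.8, 0.3, 0.1, 0.2])
        labels = _series(["disease", "disease", "disease", "normal", "normal"])
        metrics = biomarker.sens_spec_at(scores, labels, 0.25, "hyper")
        assert metrics.confusion.to_dict() == {"TP": 3, "FN": 0, "FP": 0, "TN": 2}
        assert metrics.sensitivity == 1.0

    def test_empty_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            ConfusionCounts(tp=0, fn=0, fp=1, tn=1).sensitivity


class TestBootstrapCompare:
    def _cohort_scores(self):
        man = synthetic.generate_manifest(800, 30, seed=51)
        betas = synthetic.generate_baseline_betas(man, 120, seed=52)
        betas.columns = [f"N{i}" for i in range(60)] + [f"D{i}" for i in range(60)]
        groups = pd.Series(["normal"] * 60 + ["cancer"] * 60, index=betas.columns)
        spec = synthetic.EffectSpec(
            n_hyper_sites=150, n_hypo_sites=150,
            hyper_delta={"cancer": 0.3}, hypo_delta={"cancer": -0.1}, seed=53,
        )
        shifted, truth = synthetic.inject_effects(betas, man, groups, spec)
        hyper = tuple(truth.loc[truth["true_delta"] > 0, "probe_id"].unique())
        hypo = tuple(truth.loc[truth["true_delta"] < 0, "probe_id"].unique())
        sa = biomarker.mbv(shifted, SiteSet("hyper", hyper, "hyper"))
        sb = biomarker.mbv(shifted, SiteSet("hypo", hypo, "hypo"))
        labels = biomarker.as_binary_labels(groups)
        return sa, sb, labels

    def test_identical_models_give_null_p(self):
        sa, _, labels = self._cohort_scores()
        result = biomarker.bootstrap_auc_compare(sa, sa, labels, n_replicates=500, seed=1)
        assert (result.differences == 0).all()
        assert 0.9 < result.p_value <= 1.0

    def test_stronger_hyper_model_wins(self):
        sa, sb, labels = self._cohort_scores()
        result = biomarker.bootstrap_auc_compare(
            sa, sb, labels, polarity_a="hyper", polarity_b="hypo",
            n_replicates=1000, seed=2,
        )
        assert result.observed_auc_a > result.observed_auc_b
        assert result.p_value < 0.01

    def test_deterministic_for_fixed_seed(self):
        sa, sb, labels = self._cohort_scores()
        kwargs = dict(polarity_a="hyper", polarity_b="hypo", n_replicates=300, seed=7)
        r1 = biomarker.bootstrap_auc_compare(sa, sb, labels, **kwargs)
        r2 = biomarker.bootstrap_auc_compare(sa, sb, labels, **kwargs)
        assert r1.p_value == r2.p_value
        assert (r1.differences == r2.differences).all()

    def test_unpaired_samples_rejected(self):
        sa, sb, labels = self._cohort_scores()
        with pytest.raises(DataError, match="paired"):
            biomarker.bootstrap_auc_compare(sa, sb.iloc[:-1], labels)

    def test_null_p_values_not_anticonservative(self):
        # exchangeable null: two noise score vectors on the same samples
        rng = np.random.default_rng(17)
        labels = _series(["disease"] * 15 + ["normal"] * 15)
        small_p = 0
        n_runs = 20
        for s in range(n_runs):
            sa = _series(rng.uniform(size=30))
            sb = _series(rng.uniform(size=30))
            res = biomarker.bootstrap_auc_compare(
                sa, sb, labels, n_replicates=200, seed=s
            )
            small_p += res.p_value < 0.2
        assert small_p / n_runs <= 0.4
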