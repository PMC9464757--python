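"""Bootstrap, multimodality thresholds and Single/Dual/Triple calling."""

import itertools

import numpy as np
import pandas as pd
import pytest

import dualsubtype as ds
from dualsubtype.dual import (
    ClassThreshold,
    _quantile_threshold,
    bootstrap_scores,
    canonical_label,
    fit_difference_thresholds,
)
from dualsubtype.errors import BootstrapFailureError, ClassificationError
from dualsubtype.scoring import pearson_score


def two_gene_model():
    """Two 2-gene classes; every valid resample has a deterministic score."""
    return ds.SignatureModel(
        classes=("A", "B"),
        genes={"A": ("a1", "a2"), "B": ("b1", "b2")},
        centroids={"A": np.array([1.0, 2.0]), "B": np.array([2.0, 1.0])},
    )


def enumerate_flip_fraction(profile, model, top, other):
    """Exhaustive oracle over all joint gene resamples with the same validity
    rule as the bootstrap (a replicate is valid iff every class's resampled
    restriction has nonzero variance in both profile and centroid)."""
    per_class = {}
    for cls in model.classes:
        genes = list(model.genes[cls])
        k = len(genes)
        x = np.array([profile[g] for g in genes])
        c = model.centroids[cls]
        outcomes = []
        for idx in itertools.product(range(k), repeat=k):
            xs, cs = x[list(idx)], c[list(idx)]
            if np.ptp(xs) == 0 or np.ptp(cs) == 0:
                outcomes.append(None)
            else:
                outcomes.append(pearson_score(xs, cs))
        per_class[cls] = outcomes
    flips = total = 0
    for combo in itertools.product(*[per_class[c] for c in model.classes]):
        if any(v is None for v in combo):
            continue
        total += 1
        scores = dict(zip(model.classes, combo))
        if scores[other] >= scores[top]:
            flips += 1
    return flips / total


class TestBootstrap:
    def test_deterministic_under_seed(self, toy_model, toy_profile):
        a = bootstrap_scores(toy_profile, toy_model, B=50, seed=3)
        b = bootstrap_scores(toy_profile, toy_model, B=50, seed=3)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_centroid_replica_scores_exactly_one(self, toy_model):
        profile = {g: v for cls in toy_model.classes
                   for g, v in zip(toy_model.genes[cls], toy_model.centroids[cls])}
        boot = bootstrap_scores(profile, toy_model, B=200, seed=0)
        # any gene resample of two identical vectors correlates at exactly 1
        assert np.allclose(boot.scores[boot.valid], 1.0)

    def test_flip_fractions_match_exhaustive_enumeration(self):
        model = two_gene_model()
        # aligned with A's centroid, anti-aligned with B's: every valid
        # resample gives score +1 for A and -1 for B, so any finite B matches
        # the enumeration exactly
        profile = {"a1": 0.0, "a2": 1.0, "b1": 1.0, "b2": 0.0}
        for B in (1, 3, 5):
            boot = bootstrap_scores(profile, model, B=B, seed=11,
                                    max_invalid_fraction=1.0)
            if not boot.valid.any():
                continue
            assert boot.flip_fraction("A", "B") == enumerate_flip_fraction(
                profile, model, "A", "B")
            assert boot.flip_fraction("B", "A") == enumerate_flip_fraction(
                profile, model, "B", "A")

    def test_flip_fraction_tie_rule(self, toy_model):
        profile = {g: v for cls in toy_model.classes
                   for g, v in zip(toy_model.genes[cls], toy_model.centroids[cls])}
        boot = bootstrap_scores(profile, toy_model, B=100, seed=0)
        # all scores are 1.0: ties count in both directions
        f_ab = boot.flip_fraction("Luminal", "Basal")
        f_ba = boot.flip_fraction("Basal", "Luminal")
        assert f_ab + f_ba >= 1.0
        assert 0.0 <= f_ab <= 1.0

    def test_excessive_invalid_replicates_raise(self):
        model = two_gene_model()
        profile = {"a1": 0.0, "a2": 1.0, "b1": 1.0, "b2": 0.0}
        # with 2-gene signatures ~3/4 of joint replicates are degenerate
        with pytest.raises(BootstrapFailureError):
            bootstrap_scores(profile, model, B=400, seed=1)

    def test_planted_dual_flips_more_than_planted_single(self, sim_config, cohort,
                                                         trained_model, scores_table):
        expr, truth = cohort
        duals = truth.index[truth["true_label_kind"] == "Dual"][:25]
        singles = truth.index[truth["true_label_kind"] == "Single"][:25]
        dual_flips, single_flips = [], []
        for sids, sink in ((duals, dual_flips), (singles, single_flips)):
            for i, sid in enumerate(sids):
                boot = bootstrap_scores(expr[sid], trained_model, B=400, seed=100 + i)
                row = scores_table.loc[sid]
                sink.append(boot.flip_fraction(row["winning_class"],
                                               row["runner_up_class"]))
        assert np.mean([f > 0.05 for f in dual_flips]) > 0.5
        assert np.mean([f < 0.05 for f in single_flips]) > 0.5


class TestThresholds:
    def test_bimodal_mixture_valley_matches_numeric_oracle(self):
        rng = np.random.default_rng(42)
        d = np.concatenate([rng.normal(0.05, 0.01, 1000),
                            rng.normal(0.40, 0.05, 1000)])
        tab = pd.DataFrame({"winning_class": ["Luminal"] * 2000, "d_top": d})
        t = fit_difference_thresholds(tab)["Luminal"]
        assert t.decision == "bimodal-valley"
        # numeric oracle: minimize the true generating density
        from scipy.stats import norm

        grid = np.arange(0.05, 0.40, 1e-5)
        dens = 0.5 * norm.pdf(grid, 0.05, 0.01) + 0.5 * norm.pdf(grid, 0.40, 0.05)
        true_valley = grid[np.argmin(dens)]
        assert 0.08 <= t.value <= 0.25
        assert abs(t.value - true_valley) < 0.05

    def test_unimodal_falls_back_to_quantile(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.3, 0.05, 2000)
        t = fit_difference_thresholds(
            pd.DataFrame({"winning_class": ["Basal"] * 2000, "d_top": d}))["Basal"]
        assert t.decision == "quantile-fallback"
        assert t.value == pytest.approx(np.percentile(d, 5, method="lower"), abs=1e-12)
        assert t.value == pytest.approx(0.3 - 1.645 * 0.05, abs=0.01)

    def test_degenerate_distribution_returns_constant(self):
        tab = pd.DataFrame({"winning_class": ["HER2"] * 120, "d_top": [0.25] * 120})
        t = fit_difference_thresholds(tab)["HER2"]
        assert t.decision == "quantile-fallback"
        assert t.value == 0.25

    def test_small_class_pools_and_empty_class_is_undefined(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({
            "winning_class": ["Luminal"] * 200 + ["Basal"] * 10,
            "d_top": np.r_[rng.normal(0.5, 0.05, 200), rng.normal(0.5, 0.05, 10)],
        })
        ts = fit_difference_thresholds(tab, classes=("Luminal", "Basal", "HER2"))
        assert ts["Basal"].diagnostics.get("pooled") is True
        assert ts["HER2"].decision == "undefined" and ts["HER2"].value is None

    def test_quantile_threshold_is_an_observed_value(self):
        d = np.array([0.3, 0.1, 0.5, 0.2, 0.4])
        assert _quantile_threshold(d, 5.0) in d


class TestClassifySingleDual:
    def _thresholds(self, value=0.1):
        return ds.ThresholdSet({c: ClassThreshold(value, "bimodal-valley", {})
                                for c in ds.CLASS_ORDER})

    def _boot(self, flip_top=0.0, flip_second=0.0):
        """Fake bootstrap: fixed flip for the first queried pair (top vs
        second) and for the second queried pair (second vs third)."""

        class FakeBoot:
            calls = 0

            def flip_fraction(self, hi, lo):
                FakeBoot.calls += 1
                return flip_top if FakeBoot.calls == 1 else flip_second

        return FakeBoot()

    def test_equal_top_scores_never_single(self):
        scores = {"Luminal": 0.6, "Basal": 0.6, "HER2": -0.5}
        boot = self._boot(flip_top=0.5)
        call = ds.classify_single_dual(scores, boot, self._thresholds(0.0), alpha=0.05)
        assert call.kind != "Single"

    def test_large_gap_zero_flip_is_single(self):
        scores = {"Luminal": 0.8, "Basal": 0.3, "HER2": -0.5}
        call = ds.classify_single_dual(scores, self._boot(), self._thresholds(0.1))
        assert call.kind == "Single"
        assert call.components == ("Luminal",)
        assert call.label == "Luminal-single-type"

    def test_dual_components_ordered_by_score(self):
        scores = {"Luminal": 0.55, "Basal": 0.60, "HER2": -0.5}
        call = ds.classify_single_dual(scores, self._boot(flip_top=0.4),
                                       self._thresholds(0.1))
        assert call.kind == "Dual"
        assert call.components == ("Basal", "Luminal")
        assert call.label == "Basal-Luminal-type"
        assert canonical_label(call.components) == "Luminal-Basal-type"

    def test_triple_requires_both_pairs_indiscernible(self):
        scores = {"Luminal": 0.60, "Basal": 0.58, "HER2": 0.57}
        call = ds.classify_single_dual(scores, self._boot(flip_top=0.4, flip_second=0.4),
                                       self._thresholds(0.05))
        assert call.kind == "Triple"
        assert call.components == ("Luminal", "Basal", "HER2")
        call2 = ds.classify_single_dual(scores, self._boot(flip_top=0.4, flip_second=0.0),
                                        self._thresholds(0.0001))
        assert call2.kind == "Dual"

    def test_missing_threshold_is_classification_error(self):
        scores = {"Luminal": 0.8, "Basal": 0.3, "HER2": -0.5}
        ts = ds.ThresholdSet({"Luminal": ClassThreshold(None, "undefined", {})})
        with pytest.raises(ClassificationError):
            ds.classify_single_dual(scores, self._boot(), ts)

    def test_criteria_can_be_disabled(self):
        scores = {"Luminal": 0.8, "Basal": 0.79, "HER2": -0.5}
        # d=0.01 < t fires the threshold criterion; disabling it leaves the
        # (zero) flip criterion, giving Single
        call_on = ds.classify_single_dual(scores, self._boot(), self._thresholds(0.1))
        call_off = ds.classify_single_dual(scores, self._boot(), self._thresholds(0.1),
                                           use_threshold=False)
        assert call_on.kind == "Dual" and call_off.kind == "Single"


class TestClassifyCohortDual:
    def test_partition_and_determinism(self, cohort, trained_model):
        expr, _ = cohort
        sub = expr.iloc[:, :80]
        calls1, _ = ds.classify_cohort_dual(sub, trained_model, B=150, seed=5,
                                            min_class_n=10)
        calls2, _ = ds.classify_cohort_dual(sub, trained_model, B=150, seed=5,
                                            min_class_n=10)
        pd.testing.assert_frame_equal(calls1, calls2)
        kinds = calls1["kind"].value_counts()
        assert kinds.sum() == sub.shape[1]
        assert set(kinds.index) <= {"Single", "Dual", "Triple"}

    def test_noise_free_all_single_cohort_is_all_single(self):
        cfg = ds.SimConfig(n_samples=120, dual_fraction=0.0, triple_fraction=0.0,
                           noise_sd=0.0, seed=3)
        expr, truth = ds.generate_expression_cohort(cfg)
        labels = truth["true_components"].map(lambda c: c[0])
        model = ds.train_centroids(expr, labels, ds.signature_gene_names(cfg),
                                   class_order=ds.CLASS_ORDER)
        calls, _ = ds.classify_cohort_dual(expr, model, B=60, seed=1, min_class_n=10)
        assert (calls["kind"] == "Single").all()

    def test_raising_threshold_never_decreases_dual_calls(self, cohort, trained_model):
        expr, _ = cohort
        sub = expr.iloc[:, :60]
        scores = ds.classify_cohort(sub, trained_model)
        low = ds.ThresholdSet({c: ClassThreshold(0.05, "bimodal-valley", {})
                               for c in ds.CLASS_ORDER})
        high = ds.ThresholdSet({c: ClassThreshold(0.8, "bimodal-valley", {})
                                for c in ds.CLASS_ORDER})
        n_multi = {}
        for name, ts in (("low", low), ("high", high)):
            calls, _ = ds.classify_cohort_dual(sub, trained_model, B=100, seed=2,
                                               thresholds=ts)
            n_multi[name] = (calls["kind"] != "Single").sum()
        assert n_multi["high"] >= n_multi["low"]

    def test_empty_cohort(self, trained_model):
        expr = pd.DataFrame(index=pd.Index(trained_model.all_genes), dtype=float)
        calls, _ = ds.classify_cohort_dual(expr, trained_model, B=10, seed=0)
        assert len(calls) == 0

    def test_dual_components_are_top_two_scores(self, cohort, trained_model):
        expr, truth = cohort
        dual_ids = truth.index[truth["true_label_kind"] == "Dual"][:20]
        calls, _ = ds.classify_cohort_dual(expr[dual_ids], trained_model, B=200,
                                           seed=4, min_class_n=10**9, fallback_q=5.0)
        score_cols = {c: f"score_{c}" for c in trained_model.classes}
        for sid, row in calls.iterrows():
            comp = row["components"].split("|")
            ranked = sorted(trained_model.classes,
                            key=lambda c: -row[score_cols[c]])
            assert list(comp) == ranked[: len(comp)]
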