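"""Centroid training and correlation scoring: oracles and invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dualsubtype as ds
from dualsubtype.errors import GeneLookupError, TrainingError, UndefinedScoreError
from dualsubtype.scoring import pearson_score


def brute_force_pearson(x, c):
    """Direct covariance-formula oracle, independent of the implementation."""
    x, c = list(x), list(c)
    n = len(x)
    mx = sum(x) / n
    mc = sum(c) / n
    cov = sum((a - mx) * (b - mc) for a, b in zip(x, c))
    vx = sum((a - mx) ** 2 for a in x)
    vc = sum((b - mc) ** 2 for b in c)
    return cov / (vx**0.5 * vc**0.5)


class TestTrainCentroids:
    def test_centroid_is_per_gene_class_mean(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 2.0, 9.0], "s2": [3.0, 4.0, 9.0]},
            index=["g1", "g2", "g3"],
        )
        model = ds.train_centroids(
            expr, {"s1": "A", "s2": "A"}, {"A": ["g1", "g2"]}
        )
        np.testing.assert_allclose(model.centroids["A"], [2.0, 3.0])

    def test_identical_samples_give_that_profile(self):
        expr = pd.DataFrame({"s1": [1.0, 5.0], "s2": [1.0, 5.0]}, index=["g1", "g2"])
        model = ds.train_centroids(expr, {"s1": "A", "s2": "A"}, {"A": ["g1", "g2"]})
        np.testing.assert_allclose(model.centroids["A"], [1.0, 5.0])

    def test_missing_gene_errors_name_the_gene(self, cohort, sim_config):
        expr, truth = cohort
        labels = truth["true_components"].map(lambda c: c[0])
        gene_sets = ds.signature_gene_names(sim_config)
        gene_sets = {**gene_sets, "Luminal": list(gene_sets["Luminal"]) + ["NOPE_1"]}
        with pytest.raises(GeneLookupError, match="NOPE_1"):
            ds.train_centroids(expr, labels, gene_sets)

    def test_class_with_single_sample_is_training_error(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(TrainingError):
            ds.train_centroids(expr, {"s1": "A", "s2": "B"},
                               {"A": ["g1", "g2"], "B": ["g1", "g2"]})

    def test_trained_centroids_near_generating_means(self):
        cfg = ds.SimConfig(n_samples=300, noise_sd=0.1, dual_fraction=0.0,
                           triple_fraction=0.0, seed=11)
        expr, truth = ds.generate_expression_cohort(cfg)
        labels = truth["true_components"].map(lambda c: c[0])
        gn = ds.signature_gene_names(cfg)
        model = ds.train_centroids(expr, labels, gn, class_order=ds.CLASS_ORDER)
        from dualsubtype.simulate import activation_loadings, baseline_profile

        for cls in ds.CLASS_ORDER:
            k = cfg.signature_sizes[cls]
            target = baseline_profile(k) + cfg.activation_effect * activation_loadings(k)
            n_cls = (labels == cls).sum()
            se = cfg.noise_sd / np.sqrt(n_cls)
            dev = np.abs(model.centroids[cls] - target)
            # 90 genes are checked in total, so a stray 3-sigma gene is
            # expected; bound the worst gene at 4.5 SE and the mean at 2 SE
            assert dev.max() < 4.5 * se
            assert dev.mean() < 2 * se


class TestScoreSample:
    def test_profile_equal_to_centroid_scores_one(self, toy_model):
        profile = {g: v for cls in toy_model.classes
                   for g, v in zip(toy_model.genes[cls], toy_model.centroids[cls])}
        entry = ds.score_sample(profile, toy_model)
        for cls in toy_model.classes:
            assert entry["scores"][cls] == pytest.approx(1.0, abs=1e-12)

    @given(a=st.floats(0.25, 4.0), b=st.floats(-4.0, 4.0))
    @settings(max_examples=50, derandomize=True)
    def test_affine_invariance(self, toy_model, toy_profile, a, b):
        base = ds.score_sample(toy_profile, toy_model)
        moved = ds.score_sample(a * toy_profile + b, toy_model)
        for cls in toy_model.classes:
            assert moved["scores"][cls] == pytest.approx(base["scores"][cls], abs=1e-12)

    def test_matches_brute_force_pearson(self):
        x = [1.0, 0.0, 2.0, 1.0]
        c = [0.5, 0.2, 1.1, 0.7]
        assert pearson_score(np.array(x), np.array(c)) == pytest.approx(
            brute_force_pearson(x, c), abs=1e-12
        )

    def test_zero_variance_restriction_is_an_error(self, toy_model):
        profile = {g: 1.0 for g in toy_model.all_genes}
        with pytest.raises(UndefinedScoreError):
            ds.score_sample(profile, toy_model)

    def test_gene_permutation_invariance(self, toy_model, toy_profile):
        perm_model = ds.SignatureModel(
            classes=toy_model.classes,
            genes={c: toy_model.genes[c][::-1] for c in toy_model.classes},
            centroids={c: toy_model.centroids[c][::-1] for c in toy_model.classes},
        )
        a = ds.score_sample(toy_profile, toy_model)
        b = ds.score_sample(toy_profile, perm_model)
        for cls in toy_model.classes:
            assert a["scores"][cls] == pytest.approx(b["scores"][cls], abs=1e-12)


class TestStandardClassify:
    def test_argmax(self):
        assert ds.standard_classify({"Basal": 0.62, "Luminal": 0.10, "HER2": -0.05}) == "Basal"

    def test_tie_broken_by_fixed_class_order(self):
        assert ds.standard_classify({"Luminal": 0.4, "Basal": 0.4, "HER2": 0.1}) == "Luminal"
        assert ds.standard_classify({"Basal": 0.4, "HER2": 0.4, "Luminal": 0.1}) == "Basal"


class TestClassifyCohort:
    def test_centroid_replica_cohort_wins_with_score_one(self, toy_model):
        rng = np.random.default_rng(0)
        cols = {}
        for cls in toy_model.classes:
            vals = {g: float(rng.normal()) for g in toy_model.all_genes}
            for g, v in zip(toy_model.genes[cls], toy_model.centroids[cls]):
                vals[g] = float(v)  # exact replica on the class's own genes
            cols[cls] = pd.Series(vals)
        expr = pd.DataFrame(cols)
        tab = ds.classify_cohort(expr, toy_model)
        assert list(tab["winning_class"]) == list(toy_model.classes)
        for cls in toy_model.classes:
            assert tab.loc[cls, f"score_{cls}"] == pytest.approx(1.0, abs=1e-12)

    def test_empty_matrix_gives_empty_table(self, toy_model):
        expr = pd.DataFrame(index=pd.Index(toy_model.all_genes), columns=[], dtype=float)
        tab = ds.classify_cohort(expr, toy_model)
        assert len(tab) == 0

    def test_noise_free_cohort_reproduces_truth_exactly(self):
        cfg = ds.SimConfig(n_samples=60, dual_fraction=0.0, triple_fraction=0.0,
                           noise_sd=0.0, seed=2)
        expr, truth = ds.generate_expression_cohort(cfg)
        labels = truth["true_components"].map(lambda c: c[0])
        model = ds.train_centroids(expr, labels, ds.signature_gene_names(cfg),
                                   class_order=ds.CLASS_ORDER)
        tab = ds.classify_cohort(expr, model)
        assert (tab["winning_class"] == labels).all()
        # own-class score is exactly 1 for noise-free replicas of the centroid
        for sid in expr.columns[:5]:
            assert tab.loc[sid, f"score_{labels[sid]}"] == pytest.approx(1.0, abs=1e-9)

    def test_high_noise_cohort_accuracy(self, cohort, trained_model, scores_table):
        _, truth = cohort
        singles = truth["true_label_kind"] == "Single"
        labels = truth.loc[singles, "true_components"].map(lambda c: c[0])
        acc = (scores_table.loc[singles, "winning_class"] == labels).mean()
        assert acc >= 0.95

    def test_vectorized_agrees_with_score_sample(self, cohort, trained_model,
                                                 scores_table):
        expr, _ = cohort
        for sid in expr.columns[:10]:
            entry = ds.score_sample(expr[sid], trained_model)
            for cls in trained_model.classes:
                assert scores_table.loc[sid, f"score_{cls}"] == pytest.approx(
                    entry["scores"][cls], abs=1e-12
                )

    def test_d_top_nonnegative_and_consistent(self, scores_table, trained_model):
        assert (scores_table["d_top"] >= 0).all()
        assert (scores_table["d_low"] >= scores_table["d_top"] - 1e-12).all()
        score_cols = [f"score_{c}" for c in trained_model.classes]
        max_scores = scores_table[score_cols].max(axis=1)
        win_scores = np.array([
            scores_table.loc[i, f"score_{scores_table.loc[i, 'winning_class']}"]
            for i in scores_table.index[:20]
        ])
        np.testing.assert_allclose(win_scores, max_scores.iloc[:20], atol=1e-12)


class TestSignatureModelJson:
    def test_round_trip(self, toy_model, tmp_path):
        path = tmp_path / "model.json"
        toy_model.to_json(path)
        back = ds.SignatureModel.from_json(path)
        assert back.classes == toy_model.classes
        for cls in toy_model.classes:
            assert back.genes[cls] == toy_model.genes[cls]
            np.testing.assert_array_equal(back.centroids[cls], toy_model.centroids[cls])

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ds.SignatureModel(classes=("A",), genes={"A": ("g1", "g1")},
                              centroids={"A": np.array([1.0, 2.0])})

    def test_constant_centroid_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ds.SignatureModel(classes=("A",), genes={"A": ("g1", "g2")},
                              centroids={"A": np.array([1.0, 1.0])})
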