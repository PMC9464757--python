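"""Shared fixtures: one mid-size synthetic cohort reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import dualsubtype as ds


@pytest.fixture(scope="session")
def sim_config() -> ds.SimConfig:
    return ds.SimConfig(n_samples=400, seed=7)


@pytest.fixture(scope="session")
def cohort(sim_config):
    expr, truth = ds.generate_expression_cohort(sim_config)
    return expr, truth


@pytest.fixture(scope="session")
def trained_model(sim_config, cohort):
    expr, truth = cohort
    labels = truth.loc[truth["true_label_kind"] == "Single", "true_components"].map(
        lambda c: c[0]
    )
    return ds.train_centroids(
        expr, labels, ds.signature_gene_names(sim_config), class_order=ds.CLASS_ORDER
    )


@pytest.fixture(scope="session")
def scores_table(cohort, trained_model):
    expr, _ = cohort
    return ds.classify_cohort(expr, trained_model)


@pytest.fixture(scope="session")
def toy_model() -> ds.SignatureModel:
    """Tiny 3-class model over disjoint 3-gene signatures."""
    return ds.SignatureModel(
        classes=("Luminal", "Basal", "HER2"),
        genes={
            "Luminal": ("g1", "g2", "g3"),
            "Basal": ("g4", "g5", "g6"),
            "HER2": ("g7", "g8", "g9"),
        },
        centroids={
            "Luminal": np.array([1.0, 2.0, 3.0]),
            "Basal": np.array([3.0, 1.0, 2.0]),
            "HER2": np.array([2.0, 3.0, 1.0]),
        },
    )


@pytest.fixture(scope="session")
def toy_profile(toy_model) -> pd.Series:
    rng = np.random.default_rng(5)
    vals = {g: float(rng.normal()) for g in toy_model.all_genes}
    # make Luminal the clear winner
    for g, v in zip(toy_model.genes["Luminal"], toy_model.centroids["Luminal"]):
        vals[g] = float(v + 0.01 * rng.normal())
    return pd.Series(vals)
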