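"""Burstein-style four-class re-classification of Basal-involved tumors.

Triple-negative / Basal-like breast cancers split into four expression
subtypes: basal-like immuno-activated (BLIA), basal-like immuno-suppressed
(BLIS), luminal androgen receptor (LAR) and mesenchymal (MES).  The
classifier here is a generic shared-panel nearest-centroid classifier: four
centroids over one 80-gene panel, argmax Pearson correlation, ties broken by
fixed class order (BLIA, BLIS, LAR, MES).

The originally published centroid values are *not* hard-coded; a model is
supplied as a JSON config (same schema as :class:`~dualsubtype.scoring.SignatureModel`)
which users may populate from the published tables.  A synthetic default model
is provided for testing the classifier mechanics.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .scoring import SignatureModel, classify_cohort

BURSTEIN_CLASSES: tuple[str, ...] = ("BLIA", "BLIS", "LAR", "MES")


def validate_burstein_model(model: SignatureModel) -> SignatureModel:
    """Check the 4-class shared-panel structure of a Burstein-style model."""
    if len(model.classes) != 4:
        raise SchemaError(f"Burstein model needs exactly 4 classes, got {len(model.classes)}")
    panels = {model.genes[c] for c in model.classes}
    if len(panels) != 1:
        raise SchemaError("all Burstein classes must share one gene panel")
    return model


def make_synthetic_burstein_model(
    seed: int = 7,
    n_genes: int = 80,
    classes: Sequence[str] = BURSTEIN_CLASSES,
) -> SignatureModel:
    """Synthetic stand-in for the published Burstein centroids.

    Four random log2 centroids over a shared panel of ``n_genes`` genes,
    suitable for exercising the classifier mechanics; it carries no biological
    meaning and is clearly not the published model.
    """
    rng = np.random.default_rng(seed)
    genes = tuple(f"BURST_{i:03d}" for i in range(1, n_genes + 1))
    centroids = {c: rng.normal(0.0, 1.0, size=n_genes) for c in classes}
    return validate_burstein_model(
        SignatureModel(classes=tuple(classes), genes={c: genes for c in classes},
                       centroids=centroids)
    )


def simulate_burstein_cohort(
    model: SignatureModel,
    n_per_class: int,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Centroid-plus-noise cohort for exercising the classifier; returns
    ``(expr, true_class)``."""
    rng = np.random.default_rng(seed)
    genes = list(model.genes[model.classes[0]])
    cols, truths, mats = [], [], []
    for cls in model.classes:
        block = (model.centroids[cls][:, None]
                 + rng.normal(0.0, noise_sd, size=(len(genes), n_per_class)))
        mats.append(block)
        cols += [f"{cls}_{i:04d}" for i in range(1, n_per_class + 1)]
        truths += [cls] * n_per_class
    expr = pd.DataFrame(np.hstack(mats) if mats else np.empty((len(genes), 0)),
                        index=pd.Index(genes, name="gene_id"), columns=cols)
    return expr, pd.Series(truths, index=cols, name="true_class")


def classify_burstein(expr: pd.DataFrame, model: SignatureModel) -> pd.Series:
    """Argmax-correlation call over the four shared-panel centroids.

    Reuses the generic scoring core; missing panel genes raise a lookup error
    listing them.
    """
    validate_burstein_model(model)
    table = classify_cohort(expr, model)
    return table["winning_class"].rename("burstein_class")


def crosstab_burstein_vs_dual(
    burstein_calls: pd.Series,
    dual_labels: pd.Series,
    expected_burstein: Sequence[str] = BURSTEIN_CLASSES,
) -> pd.DataFrame:
    """k x 4 contingency table of single/dual group vs Burstein class.

    Testing is delegated to :func:`dualsubtype.cohort_stats.chi_square_test`.
    """
    bad = set(burstein_calls.unique()) - set(expected_burstein)
    if bad:
        raise SchemaError(f"unexpected Burstein label(s): {sorted(bad)}")
    burstein_calls, dual_labels = burstein_calls.align(dual_labels, join="inner")
    if len(burstein_calls) == 0:
        raise SchemaError("no overlapping samples between the two call tables")
    tab = pd.crosstab(dual_labels, burstein_calls)
    return tab.reindex(columns=[c for c in expected_burstein], fill_value=0)
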