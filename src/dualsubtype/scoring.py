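"""Correlation-to-centroid subtype scoring.

Each molecular class (Luminal, Basal, HER2 in the standard three-class model)
is represented by a gene list and a centroid vector over those genes, on the
log2 expression scale.  A sample is scored against a class by the Pearson
correlation between the sample's profile restricted to that class's genes and
the class centroid; the class with the highest score is the standard subtype
call.  This correlation-to-centroid rule is the established design of
nearest-centroid expression classifiers; alternative score functions can be
plugged in via ``score_fn``.

Genes are standardized *neither* in the profile nor in the centroid by
default (``standardize=False``); Pearson correlation is already invariant to
per-profile affine transforms, and gene-wise standardization is a cohort-level
preprocessing decision left to the caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GeneLookupError, TrainingError, UndefinedScoreError

#: Fixed tie-break order for the standard three-class model (most to least
#: prevalent in typical early-breast-cancer cohorts).  Purely a determinism
#: contract: an exact score tie is broken in favour of the earlier class.
CLASS_ORDER: tuple[str, ...] = ("Luminal", "Basal", "HER2")


@dataclass(frozen=True)
class SignatureModel:
    """Named classes, each with a gene list and a centroid over those genes.

    Parameters
    ----------
    classes
        Ordered class names; the order doubles as the tie-break order.
    genes
        Per-class gene identifier lists (no duplicates within a class).
    centroids
        Per-class centroid vectors, log2 units, same length as the gene list
        and with nonzero variance (required for Pearson correlation).
    """

    classes: tuple[str, ...]
    genes: dict[str, tuple[str, ...]] = field(repr=False)
    centroids: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.classes) != len(set(self.classes)):
            raise ValueError("duplicate class names")
        for cls in self.classes:
            g = tuple(self.genes[cls])
            c = np.asarray(self.centroids[cls], dtype=float)
            if len(g) != len(set(g)):
                raise ValueError(f"duplicate genes in signature {cls!r}")
            if len(c) != len(g):
                raise ValueError(
                    f"centroid length {len(c)} != gene list length {len(g)} for {cls!r}"
                )
            if len(g) < 2 or np.ptp(c) == 0.0:
                raise ValueError(f"centroid of {cls!r} has zero variance")
            object.__setattr__(self, "genes", {**self.genes, cls: g})
            object.__setattr__(self, "centroids", {**self.centroids, cls: c})

    @property
    def all_genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for cls in self.classes:
            for g in self.genes[cls]:
                seen.setdefault(g)
        return tuple(seen)

    # -- JSON serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "signatures": {
                cls: {
                    "genes": list(self.genes[cls]),
                    "centroid": [float(v) for v in self.centroids[cls]],
                }
                for cls in self.classes
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SignatureModel":
        classes = tuple(d["classes"])
        sig = d["signatures"]
        return cls(
            classes=classes,
            genes={c: tuple(sig[c]["genes"]) for c in classes},
            centroids={c: np.asarray(sig[c]["centroid"], dtype=float) for c in classes},
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_centroids(
    expr: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    class_order: Sequence[str] | None = None,
) -> SignatureModel:
    """Train per-class mean centroids from a labeled cohort.

    ``expr`` is genes x samples; ``labels`` maps sample id -> class name.
    The centroid of a class is the per-gene mean over that class's samples,
    restricted to that class's gene set.  Substitutes for proprietary assay
    centroids, which are not redistributable.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    missing = [g for gs in gene_sets.values() for g in gs if g not in expr.index]
    if missing:
        raise GeneLookupError(sorted(set(missing)))
    classes = tuple(class_order) if class_order is not None else tuple(gene_sets)
    genes: dict[str, tuple[str, ...]] = {}
    centroids: dict[str, np.ndarray] = {}
    for cls in classes:
        members = labels.index[labels == cls]
        members = [s for s in members if s in expr.columns]
        if len(members) < 2:
            raise TrainingError(f"class {cls!r} has {len(members)} labeled samples; need >=2")
        sub = expr.loc[list(gene_sets[cls]), members]
        genes[cls] = tuple(gene_sets[cls])
        centroids[cls] = sub.mean(axis=1).to_numpy(dtype=float)
    return SignatureModel(classes=classes, genes=genes, centroids=centroids)


def pearson_score(x: np.ndarray, c: np.ndarray) -> float:
    """Pearson correlation of a profile restriction against a centroid.

    Raises :class:`UndefinedScoreError` when either vector is constant rather
    than silently returning 0.
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    xc = x - x.mean()
    cc = c - c.mean()
    sx = float(np.sqrt(xc @ xc))
    sc = float(np.sqrt(cc @ cc))
    if sx == 0.0 or sc == 0.0:
        raise UndefinedScoreError("zero-variance restriction: correlation undefined")
    return float(np.clip((xc @ cc) / (sx * sc), -1.0, 1.0))


def score_sample(
    profile: Mapping[str, float] | pd.Series,
    model: SignatureModel,
    score_fn: Callable[[np.ndarray, np.ndarray], float] = pearson_score,
) -> dict:
    """Score one expression profile against every class of a model.

    Returns a dict with per-class ``scores``, ``winning_class``,
    ``runner_up_class`` and the nonnegative top difference ``d_top``
    (winner minus runner-up); ``d_low`` (winner minus lowest) is kept as a
    diagnostic.  Ties are broken by the model's class order.
    """
    if not isinstance(profile, pd.Series):
        profile = pd.Series(profile, dtype=float)
    missing = [g for g in model.all_genes if g not in profile.index]
    if missing:
        raise GeneLookupError(missing)
    scores = {
        cls: score_fn(profile.loc[list(model.genes[cls])].to_numpy(dtype=float),
                      model.centroids[cls])
        for cls in model.classes
    }
    ranked = rank_classes(scores, model.classes)
    d_top = scores[ranked[0]] - scores[ranked[1]]
    return {
        "scores": scores,
        "winning_class": ranked[0],
        "runner_up_class": ranked[1],
        "d_top": d_top,
        "d_low": scores[ranked[0]] - scores[ranked[-1]],
    }


def rank_classes(scores: Mapping[str, float], order: Sequence[str]) -> list[str]:
    """Classes sorted by descending score, ties broken by ``order``."""
    pos = {c: i for i, c in enumerate(order)}
    return sorted(scores, key=lambda c: (-scores[c], pos[c]))


def standard_classify(scores: Mapping[str, float],
                      order: Sequence[str] = CLASS_ORDER) -> str:
    """Standard subtype call: the argmax class, ties broken by fixed order."""
    present = [c for c in order if c in scores] + [c for c in scores if c not in order]
    return rank_classes(scores, present)[0]


def classify_cohort(
    expr: pd.DataFrame,
    model: SignatureModel,
) -> pd.DataFrame:
    """Score and classify every sample of a genes x samples matrix.

    Vectorized over samples.  Output is indexed by sample id with columns
    ``score_<class>`` per class, ``winning_class``, ``runner_up_class``,
    ``d_top`` and ``d_low``.  A zero-variance restriction raises
    :class:`UndefinedScoreError` naming the offending sample.
    """
    cols = [f"score_{c}" for c in model.classes]
    if expr.shape[1] == 0:
        return pd.DataFrame(
            columns=cols + ["winning_class", "runner_up_class", "d_top", "d_low"]
        )
    missing = [g for g in model.all_genes if g not in expr.index]
    if missing:
        raise GeneLookupError(missing)

    n = expr.shape[1]
    score_mat = np.empty((n, len(model.classes)))
    for j, cls in enumerate(model.classes):
        x = expr.loc[list(model.genes[cls])].to_numpy(dtype=float)  # k x n
        c = model.centroids[cls]
        xc = x - x.mean(axis=0, keepdims=True)
        cc = c - c.mean()
        sx = np.sqrt((xc**2).sum(axis=0))
        sc = np.sqrt(cc @ cc)
        bad = np.flatnonzero(sx == 0.0)
        if bad.size:
            raise UndefinedScoreError(
                f"zero-variance restriction for class {cls!r} in sample(s) "
                f"{list(expr.columns[bad[:5]])}"
            )
        score_mat[:, j] = np.clip((xc.T @ cc) / (sx * sc), -1.0, 1.0)

    # argsort with the class order as secondary key via stable sort on -score
    order_idx = np.argsort(-score_mat, axis=1, kind="stable")
    classes = np.asarray(model.classes)
    win = classes[order_idx[:, 0]]
    run = classes[order_idx[:, 1]]
    top = np.take_along_axis(score_mat, order_idx[:, :1], axis=1)[:, 0]
    second = np.take_along_axis(score_mat, order_idx[:, 1:2], axis=1)[:, 0]
    low = score_mat.min(axis=1)
    out = pd.DataFrame(score_mat, index=expr.columns, columns=cols)
    out["winning_class"] = win
    out["runner_up_class"] = run
    out["d_top"] = top - second
    out["d_low"] = top - low
    out.index.name = "sample_id"
    return out
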