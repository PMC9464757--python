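"""Single / dual / triple subtype calling.

A sample whose top two (or three) subtype scores are statistically
indiscernible carries more than one activated expression program.  Two
complementary sources of evidence decide indiscernibility:

1. **Cohort thresholds from multimodality detection.**  Across a cohort, the
   top difference ``d = score(winner) - score(runner-up)`` of samples won by a
   given class is collected.  When its distribution is bimodal — a low-``d``
   mode of multi-program samples and a high-``d`` mode of clean singles — the
   valley between the two modes is the natural per-class threshold.  Bimodality
   is detected by comparing 1- and 2-component Gaussian mixtures by BIC with a
   separation guard; without convincing bimodality the threshold falls back to
   a low quantile of ``d``.

2. **Per-sample gene bootstrap.**  Each signature's genes are resampled with
   replacement and the correlation scores recomputed; the *flip fraction* of a
   class pair is the fraction of replicates in which the lower-ranked class
   meets or exceeds the top class.  A high flip fraction means the observed
   ranking is not stable under sampling of the signature genes.

A pair is called indiscernible when **either** criterion fires (the observed
``d`` is strictly below the winning class's threshold, or the flip fraction
exceeds ``alpha``); both criteria can be disabled individually.  A sample is
Dual when the (top, second) pair is indiscernible, Triple when (second, third)
also is, and Single otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .errors import BootstrapFailureError, ClassificationError
from .scoring import CLASS_ORDER, SignatureModel, classify_cohort, rank_classes


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapDistribution:
    """Per-replicate class scores for one sample's gene bootstrap.

    ``scores`` is (B x n_classes) with NaN rows for invalid replicates (a
    resampled gene multiset with zero profile or centroid variance).
    """

    sample_id: str | None
    classes: tuple[str, ...]
    scores: np.ndarray = field(repr=False)

    @property
    def B(self) -> int:
        return self.scores.shape[0]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.scores).all(axis=1)

    def flip_fraction(self, top: str, other: str) -> float:
        """Fraction of valid replicates where ``other`` scores >= ``top``.

        Ties count as flips, so flip(i,j) + flip(j,i) >= 1.
        """
        v = self.valid
        if not v.any():
            raise BootstrapFailureError("no valid bootstrap replicates")
        i = self.classes.index(top)
        j = self.classes.index(other)
        return float(np.mean(self.scores[v, j] >= self.scores[v, i]))


def bootstrap_scores(
    profile: Mapping[str, float] | pd.Series,
    model: SignatureModel,
    B: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    sample_id: str | None = None,
    max_invalid_fraction: float = 0.5,
) -> BootstrapDistribution:
    """Gene bootstrap of one sample's correlation scores.

    Each replicate resamples, independently for each class, that class's
    genes with replacement (same size as the signature) and recomputes the
    Pearson score on the resampled gene multiset.  All classes draw from a
    single RNG stream so a (seed, B) pair fully determines the replicates.
    Raises :class:`BootstrapFailureError` when more than half the replicates
    are invalid.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not isinstance(profile, pd.Series):
        profile = pd.Series(profile, dtype=float)
    rng = np.random.default_rng(seed)
    scores = np.empty((B, len(model.classes)))
    for j, cls in enumerate(model.classes):
        genes = list(model.genes[cls])
        k = len(genes)
        x = profile.loc[genes].to_numpy(dtype=float)
        c = model.centroids[cls]
        idx = rng.integers(0, k, size=(B, k))
        xs = x[idx]
        cs = c[idx]
        xc = xs - xs.mean(axis=1, keepdims=True)
        cc = cs - cs.mean(axis=1, keepdims=True)
        sx = np.sqrt((xc**2).sum(axis=1))
        sc = np.sqrt((cc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc * cc).sum(axis=1) / (sx * sc)
        r[(sx == 0.0) | (sc == 0.0)] = np.nan
        scores[:, j] = np.clip(r, -1.0, 1.0)
    boot = BootstrapDistribution(sample_id=sample_id, classes=tuple(model.classes),
                                 scores=scores)
    if 1.0 - boot.valid.mean() > max_invalid_fraction:
        raise BootstrapFailureError(
            f"{(~boot.valid).sum()} of {B} bootstrap replicates invalid"
        )
    return boot


# ---------------------------------------------------------------------------
# cohort thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassThreshold:
    """Threshold on the top difference for one winning class."""

    value: float | None
    decision: str  # "bimodal-valley" | "quantile-fallback" | "undefined"
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-winning-class thresholds plus the modality evidence behind each."""

    thresholds: dict[str, ClassThreshold]

    def __getitem__(self, cls: str) -> ClassThreshold:
        return self.thresholds[cls]

    def __contains__(self, cls: str) -> bool:
        return cls in self.thresholds

    def to_dict(self) -> dict:
        return {
            cls: {"threshold": t.value, "decision": t.decision,
                  "diagnostics": t.diagnostics}
            for cls, t in self.thresholds.items()
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def _quantile_threshold(d: np.ndarray, fallback_q: float) -> float:
    # 'lower' returns an observed order statistic; together with the strict
    # comparison in the calling rule, the sample attaining the threshold is
    # not flagged (so a degenerate all-equal distribution yields no duals).
    return float(np.percentile(d, fallback_q, method="lower"))


#: Below this many observations a 2-component mixture fit is meaningless;
#: the quantile fallback is used directly.
MIN_MIXTURE_N = 20


def _fit_threshold_one(d: np.ndarray, fallback_q: float, grid_step: float,
                       random_state: int) -> ClassThreshold:
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        return ClassThreshold(None, "undefined", {"n": 0})
    if np.unique(d).size < 3 or d.size < MIN_MIXTURE_N:
        return ClassThreshold(_quantile_threshold(d, fallback_q),
                              "quantile-fallback",
                              {"n": int(d.size), "quantile": fallback_q,
                               "note": "too few/degenerate observations"})
    X = d[:, None]
    gm1 = GaussianMixture(1, random_state=random_state).fit(X)
    gm2 = GaussianMixture(2, n_init=3, random_state=random_state).fit(X)
    means = gm2.means_.ravel()
    sds = np.sqrt(gm2.covariances_.ravel())
    weights = gm2.weights_.ravel()
    separated = abs(means[0] - means[1]) > sds.sum()
    if gm2.bic(X) < gm1.bic(X) and separated:
        lo, hi = sorted(means)
        grid = np.arange(lo, hi + grid_step, grid_step)
        dens = (weights[:, None]
                * stats.norm.pdf(grid[None, :], means[:, None], sds[:, None])).sum(axis=0)
        value = float(grid[int(np.argmin(dens))])
        return ClassThreshold(
            value, "bimodal-valley",
            {"n": int(d.size), "means": means.tolist(), "sds": sds.tolist(),
             "weights": weights.tolist(),
             "bic_1": float(gm1.bic(X)), "bic_2": float(gm2.bic(X))},
        )
    value = _quantile_threshold(d, fallback_q)
    return ClassThreshold(
        value, "quantile-fallback",
        {"n": int(d.size), "quantile": fallback_q,
         "bic_1": float(gm1.bic(X)), "bic_2": float(gm2.bic(X)),
         "separated": bool(separated)},
    )


def fit_difference_thresholds(
    scores_table: pd.DataFrame,
    classes: Sequence[str] | None = None,
    min_class_n: int = 50,
    fallback_q: float = 5.0,
    grid_step: float = 1e-4,
    random_state: int = 0,
) -> ThresholdSet:
    """Fit per-winning-class thresholds on the top difference ``d``.

    For each class, the ``d_top`` values of samples won by that class are
    modelled with 1- and 2-component Gaussian mixtures.  When the 2-component
    fit wins on BIC *and* its component means are separated by more than the
    sum of their SDs, the threshold is the density minimum between the two
    means (grid search at ``grid_step``); otherwise it is the ``fallback_q``-th
    percentile of ``d``.  Classes with fewer than ``min_class_n`` winners fall
    back to the pooled distribution over all samples; classes with no samples
    get an undefined threshold.
    """
    if classes is None:
        classes = [c for c in CLASS_ORDER if (scores_table["winning_class"] == c).any()]
        classes += [c for c in scores_table["winning_class"].unique() if c not in classes]
    pooled = scores_table["d_top"].to_numpy(dtype=float)
    out: dict[str, ClassThreshold] = {}
    for cls in classes:
        d = scores_table.loc[scores_table["winning_class"] == cls, "d_top"].to_numpy(float)
        if d.size == 0:
            out[cls] = ClassThreshold(None, "undefined", {"n": 0})
        elif d.size < min_class_n:
            t = _fit_threshold_one(pooled, fallback_q, grid_step, random_state)
            out[cls] = ClassThreshold(t.value, t.decision,
                                      {**t.diagnostics, "pooled": True})
        else:
            out[cls] = _fit_threshold_one(d, fallback_q, grid_step, random_state)
    return ThresholdSet(out)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DualCall:
    """Final Single/Dual/Triple call for one sample with its evidence."""

    sample_id: str | None
    kind: str  # "Single" | "Dual" | "Triple"
    components: tuple[str, ...]  # classes by descending observed score
    evidence: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        if self.kind == "Single":
            return f"{self.components[0]}-single-type"
        return "-".join(self.components) + "-type"


def canonical_label(components: Sequence[str]) -> str:
    """Group label with components in fixed class order (score-independent),
    for grouping samples regardless of which component scored higher."""
    comp = tuple(components)
    if len(comp) == 1:
        return f"{comp[0]}-single-type"
    ordered = [c for c in CLASS_ORDER if c in comp] + [c for c in comp
                                                       if c not in CLASS_ORDER]
    return "-".join(ordered) + "-type"


def classify_single_dual(
    scores: Mapping[str, float],
    boot: BootstrapDistribution | None,
    thresholds: ThresholdSet,
    alpha: float = 0.05,
    use_threshold: bool = True,
    use_bootstrap: bool = True,
    sample_id: str | None = None,
) -> DualCall:
    """Call one sample Single, Dual or Triple.

    ``scores`` maps class name -> observed score.  The (top, second) pair is
    indiscernible iff ``d < t_winning`` or ``flip_fraction(top, second) >
    alpha``; the (second, third) pair is tested by the same rule, reusing the
    winning class's threshold on ``score(second) - score(third)``.  Triple iff
    both pairs are indiscernible, Dual iff only the first, else Single.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0,1)")
    if use_bootstrap and boot is None:
        raise ClassificationError("bootstrap criterion enabled but no bootstrap given")
    ranked = rank_classes(scores, [c for c in CLASS_ORDER if c in scores]
                          + [c for c in scores if c not in CLASS_ORDER])
    winner = ranked[0]
    t: float | None = None
    if use_threshold:
        if winner not in thresholds or thresholds[winner].value is None:
            raise ClassificationError(
                f"no threshold defined for winning class {winner!r}"
                + (f" (sample {sample_id})" if sample_id else "")
            )
        t = thresholds[winner].value

    def indiscernible(hi: str, lo: str) -> tuple[bool, float, float | None]:
        d = scores[hi] - scores[lo]
        flip = boot.flip_fraction(hi, lo) if use_bootstrap else None
        # strictly below: the fallback threshold is itself an observed d
        # value, and the sample attaining it must not be flagged (a
        # degenerate all-equal d distribution stays all-Single).
        by_t = use_threshold and d < t
        by_b = use_bootstrap and flip > alpha
        return (by_t or by_b), d, flip

    pair1, d1, flip1 = indiscernible(ranked[0], ranked[1])
    evidence = {
        "d_top": d1, "flip_fraction_top": flip1, "threshold_applied": t,
        "alpha": alpha,
    }
    if not pair1:
        return DualCall(sample_id, "Single", (winner,), evidence)
    if len(ranked) >= 3:
        pair2, d2, flip2 = indiscernible(ranked[1], ranked[2])
        evidence.update({"d_second": d2, "flip_fraction_second": flip2})
        if pair2:
            return DualCall(sample_id, "Triple", tuple(ranked[:3]), evidence)
    return DualCall(sample_id, "Dual", tuple(ranked[:2]), evidence)


def classify_cohort_dual(
    expr: pd.DataFrame,
    model: SignatureModel,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    thresholds: ThresholdSet | None = None,
    min_class_n: int = 50,
    fallback_q: float = 5.0,
    use_threshold: bool = True,
    use_bootstrap: bool = True,
) -> tuple[pd.DataFrame, ThresholdSet]:
    """Two-pass cohort classification.

    Pass 1 scores every sample and fits per-class thresholds from the cohort's
    top-difference distributions (unless ``thresholds`` is supplied); pass 2
    bootstraps each sample and produces the final call.  Per-sample bootstrap
    seeds are spawned from ``seed``, so results are order-independent and
    bit-reproducible.

    Returns ``(calls, thresholds)`` where ``calls`` has one row per sample:
    per-class scores, ``kind``, ``label`` (components in score order),
    ``canonical_label``, ``d_top``, ``flip_fraction_top``,
    ``threshold_applied``.
    """
    scores_table = classify_cohort(expr, model)
    if thresholds is None:
        thresholds = fit_difference_thresholds(
            scores_table, classes=model.classes, min_class_n=min_class_n,
            fallback_q=fallback_q,
        )
    n = scores_table.shape[0]
    if n == 0:
        cols = ([f"score_{c}" for c in model.classes]
                + ["kind", "label", "canonical_label", "components",
                   "d_top", "flip_fraction_top", "threshold_applied"])
        return pd.DataFrame(columns=cols), thresholds
    children = np.random.SeedSequence(seed).spawn(n)
    records = []
    for child, (sid, row) in zip(children, scores_table.iterrows()):
        scores = {c: row[f"score_{c}"] for c in model.classes}
        boot = None
        if use_bootstrap:
            boot = bootstrap_scores(expr[sid], model, B=B, seed=child, sample_id=sid)
        call = classify_single_dual(
            scores, boot, thresholds, alpha=alpha,
            use_threshold=use_threshold, use_bootstrap=use_bootstrap, sample_id=sid,
        )
        rec = {f"score_{c}": scores[c] for c in model.classes}
        rec.update(
            kind=call.kind,
            label=call.label,
            canonical_label=canonical_label(call.components),
            components="|".join(call.components),
            d_top=call.evidence["d_top"],
            flip_fraction_top=call.evidence["flip_fraction_top"],
            threshold_applied=call.evidence["threshold_applied"],
        )
        records.append(rec)
    calls = pd.DataFrame(records, index=scores_table.index)
    calls.index.name = "sample_id"
    return calls, thresholds
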