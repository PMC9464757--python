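"""Clinical-subtype derivation rules and the cohort statistical toolkit.

Receptor-status rules follow standard clinical practice: a tumor is
HR-positive when ER or PR immunohistochemistry shows at least 1% positivity;
HER2 status combines IHC (0/1+/2+/3+) with FISH reflex testing for the
equivocal 2+ category.  The statistics are the cohort-level workhorses:
Pearson chi-square tests of independence (no continuity correction), Welch
two-sample t-tests, Wilson proportion intervals, and maximum-likelihood
logistic regression with Wald inference.

No multiple-testing adjustment is applied anywhere; every p-value returned is
raw.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import Logit
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import (
    DegenerateTableError,
    InsufficientDataError,
    MissingStatusError,
    SeparationError,
)

#: Ki67 dichotomization threshold (%) tagging the low-proliferation range
#: proposed for triple-negative low-proliferation (TNLP) tumors.
KI67_TNLP_THRESHOLD = 30.0

#: ER-low-positive band (% IHC), inclusive on both ends.
ER_LOW_RANGE = (1.0, 10.0)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def derive_hr_status(er_pct: float | None, pr_pct: float | None) -> str:
    """HR+ iff ER or PR shows at least 1% positivity; HR- otherwise.

    Raises :class:`MissingStatusError` when both fields are missing.  A single
    available field decides the call on its own.
    """
    er_missing, pr_missing = _is_missing(er_pct), _is_missing(pr_pct)
    if er_missing and pr_missing:
        raise MissingStatusError("both er_pct and pr_pct missing")
    if (not er_missing and er_pct >= 1.0) or (not pr_missing and pr_pct >= 1.0):
        return "HR+"
    return "HR-"


def derive_her2_status(her2_ihc: str | None, her2_fish: str | None = None) -> str:
    """HER2 status from IHC with FISH reflex for the equivocal 2+ score.

    IHC 0, 1+ and 2+/FISH-non-amplified are HER2-; IHC 2+/FISH-amplified and
    3+ are HER2+.  IHC 2+ without a FISH result cannot be resolved.
    """
    if _is_missing(her2_ihc):
        raise MissingStatusError("her2_ihc missing")
    ihc = str(her2_ihc)
    if ihc not in {"0", "1+", "2+", "3+"}:
        raise MissingStatusError(f"unrecognized her2_ihc value {her2_ihc!r}")
    if ihc == "3+":
        return "HER2+"
    if ihc in {"0", "1+"}:
        return "HER2-"
    # ihc == "2+": FISH decides
    if _is_missing(her2_fish):
        raise MissingStatusError("her2_ihc 2+ requires a FISH result")
    fish = str(her2_fish)
    if fish == "amplified":
        return "HER2+"
    if fish == "non-amplified":
        return "HER2-"
    raise MissingStatusError(f"unrecognized her2_fish value {her2_fish!r}")


def derive_clinical_subtype(er_pct, pr_pct, her2_ihc, her2_fish=None) -> str:
    """Combined four-way clinical subtype, e.g. ``HR+HER2-``."""
    return derive_hr_status(er_pct, pr_pct) + derive_her2_status(her2_ihc, her2_fish)


def is_er_low_positive(er_pct: float) -> bool:
    """ER-low positive: 1-10% IHC staining, inclusive."""
    return ER_LOW_RANGE[0] <= er_pct <= ER_LOW_RANGE[1]


def is_tnlp_range(ki67_pct: float) -> bool:
    """Low-proliferation (TNLP) range: Ki67 below 30%."""
    return ki67_pct < KI67_TNLP_THRESHOLD


# ---------------------------------------------------------------------------
# tests and summaries
# ---------------------------------------------------------------------------

def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    ``table`` is an r x c array-like (or DataFrame) of nonnegative counts.
    Returns ``(statistic, df, p)``; any zero expected count is an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateTableError("table must be at least 2x2")
    if (obs < 0).any():
        raise DegenerateTableError("counts must be nonnegative")
    n = obs.sum()
    if n == 0:
        raise DegenerateTableError("empty table")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if (expected == 0).any():
        raise DegenerateTableError("zero expected count")
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


def welch_t_test(x, y, equal_var: bool = False) -> tuple[float, float, float]:
    """Unpaired two-sample t-test; Welch (unequal variances) by default.

    Returns ``(t, df, p)`` with Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each group needs >= 2 observations")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def proportion_with_ci(k: int, n: int) -> dict:
    """Fraction ``k/n`` with a 95% Wilson score interval.

    Returns ``{"fraction", "pct", "ci_low", "ci_high"}`` (CI on the fraction
    scale).
    """
    if n < 1:
        raise InsufficientDataError("n must be >= 1")
    if not (0 <= k <= n):
        raise InsufficientDataError("k must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    frac = k / n
    return {"fraction": frac, "pct": 100.0 * frac,
            "ci_low": float(lo), "ci_high": float(hi)}


@dataclass(frozen=True)
class LogisticFit:
    """Per-covariate MLE results of a logistic regression."""

    table: pd.DataFrame = field(repr=False)  # coef, se, z, p per covariate
    converged: bool
    separation: bool
    llf: float

    @property
    def usable(self) -> bool:
        return self.converged and not self.separation

    def coef(self, name: str) -> float:
        return float(self.table.loc[name, "coef"])


def logistic_fit(
    design: pd.DataFrame,
    outcome: Sequence[int] | pd.Series,
    add_intercept: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald p-values.

    The model is fit by Newton-Raphson (iteratively reweighted least squares),
    converging when the gradient norm drops below 1e-8 (at most 100
    iterations).  Constant or exactly collinear columns and degenerate
    outcomes are rejected.  Under separation the likelihood is unbounded: a
    fit the optimizer aborts raises :class:`SeparationError`, while diverging
    but finite estimates are returned with ``separation=True`` (``usable`` is
    False) and a warning — never silently reported as trustworthy.
    """
    X = design.astype(float).copy()
    y = np.asarray(outcome, dtype=float)
    if len(X) != len(y):
        raise InsufficientDataError("design and outcome lengths differ")
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("all outcomes identical")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise InsufficientDataError("outcome must be binary 0/1")
    for col in X.columns:
        if X[col].nunique() < 2:
            raise InsufficientDataError(f"column {col!r} is constant")
    if add_intercept:
        X.insert(0, "intercept", 1.0)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise InsufficientDataError("design matrix is rank deficient (collinear columns)")
    try:
        res = Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(str(exc)) from exc
    separation = bool(np.any(np.abs(res.params) > 30.0))
    if separation:
        warnings.warn(
            "separation detected: |coefficient| diverging; estimates flagged unusable",
            RuntimeWarning,
            stacklevel=2,
        )
    table = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues}
    )
    return LogisticFit(table=table, converged=bool(res.mle_retvals["converged"]),
                       separation=separation, llf=float(res.llf))
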