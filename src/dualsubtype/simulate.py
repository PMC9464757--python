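"""Synthetic expression cohorts with planted single/dual/triple subtype structure.

The generator emulates the statistical shape of an early-breast-cancer
molecular-subtyping cohort: three expression programs (Luminal, Basal, HER2),
each carried by its own signature gene set, a majority of samples with one
dominant program, a minority with two (or all three) programs simultaneously
active at attenuated strength, plus background genes that are pure noise.
Clinical annotations (ER%, PR%, Ki67%, HER2 IHC/FISH, stage, grade, therapy)
are drawn from class-conditional distributions so that the couplings seen in
real cohorts hold by construction: ER% highest in Luminal-singles and
intermediate in Luminal-containing duals; Ki67% ordered
Luminal-single < Luminal-dual < Basal/HER2-single; HER2 IHC/FISH consistent
with the assigned clinical subtype.

Counts of the planted compositions are allocated deterministically by
largest-remainder rounding, so fixture sizes are exact; randomness is
confined to expression noise and the clinical/outcome draws.  Every operation
is bit-reproducible under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyCohortError
from .scoring import CLASS_ORDER

#: The four clinical subtypes (hormone-receptor status x HER2 status).
CLINICAL_SUBTYPES: tuple[str, ...] = ("HR+HER2-", "HR+HER2+", "HR-HER2+", "HR-HER2-")

#: Class-conditional clinical-subtype probabilities.  Chosen once to mirror
#: the cross-classification patterns of clinical vs molecular subtype in
#: early-breast-cancer registries: Luminal-singles are overwhelmingly
#: HR+HER2-, Basal-singles split between triple-negative and HR+HER2-
#: (ER-low) disease, HER2-singles are mostly clinically HER2+, and
#: Luminal-Basal duals are almost always clinically HER2-.
_CLINICAL_TABLE: dict[tuple[str, ...], tuple[float, float, float, float]] = {
    ("Luminal",): (0.92, 0.06, 0.01, 0.01),
    ("Basal",): (0.40, 0.02, 0.03, 0.55),
    ("HER2",): (0.07, 0.45, 0.45, 0.03),
    ("Luminal", "Basal"): (0.66, 0.03, 0.01, 0.30),
    ("Luminal", "HER2"): (0.18, 0.60, 0.20, 0.02),
    ("Basal", "HER2"): (0.05, 0.15, 0.50, 0.30),
    ("Luminal", "Basal", "HER2"): (0.25, 0.25, 0.25, 0.25),
}

_KIND_NAMES = {1: "Single", 2: "Dual", 3: "Triple"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``activation_effect`` is the mean log2 shift of an active signature's
    genes; when two or more programs are co-active each program's shift is
    scaled by ``dual_attenuation`` (duals show intermediate marker levels).
    ``signature_sizes`` defaults to the 58/28/4-gene Luminal/Basal/HER2
    panel of the 80-gene assay family.
    """

    n_samples: int = 2000
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"Luminal": 0.80, "Basal": 0.12, "HER2": 0.08}
    )
    dual_fraction: float = 0.05
    triple_fraction: float = 0.003
    signature_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"Luminal": 58, "Basal": 28, "HER2": 4}
    )
    n_background_genes: int = 100
    activation_effect: float = 2.0
    dual_attenuation: float = 0.7
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples == 0:
            raise EmptyCohortError("n_samples must be positive")
        if self.n_samples < 0:
            raise ConfigurationError("n_samples must be positive")
        if set(self.class_proportions) != set(CLASS_ORDER):
            raise ConfigurationError(
                f"class_proportions must cover exactly {CLASS_ORDER}"
            )
        total = float(sum(self.class_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class_proportions sum to {total}, not 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ConfigurationError("class proportions must be nonnegative")
        if not (0.0 <= self.dual_fraction <= 1.0 and 0.0 <= self.triple_fraction <= 1.0):
            raise ConfigurationError("dual/triple fractions must lie in [0,1]")
        if self.dual_fraction + self.triple_fraction > 1.0 + 1e-12:
            raise ConfigurationError("dual_fraction + triple_fraction must be <= 1")
        if self.n_background_genes < 0:
            raise ConfigurationError("n_background_genes must be nonnegative")
        if self.activation_effect <= 0:
            raise ConfigurationError("activation_effect must be positive")
        if not (0.0 < self.dual_attenuation <= 1.0):
            raise ConfigurationError("dual_attenuation must lie in (0,1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if any(self.signature_sizes.get(c, 0) < 2 for c in CLASS_ORDER):
            raise ConfigurationError("each signature needs >=2 genes")


def allocate_counts(total: int, weights: Sequence[float]) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` across ``weights``."""
    raw = np.asarray(weights, dtype=float)
    if total == 0 or raw.sum() == 0.0:
        if total > 0:
            raise ConfigurationError("cannot allocate a positive total over zero weights")
        return np.zeros(len(raw), dtype=int)
    raw = raw / raw.sum() * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def signature_gene_names(config: SimConfig) -> dict[str, list[str]]:
    """Deterministic gene identifiers for each signature."""
    prefix = {"Luminal": "LUM", "Basal": "BAS", "HER2": "HER"}
    return {
        cls: [f"{prefix[cls]}_{i:03d}" for i in range(1, config.signature_sizes[cls] + 1)]
        for cls in CLASS_ORDER
    }


#: Amplitude (log2 units) of the anti-aligned baseline of signature genes:
#: marker genes sit *below* their activated level when their program is off
#: (e.g. HER2-amplicon genes in non-amplified tumors), so inactive samples
#: anti-correlate with the class centroid instead of scoring at random.
BASELINE_CONTRAST = 1.0


def activation_loadings(k: int) -> np.ndarray:
    """Per-gene activation loadings: linspace(-1, 3) with mean exactly 1.

    An active program shifts gene g by ``activation_effect * loading_g``;
    negative loadings are genes the program represses, as in real subtype
    panels.  The graded loadings give each signature internal structure (a
    flat shift would be invisible to correlation scoring) while the unit mean
    keeps the average shift equal to ``activation_effect``; the wide span
    keeps the pairwise gene contrasts of even a 4-gene signature well above
    typical noise levels, as expected of a curated on/off marker panel.
    """
    return np.linspace(-1.0, 3.0, k)


def baseline_profile(k: int) -> np.ndarray:
    """Inactive-state baseline of a signature's genes: ``-(w - 1)`` scaled by
    :data:`BASELINE_CONTRAST`, where ``w`` are the activation loadings.

    The baseline has mean exactly 0 (it does not move the signature's mean
    expression) and is anti-aligned with the activation pattern, so a sample
    whose program is off scores strongly negative against the class centroid.
    """
    return -BASELINE_CONTRAST * (activation_loadings(k) - 1.0)


def _compositions(config: SimConfig) -> list[tuple[tuple[str, ...], int]]:
    """Deterministic (composition, count) allocation for one cohort."""
    n = config.n_samples
    n_single, n_dual, n_triple = allocate_counts(
        n,
        [1.0 - config.dual_fraction - config.triple_fraction,
         config.dual_fraction, config.triple_fraction],
    )
    out: list[tuple[tuple[str, ...], int]] = []
    p = {c: config.class_proportions[c] for c in CLASS_ORDER}
    single_counts = allocate_counts(int(n_single), [p[c] for c in CLASS_ORDER])
    out += [((c,), int(k)) for c, k in zip(CLASS_ORDER, single_counts)]
    pairs = [("Luminal", "Basal"), ("Luminal", "HER2"), ("Basal", "HER2")]
    pair_w = [p[a] * p[b] for a, b in pairs]
    dual_counts = allocate_counts(int(n_dual), pair_w)
    out += [(pair, int(k)) for pair, k in zip(pairs, dual_counts)]
    out.append((("Luminal", "Basal", "HER2"), int(n_triple)))
    return out


def truth_group(components: Sequence[str]) -> str:
    """Human-readable group label, e.g. ``Luminal-single-type``,
    ``Luminal-Basal-type`` (components in canonical class order)."""
    comp = tuple(components)
    if len(comp) == 1:
        return f"{comp[0]}-single-type"
    ordered = [c for c in CLASS_ORDER if c in comp]
    return "-".join(ordered) + "-type"


def generate_expression_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples log2 expression matrix plus its truth table.

    Returns ``(expr, truth)`` where ``truth`` has one row per sample with
    columns ``true_components`` (tuple of class names), ``true_label_kind``
    (Single/Dual/Triple), ``true_label`` (group name) and ``clinical_subtype``.
    Every signature gene carries a zero-mean anti-aligned off-state baseline
    (see :func:`baseline_profile`); active signature genes are additionally
    shifted by ``activation_effect`` times the per-gene loading (times
    ``dual_attenuation`` when >=2 programs are active), so the *mean* shift
    of an active signature equals ``activation_effect`` exactly.  Background
    genes are pure Gaussian noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    gene_names = signature_gene_names(config)
    bg = [f"BG_{i:04d}" for i in range(1, config.n_background_genes + 1)]
    all_genes = [g for c in CLASS_ORDER for g in gene_names[c]] + bg
    n = config.n_samples
    sample_ids = [f"S{i:05d}" for i in range(1, n + 1)]

    rows = []
    for comp, count in _compositions(config):
        rows.extend([(comp, _KIND_NAMES[len(comp)])] * count)
    # clinical subtypes drawn per sample, conditional on composition
    clin = [
        CLINICAL_SUBTYPES[rng.choice(4, p=np.asarray(_CLINICAL_TABLE[comp]))]
        for comp, _kind in rows
    ]
    truth = pd.DataFrame(
        {
            "true_components": [comp for comp, _ in rows],
            "true_label_kind": [kind for _, kind in rows],
            "true_label": [truth_group(comp) for comp, _ in rows],
            "clinical_subtype": clin,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    expr = rng.normal(0.0, config.noise_sd, size=(len(all_genes), n))
    row_of = {g: i for i, g in enumerate(all_genes)}
    loadings = {c: activation_loadings(config.signature_sizes[c]) for c in CLASS_ORDER}
    for cls in CLASS_ORDER:
        # zero-mean anti-aligned off-state baseline on every sample
        idx = [row_of[g] for g in gene_names[cls]]
        expr[idx, :] += baseline_profile(config.signature_sizes[cls])[:, None]
    for j, (comp, _kind) in enumerate(rows):
        scale = 1.0 if len(comp) == 1 else config.dual_attenuation
        for cls in comp:
            idx = [row_of[g] for g in gene_names[cls]]
            expr[idx, j] += config.activation_effect * scale * loadings[cls]
    expr_df = pd.DataFrame(expr, index=pd.Index(all_genes, name="gene_id"),
                           columns=sample_ids)
    return expr_df, truth


# -- clinical annotations ---------------------------------------------------

# (mean, sd) of ER% among HR+ samples and of Ki67%, by molecular group kind.
_ER_PARAMS = {
    "luminal_single": (90.0, 8.0),
    "dual_with_luminal": (60.0, 15.0),
    "her2_single": (45.0, 20.0),
    "basal_single": (12.0, 8.0),
    "other": (30.0, 15.0),
}
_KI67_PARAMS = {
    "luminal_single": (18.0, 10.0),
    "dual_with_luminal": (38.0, 12.0),
    "triple": (45.0, 12.0),
    "basal_single": (62.0, 15.0),
    "her2_single": (55.0, 15.0),
    "other": (55.0, 15.0),
}


def _er_group(comp: tuple[str, ...]) -> str:
    if comp == ("Luminal",):
        return "luminal_single"
    if comp == ("Basal",):
        return "basal_single"
    if comp == ("HER2",):
        return "her2_single"
    if "Luminal" in comp:
        return "dual_with_luminal"
    return "other"


def _ki67_group(comp: tuple[str, ...]) -> str:
    if len(comp) == 3:
        return "triple"
    if comp == ("Luminal",):
        return "luminal_single"
    if comp == ("Basal",):
        return "basal_single"
    if comp == ("HER2",):
        return "her2_single"
    if "Luminal" in comp:
        return "dual_with_luminal"
    return "other"


def generate_clinical_annotations(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Draw per-sample clinical records coupled to the planted truth.

    ER%/PR% respect the sample's clinical HR status (HR- samples get <1%),
    and among HR+ samples the class-conditional ER means are ordered
    Luminal-single > Luminal-containing dual > Basal-single.  Ki67% means are
    ordered Luminal-single < Luminal-dual < Basal/HER2-single.  HER2 IHC and
    FISH are drawn consistently with the clinical subtype.  An empty truth
    table yields an empty annotation table.
    """
    cols = ["er_pct", "pr_pct", "ki67_pct", "her2_ihc", "her2_fish",
            "stage", "grade", "therapy"]
    if len(truth) == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    records = []
    for sid, row in truth.iterrows():
        comp = tuple(row["true_components"])
        subtype = row["clinical_subtype"]
        hr_pos = subtype.startswith("HR+")
        her2_pos = subtype.endswith("HER2+")
        if hr_pos:
            mu, sd = _ER_PARAMS[_er_group(comp)]
            er = float(np.clip(rng.normal(mu, sd), 1.0, 100.0))
            pr = float(np.clip(0.7 * er + rng.normal(0.0, 10.0), 0.0, 100.0))
        else:
            er = float(rng.uniform(0.0, 0.99))
            pr = float(rng.uniform(0.0, 0.99))
        mu, sd = _KI67_PARAMS[_ki67_group(comp)]
        ki67 = float(np.clip(rng.normal(mu, sd), 0.0, 100.0))
        if her2_pos:
            if rng.random() < 0.7:
                ihc, fish = "3+", None
            else:
                ihc, fish = "2+", "amplified"
        else:
            ihc = ("0", "1+", "2+")[rng.choice(3, p=[0.5, 0.35, 0.15])]
            fish = "non-amplified" if ihc == "2+" else None
        stage = int(rng.choice([1, 2, 3], p=[0.35, 0.50, 0.15]))
        grade = int(rng.choice([1, 2, 3], p=[0.20, 0.45, 0.35]))
        if her2_pos:
            therapy = "C+T" if rng.random() < 0.5 else "C+T+P"
        else:
            therapy = "C"
        records.append((sid, er, pr, ki67, ihc, fish, stage, grade, therapy))
    out = pd.DataFrame(records, columns=["sample_id"] + cols).set_index("sample_id")
    return out


def generate_pcr_outcomes(
    truth: pd.DataFrame,
    rates: Mapping[str, float],
    seed: int,
) -> pd.Series:
    """Bernoulli pathological-complete-response outcomes per molecular group.

    ``rates`` maps the group label of :func:`truth_group` (e.g.
    ``HER2-single-type``, ``Luminal-HER2-type``) to a response probability.
    Every group present in ``truth`` must have a rate.
    """
    groups = truth["true_label"]
    missing = sorted(set(groups) - set(rates))
    if missing:
        raise ConfigurationError(f"no pCR rate for group(s): {missing}")
    bad = {g: r for g, r in rates.items() if not (0.0 <= r <= 1.0)}
    if bad:
        raise ConfigurationError(f"pCR rates outside [0,1]: {bad}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    p = groups.map(rates).to_numpy(dtype=float)
    draws = rng.random(len(truth))
    return pd.Series((draws < p).astype(int), index=truth.index, name="pcr")


#: Default pCR rates per molecular group: the HER2-single vs Luminal-HER2
#: contrast (0.613 vs 0.238) is the planted study condition; the remaining
#: groups use field-plausible neoadjuvant response rates.
DEFAULT_PCR_RATES: dict[str, float] = {
    "Luminal-single-type": 0.15,
    "Basal-single-type": 0.35,
    "HER2-single-type": 0.613,
    "Luminal-Basal-type": 0.30,
    "Luminal-HER2-type": 0.238,
    "Basal-HER2-type": 0.45,
    "Luminal-Basal-HER2-type": 0.30,
}
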