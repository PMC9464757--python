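"""End-to-end orchestration: simulate/ingest -> score -> dual-classify ->
prevalence -> Burstein -> cohort statistics -> report bundle.

A single configuration mapping (YAML or JSON file, or a dict) drives the run;
there are no hidden defaults outside :class:`PipelineConfig`.  Outputs are
plain CSV/JSON files in the chosen output directory, byte-identical under a
fixed config and seed (the log records the config hash, seed and stage
timings; the report files contain no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import burstein as burstein_mod
from . import cohort_stats as cs
from . import io as dio
from .dual import canonical_label, classify_cohort_dual, fit_difference_thresholds
from .errors import ConfigurationError
from .prevalence import MixtureSpec, estimate_mixture_prevalence
from .scoring import CLASS_ORDER, classify_cohort, train_centroids
from .simulate import (
    DEFAULT_PCR_RATES,
    SimConfig,
    generate_clinical_annotations,
    generate_expression_cohort,
    generate_pcr_outcomes,
    signature_gene_names,
)

logger = logging.getLogger("dualsubtype")


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one pipeline run (documented schema)."""

    simulate: bool = True
    seed: int = 1
    # simulation block (used when simulate=True)
    n_samples: int = 2000
    dual_fraction: float = 0.05
    triple_fraction: float = 0.003
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"Luminal": 0.80, "Basal": 0.12, "HER2": 0.08}
    )
    activation_effect: float = 2.0
    dual_attenuation: float = 0.7
    noise_sd: float = 0.3
    n_background_genes: int = 100
    pcr_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PCR_RATES))
    # ingest block (used when simulate=False)
    expression_path: str | None = None
    clinical_path: str | None = None
    model_path: str | None = None
    # dual classification
    bootstrap_b: int = 1000
    alpha: float = 0.05
    fallback_q: float = 5.0
    min_class_n: int = 50
    use_threshold: bool = True
    use_bootstrap: bool = True
    # prevalence
    mixture_weights: Mapping[str, float] | None = None
    prevalence_n_iter: int = 1000
    prevalence_subset_size: int = 10_000
    # burstein
    run_burstein: bool = True

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        if not cfg.simulate:
            for key in ("expression_path", "model_path"):
                p = getattr(cfg, key)
                if p is None:
                    raise ConfigurationError(f"{key} required when simulate is false")
                if not Path(p).exists():
                    raise ConfigurationError(f"{key}: file not found: {p}")
            if cfg.clinical_path is not None and not Path(cfg.clinical_path).exists():
                raise ConfigurationError(f"clinical_path: file not found: {cfg.clinical_path}")
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Mapping):
                d[k] = dict(v)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    return SimConfig(
        n_samples=cfg.n_samples,
        class_proportions=dict(cfg.class_proportions),
        dual_fraction=cfg.dual_fraction,
        triple_fraction=cfg.triple_fraction,
        activation_effect=cfg.activation_effect,
        dual_attenuation=cfg.dual_attenuation,
        noise_sd=cfg.noise_sd,
        n_background_genes=cfg.n_background_genes,
        seed=cfg.seed,
    )


def run_pipeline(
    config: PipelineConfig | Mapping[str, Any] | str | Path,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage and return the report bundle as a dict.

    ``config`` may be a :class:`PipelineConfig`, a mapping, or a path to a
    YAML/JSON config file.  When ``out_dir`` is given, the call tables,
    thresholds, prevalence report and summary are written there as CSV/JSON.
    """
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_file(config)
    elif isinstance(config, PipelineConfig):
        cfg = config
    else:
        cfg = PipelineConfig.from_mapping(config)
    logger.info("pipeline start: config=%s seed=%d", cfg.digest(), cfg.seed)
    bundle: dict[str, Any] = {"config": cfg.to_dict(), "config_hash": cfg.digest()}
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = time.perf_counter() - self.t0
                logger.info("stage %-12s %.2fs", name, timings[name])
        return _T()

    # -- stage 1: data -------------------------------------------------------
    truth = None
    with stage("data"):
        if cfg.simulate:
            sim = _sim_config(cfg)
            expr, truth = generate_expression_cohort(sim)
            clinical = generate_clinical_annotations(truth, sim)
            clinical["pcr"] = generate_pcr_outcomes(truth, dict(cfg.pcr_rates), cfg.seed)
            labels = truth.loc[truth["true_label_kind"] == "Single", "true_components"]
            model = train_centroids(
                expr, labels.map(lambda c: c[0]), signature_gene_names(sim),
                class_order=CLASS_ORDER,
            )
            clinical_subtype = truth["clinical_subtype"]
        else:
            expr = dio.read_expression_matrix(cfg.expression_path)
            model = dio.read_signature_model(cfg.model_path)
            clinical = (dio.read_clinical_table(cfg.clinical_path)
                        if cfg.clinical_path else None)
            clinical_subtype = None
            if clinical is not None:
                clinical_subtype = pd.Series(
                    {
                        sid: cs.derive_clinical_subtype(
                            row.get("er_pct"), row.get("pr_pct"),
                            row.get("her2_ihc"), row.get("her2_fish"),
                        )
                        for sid, row in clinical.iterrows()
                    },
                    name="clinical_subtype",
                )

    # -- stage 2: scoring + dual classification ------------------------------
    with stage("classify"):
        calls, thresholds = classify_cohort_dual(
            expr, model, B=cfg.bootstrap_b, seed=cfg.seed, alpha=cfg.alpha,
            min_class_n=cfg.min_class_n, fallback_q=cfg.fallback_q,
            use_threshold=cfg.use_threshold, use_bootstrap=cfg.use_bootstrap,
        )

    # -- stage 3: accounting summary -----------------------------------------
    with stage("summary"):
        standard = pd.Series(
            np.where(calls["kind"] == "Single",
                     calls["label"].str.split("-").str[0],
                     calls["components"].str.split("|").str[0]),
            index=calls.index, name="standard_class",
        )
        accounting = {
            "n": int(len(calls)),
            "kind_counts": calls["kind"].value_counts().to_dict(),
            "kind_by_standard": {
                c: calls.loc[standard == c, "kind"].value_counts().to_dict()
                for c in model.classes
            },
            "label_counts": calls["canonical_label"].value_counts().to_dict(),
        }
        bundle["accounting"] = accounting
        if truth is not None:
            planted = truth["true_label_kind"]
            singles = planted == "Single"
            duals = planted == "Dual"
            truth_single_class = truth.loc[singles, "true_components"].map(lambda c: c[0])
            acc = float((standard[singles] == truth_single_class).mean())
            dual_recall = float((calls.loc[duals, "kind"] != "Single").mean()) if duals.any() else None
            false_dual = float((calls.loc[singles, "kind"] != "Single").mean())
            bundle["truth_vs_call"] = {
                "single_standard_accuracy": acc,
                "dual_recall": dual_recall,
                "false_dual_rate_on_singles": false_dual,
            }

    # -- stage 4: prevalence -------------------------------------------------
    with stage("prevalence"):
        if clinical_subtype is not None:
            mix = (MixtureSpec(dict(cfg.mixture_weights))
                   if cfg.mixture_weights else MixtureSpec())
            prev = estimate_mixture_prevalence(
                calls["kind"], clinical_subtype, mix,
                n_iter=cfg.prevalence_n_iter,
                subset_size=cfg.prevalence_subset_size, seed=cfg.seed,
            )
            bundle["prevalence"] = prev.to_dict()

    # -- stage 5: Burstein re-classification of Basal-involved samples -------
    with stage("burstein"):
        if cfg.run_burstein:
            basal_involved = calls.index[
                calls["canonical_label"].isin(["Basal-single-type", "Luminal-Basal-type"])
            ]
            if len(basal_involved) >= 8:
                bmodel = burstein_mod.make_synthetic_burstein_model(seed=cfg.seed)
                rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
                # no measured Burstein panel exists for simulated cohorts;
                # draw panel profiles per sample from a dual-coupled mixture
                # (duals near LAR/MES, singles near BLIA/BLIS) so the
                # association mechanics are exercised end to end.
                genes = list(bmodel.genes[bmodel.classes[0]])
                is_dual = calls.loc[basal_involved, "kind"] != "Single"
                cols = []
                for sid in basal_involved:
                    if bool(is_dual.loc[sid]):
                        cls = ("LAR", "MES")[int(rng.integers(2))]
                    else:
                        cls = ("BLIA", "BLIS")[int(rng.integers(2))]
                    cols.append(bmodel.centroids[cls] + rng.normal(0, 0.3, len(genes)))
                bexpr = pd.DataFrame(
                    np.column_stack(cols), index=pd.Index(genes, name="gene_id"),
                    columns=basal_involved,
                )
                bcalls = burstein_mod.classify_burstein(bexpr, bmodel)
                tab = burstein_mod.crosstab_burstein_vs_dual(
                    bcalls, calls.loc[basal_involved, "canonical_label"])
                stat, df, p = cs.chi_square_test(tab)
                bundle["burstein"] = {
                    "crosstab": {str(k): v for k, v in tab.to_dict(orient="index").items()},
                    "chi_square": {"statistic": stat, "df": df, "p": p},
                    "synthetic_panel": cfg.simulate,
                }

    # -- stage 6: clinical statistics ----------------------------------------
    with stage("stats"):
        if clinical is not None:
            bundle["stats"] = _clinical_stats(calls, clinical)

    bundle["timings_s"] = {k: round(v, 3) for k, v in timings.items()}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        calls.to_csv(out / "dual_calls.csv")
        thresholds.to_json(out / "thresholds.json")
        report = {k: v for k, v in bundle.items() if k != "timings_s"}
        (out / "summary.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                     default=_jsonable))
        logger.info("wrote report bundle to %s", out)
    bundle["calls"] = calls
    bundle["thresholds"] = thresholds
    return bundle


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _clinical_stats(calls: pd.DataFrame, clinical: pd.DataFrame) -> dict:
    """The cohort contrasts: ER/Ki67 t-tests, Ki67<30 chi-square, pCR."""
    merged = calls.join(clinical, how="inner")
    out: dict[str, Any] = {}

    def group(label):
        return merged[merged["canonical_label"] == label]

    lum, bas = group("Luminal-single-type"), group("Basal-single-type")
    lb = group("Luminal-Basal-type")
    if len(lum) >= 2 and len(lb) >= 2 and len(bas) >= 2:
        t1 = cs.welch_t_test(lb["ki67_pct"].dropna(), lum["ki67_pct"].dropna())
        t2 = cs.welch_t_test(lb["ki67_pct"].dropna(), bas["ki67_pct"].dropna())
        out["ki67_luminal_basal_vs_luminal_single"] = dict(zip(("t", "df", "p"), t1))
        out["ki67_luminal_basal_vs_basal_single"] = dict(zip(("t", "df", "p"), t2))
        ter = cs.welch_t_test(lum["er_pct"].dropna(), lb["er_pct"].dropna())
        out["er_luminal_single_vs_luminal_basal"] = dict(zip(("t", "df", "p"), ter))
        low_lb = int((lb["ki67_pct"] < cs.KI67_TNLP_THRESHOLD).sum())
        low_bas = int((bas["ki67_pct"] < cs.KI67_TNLP_THRESHOLD).sum())
        table = [[low_lb, len(lb) - low_lb], [low_bas, len(bas) - low_bas]]
        try:
            stat, df, p = cs.chi_square_test(table)
            out["ki67_tnlp_chi_square"] = {
                "table": table, "statistic": stat, "df": df, "p": p,
                "luminal_basal_low": cs.proportion_with_ci(low_lb, len(lb))["pct"],
                "basal_single_low": cs.proportion_with_ci(low_bas, len(bas))["pct"],
            }
        except Exception as exc:  # degenerate small-cohort table
            out["ki67_tnlp_chi_square"] = {"error": str(exc)}

    if "pcr" in merged.columns:
        her2_single = group("HER2-single-type")
        lh = group("Luminal-HER2-type")
        if len(her2_single) >= 2 and len(lh) >= 2:
            k1, n1 = int(her2_single["pcr"].sum()), int(her2_single["pcr"].notna().sum())
            k2, n2 = int(lh["pcr"].sum()), int(lh["pcr"].notna().sum())
            out["pcr_her2_single_pct"] = cs.proportion_with_ci(k1, n1)["pct"]
            out["pcr_luminal_her2_pct"] = cs.proportion_with_ci(k2, n2)["pct"]
            table = [[k1, n1 - k1], [k2, n2 - k2]]
            try:
                stat, df, p = cs.chi_square_test(table)
                out["pcr_chi_square"] = {"statistic": stat, "df": df, "p": p}
            except Exception as exc:
                out["pcr_chi_square"] = {"error": str(exc)}
            # multivariate logistic: dual vs HER2-single adjusted for HR,
            # stage, grade and therapy
            sub = pd.concat([her2_single, lh])
            design = pd.DataFrame(index=sub.index)
            design["luminal_her2"] = (sub["canonical_label"] == "Luminal-HER2-type").astype(float)
            design["hr_pos"] = (sub["er_pct"].fillna(0) >= 1.0) | (sub["pr_pct"].fillna(0) >= 1.0)
            design["hr_pos"] = design["hr_pos"].astype(float)
            design["stage"] = sub["stage"].astype(float)
            design["grade"] = sub["grade"].astype(float)
            design["therapy_tp"] = (sub["therapy"] == "C+T+P").astype(float)
            design = design.loc[:, design.nunique() > 1]
            try:
                fit = cs.logistic_fit(design, sub["pcr"].astype(int))
                out["pcr_logistic"] = {
                    name: {"coef": float(r["coef"]), "se": float(r["se"]),
                           "p": float(r["p"])}
                    for name, r in fit.table.iterrows()
                }
            except Exception as exc:
                out["pcr_logistic"] = {"error": str(exc)}
    return out
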