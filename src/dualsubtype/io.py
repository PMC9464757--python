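"""Reading and writing the pipeline's plain-text formats.

Expression matrices travel as TSV (genes as rows, header row of sample ids),
clinical tables as CSV with a fixed column schema, signature models as JSON.
Readers validate identifiers, numeric cells and clinical ranges and raise
:class:`~dualsubtype.errors.SchemaError` naming the offending entry; writers
produce files whose write -> read round trip is the identity (float values to
full precision, identifiers exact).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .scoring import SignatureModel

CLINICAL_COLUMNS = [
    "er_pct", "pr_pct", "ki67_pct", "her2_ihc", "her2_fish",
    "stage", "grade", "therapy",
]
_PCT_COLUMNS = ("er_pct", "pr_pct", "ki67_pct")
_IHC_VALUES = {"0", "1+", "2+", "3+"}
_FISH_VALUES = {"amplified", "non-amplified"}


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    expr.rename_axis("gene_id").to_csv(path, sep="\t")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV; duplicate ids or non-numeric cells error."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SchemaError(f"{path}: {exc}") from exc
    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise SchemaError(f"{path}: duplicate gene id(s): {dup_genes[:5]}")
    dup_samples = [c for c in df.columns if c.endswith(".1")
                   and c[:-2] in set(df.columns)]
    if df.columns.duplicated().any() or dup_samples:
        dups = df.columns[df.columns.duplicated()].unique().tolist() or [
            c[:-2] for c in dup_samples]
        raise SchemaError(f"{path}: duplicate sample id(s): {dups[:5]}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value for sample {col!r} at gene(s) "
                f"{bad.tolist()[:5]}"
            )
        df[col] = coerced
    df.index.name = "gene_id"
    return df


def write_clinical_table(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.rename_axis("sample_id").to_csv(path)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a clinical CSV (schema: sample_id + fixed columns)."""
    df = pd.read_csv(path, index_col="sample_id",
                     dtype={"her2_ihc": "string", "her2_fish": "string"})
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise SchemaError(f"{path}: duplicate sample id(s): {dup[:5]}")
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing column(s): {missing_cols}")
    for col in _PCT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.notna() & ((vals < 0) | (vals > 100))]
        if len(bad):
            raise SchemaError(
                f"{path}: {col} outside [0,100] for sample(s) {bad.tolist()[:5]}"
            )
        df[col] = vals
    bad_ihc = df.index[df["her2_ihc"].notna() & ~df["her2_ihc"].isin(_IHC_VALUES)]
    if len(bad_ihc):
        raise SchemaError(f"{path}: invalid her2_ihc for sample(s) {bad_ihc.tolist()[:5]}")
    bad_fish = df.index[df["her2_fish"].notna() & ~df["her2_fish"].isin(_FISH_VALUES)]
    if len(bad_fish):
        raise SchemaError(f"{path}: invalid her2_fish for sample(s) {bad_fish.tolist()[:5]}")
    return df


def write_signature_model(model: SignatureModel, path: str | Path) -> None:
    model.to_json(path)


def read_signature_model(path: str | Path) -> SignatureModel:
    try:
        return SignatureModel.from_json(path)
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"{path}: invalid signature model ({exc})") from exc


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    out = truth.copy()
    out["true_components"] = ["|".join(c) for c in out["true_components"]]
    out.rename_axis("sample_id").to_csv(path)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    df["true_components"] = [tuple(str(c).split("|")) for c in df["true_components"]]
    return df
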