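"""Cohort schema, file I/O, the omega mutation score, and model-bundle persistence.

The pipeline's universal currency is the *feature table*: a pandas
DataFrame with one row per blood sample carrying 39 plasma protein
biomarker concentrations, three demographics (age, sex, ethnicity), the
cfDNA-mutation omega score, and a multi-class label.  Missing biomarker
cells are encoded as NaN; imputation is an explicit pipeline stage
(:func:`oncocascade.synthetic_cohort.impute_knn`), never performed at
load time.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd

__all__ = [
    "BIOMARKERS",
    "DEMOGRAPHICS",
    "FEATURES",
    "LABELS",
    "MERGED_LABELS",
    "CANCER_LABELS",
    "SEXES",
    "ETHNICITIES",
    "OMEGA",
    "LABEL",
    "SAMPLE_ID",
    "CHEAP_ASSAYS",
    "SchemaError",
    "ParseError",
    "DomainError",
    "BundleError",
    "normalize_marker_name",
    "validate_feature_table",
    "load_feature_table",
    "write_feature_table",
    "encode_features",
    "compute_omega_score",
    "save_bundle",
    "load_bundle",
]

#: The 39-plasma-protein panel (canonical spellings; see
#: :func:`normalize_marker_name` for accepted dialects).
BIOMARKERS: tuple[str, ...] = (
    "AFP",
    "Angiopoietin-2",
    "AXL",
    "CA 15-3",
    "CA-125",
    "CA19-9",
    "CD44",
    "CEA",
    "CYFRA 21-1",
    "DKK1",
    "Endoglin",
    "FGF2",
    "Follistatin",
    "G-CSF",
    "Galectin-3",
    "GDF15",
    "HE4",
    "HGF",
    "IL-6",
    "IL-8",
    "Kallikrein-6",
    "Leptin",
    "Mesothelin",
    "Midkine",
    "Myeloperoxidase",
    "NSE",
    "OPG",
    "OPN",
    "PAR",
    "Prolactin",
    "SHBG",
    "sEGFR",
    "sFas",
    "sHER2/sEGFR2/sErbB2",
    "sPECAM-1",
    "TGFa",
    "Thrombospondin-2",
    "TIMP-1",
    "TIMP-2",
)

DEMOGRAPHICS: tuple[str, ...] = ("age", "sex", "ethnicity")
OMEGA = "omega_score"
LABEL = "label"
SAMPLE_ID = "sample_id"

#: The 43 model features, in canonical column order.
FEATURES: tuple[str, ...] = BIOMARKERS + DEMOGRAPHICS + (OMEGA,)

#: Raw 9-class label vocabulary (before the upper-GI merge).
LABELS: tuple[str, ...] = (
    "Normal",
    "Colorectum",
    "Breast",
    "Esophagus",
    "Stomach",
    "Lung",
    "Pancreas",
    "Ovary",
    "Liver",
)

#: 8-class vocabulary after merging esophageal + gastric into upper GI.
MERGED_LABELS: tuple[str, ...] = (
    "Normal",
    "Colorectum",
    "Breast",
    "UpperGI",
    "Lung",
    "Pancreas",
    "Ovary",
    "Liver",
)
CANCER_LABELS: tuple[str, ...] = tuple(l for l in MERGED_LABELS if l != "Normal")

SEXES: tuple[str, ...] = ("female", "male")
ETHNICITIES: tuple[str, ...] = ("Caucasian", "Asian", "Black", "Hispanic", "Other")

#: Assays routinely run in clinical labs at ~$2 each; all other panel
#: members cost ~$5.5, and every assay takes ~2.5 h of lab time.
CHEAP_ASSAYS: frozenset[str] = frozenset(
    {"AFP", "CA19-9", "CA-125", "CEA", "Prolactin", "CA 15-3"}
)

_MISSING_SENTINELS = {"", "na", "nan", "n/a", "none", "null", "missing", "?"}


class SchemaError(ValueError):
    """A required column is absent or a vocabulary is violated."""


class ParseError(ValueError):
    """A cell could not be interpreted as a number or known sentinel."""


class DomainError(ValueError):
    """An input value lies outside its mathematical domain."""


class BundleError(RuntimeError):
    """A persisted model bundle is missing or incompatible."""


# ---------------------------------------------------------------------------
# column-name normalization


def _marker_key(name: str) -> str:
    # en/em dashes and figure dashes appear in published marker tables
    for dash in ("–", "—", "‒", "−"):
        name = name.replace(dash, "-")
    return "".join(name.split()).lower()


_CANONICAL_BY_KEY: dict[str, str] = {_marker_key(m): m for m in BIOMARKERS}
# common spelling dialects (spaces vs hyphens around CA antigen numbers)
for _alias, _canon in {
    "ca 19-9": "CA19-9",
    "ca-19-9": "CA19-9",
    "ca 125": "CA-125",
    "ca125": "CA-125",
    "ca15-3": "CA 15-3",
    "omega score": OMEGA,
    "omegascore": OMEGA,
    "gender": "sex",
    "ethonic": "ethnicity",  # spelling used in some published feature lists
    "race": "ethnicity",
}.items():
    _CANONICAL_BY_KEY[_marker_key(_alias)] = _canon


def normalize_marker_name(name: str) -> str:
    """Map a column-name dialect (dash variants, spacing, case) to its
    canonical spelling.  Unknown names are returned stripped but unchanged."""
    return _CANONICAL_BY_KEY.get(_marker_key(name), name.strip())


# ---------------------------------------------------------------------------
# feature-table validation and I/O


def _coerce_numeric(series: pd.Series, column: str) -> pd.Series:
    """Parse a column to float, mapping known missing sentinels to NaN and
    raising :class:`ParseError` (with the row index) on anything else."""
    if pd.api.types.is_numeric_dtype(series):
        return series.astype(float)
    cleaned = series.astype(object).where(series.notna(), np.nan)
    mask = cleaned.apply(
        lambda v: isinstance(v, str) and v.strip().lower() in _MISSING_SENTINELS
    )
    cleaned[mask] = np.nan
    parsed = pd.to_numeric(cleaned, errors="coerce")
    bad = parsed.isna() & cleaned.notna()
    if bad.any():
        row = bad[bad].index[0]
        raise ParseError(
            f"non-numeric value {series[row]!r} in column {column!r} at row {row}"
        )
    return parsed.astype(float)


def validate_feature_table(df: pd.DataFrame, *, drop_unknown_labels: bool = True) -> pd.DataFrame:
    """Validate and canonicalize a feature table.

    Column names are normalized, numeric columns parsed (missing-value
    sentinels become NaN), categorical vocabularies enforced, and a load
    report attached under ``df.attrs['report']`` (counts of missing cells
    and of rejected unknown-label rows).
    """
    df = df.rename(columns=normalize_marker_name)
    missing_cols = [c for c in (*FEATURES, LABEL) if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required columns: {missing_cols}")
    if SAMPLE_ID not in df.columns:
        df = df.copy()
        df.insert(0, SAMPLE_ID, [f"S{i:05d}" for i in range(len(df))])
    if df[SAMPLE_ID].duplicated().any():
        dup = df[SAMPLE_ID][df[SAMPLE_ID].duplicated()].iloc[0]
        raise SchemaError(f"duplicate sample_id {dup!r}")

    out = df.loc[:, [SAMPLE_ID, *FEATURES, LABEL]].copy()
    n_missing = 0
    for col in (*BIOMARKERS, "age", OMEGA):
        out[col] = _coerce_numeric(out[col], col)
        if col in BIOMARKERS:
            n_missing += int(out[col].isna().sum())
            neg = out[col] < 0
            if neg.any():
                raise DomainError(
                    f"negative concentration in {col!r} at row {neg[neg].index[0]}"
                )
    for col, vocab in ((("sex"), SEXES), (("ethnicity"), ETHNICITIES)):
        vals = out[col].astype(str).str.strip()
        vals = vals.str.capitalize() if col == "ethnicity" else vals.str.lower()
        unknown = ~vals.isin(vocab)
        if unknown.any():
            raise SchemaError(
                f"unknown {col} value {out[col][unknown].iloc[0]!r}; expected one of {vocab}"
            )
        out[col] = pd.Categorical(vals, categories=vocab)

    labels = out[LABEL].astype(str).str.strip()
    known = labels.isin(LABELS) | labels.isin(MERGED_LABELS)
    n_rejected = int((~known).sum())
    if n_rejected:
        if not drop_unknown_labels:
            raise SchemaError(f"unknown labels: {sorted(labels[~known].unique())}")
        warnings.warn(
            f"rejected {n_rejected} rows with unknown labels "
            f"{sorted(labels[~known].unique())}",
            stacklevel=2,
        )
        out = out.loc[known].reset_index(drop=True)
        labels = labels.loc[known].reset_index(drop=True)
    vocab = LABELS if labels.isin(LABELS).all() else MERGED_LABELS
    out[LABEL] = pd.Categorical(labels, categories=vocab)
    out.attrs["report"] = {"missing_biomarker_cells": n_missing, "rejected_rows": n_rejected}
    return out


def load_feature_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a CSV/TSV cohort file and return a validated feature table.

    Parameters
    ----------
    path
        File with a header row; ``.tsv`` files are tab-separated.
    schema
        Optional map from file column names to schema roles (e.g.
        ``{"diagnosis": "label"}``) applied before validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=object)
    if schema:
        raw = raw.rename(columns=dict(schema))
    return validate_feature_table(raw)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table to CSV/TSV at full precision."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table.to_csv(path, sep=sep, index=False)


def encode_features(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix for selectors and classifiers.

    sex -> {female: 0, male: 1}; ethnicity -> integer codes in vocabulary
    order.  The encoding is recorded in bundle manifests so persisted
    models stay interpretable.
    """
    X = table[list(FEATURES)].copy()
    X["sex"] = pd.Categorical(table["sex"], categories=SEXES).codes.astype(float)
    X["ethnicity"] = pd.Categorical(table["ethnicity"], categories=ETHNICITIES).codes.astype(float)
    return X.astype(float)


# ---------------------------------------------------------------------------
# omega score


def compute_omega_score(
    uid_counts: Sequence[float],
    p_cancer: Sequence[float],
    p_normal: Sequence[float],
) -> float:
    r"""Weighted log p-value ratio of mutant-allele-frequency evidence.

    For wells ``i = 1..w`` with unique-identifier (UID) template counts
    ``u_i`` and per-well p-values under the cancer and normal MAF
    distributions,

    .. math:: \Omega = \sum_i \frac{u_i}{\sum_j u_j}\,
              \ln\frac{p_i^C}{p_i^N}.

    The score is invariant to uniform rescaling of the UID counts and
    antisymmetric under swapping the two p-value vectors.
    """
    u = np.asarray(uid_counts, dtype=float)
    pc = np.asarray(p_cancer, dtype=float)
    pn = np.asarray(p_normal, dtype=float)
    if u.size == 0:
        raise DomainError("omega score needs at least one well")
    if u.shape != pc.shape or u.shape != pn.shape:
        raise DomainError("uid_counts, p_cancer, p_normal must have equal length")
    if (u < 0).any():
        raise DomainError("UID counts must be non-negative")
    total = u.sum()
    if total <= 0:
        raise DomainError("total UID count is zero")
    if (pc <= 0).any() or (pn <= 0).any():
        raise DomainError("p-values must be strictly positive")
    return float(np.sum(u / total * np.log(pc / pn)))


# ---------------------------------------------------------------------------
# bundle persistence

BUNDLE_FORMAT_VERSION = 1


def save_bundle(
    path: str | Path,
    *,
    models: Mapping[int, object] | None = None,
    tallies: Mapping[int, object] | None = None,
    reports: Mapping[str, object] | None = None,
    metadata: Mapping[str, object] | None = None,
) -> Path:
    """Persist trained per-level models, vote tallies and reports to a
    directory with a JSON manifest.  Returns the bundle path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "levels": sorted(models) if models else [],
        "encodings": {"sex": dict(zip(SEXES, range(2))),
                      "ethnicity": dict(zip(ETHNICITIES, range(5)))},
        "metadata": dict(metadata or {}),
    }
    if models:
        joblib.dump(dict(models), path / "models.joblib")
    if tallies is not None:
        joblib.dump(dict(tallies), path / "tallies.joblib")
    if reports is not None:
        joblib.dump(dict(reports), path / "reports.joblib")
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_bundle(path: str | Path) -> dict:
    """Load a bundle saved by :func:`save_bundle`.

    Raises :class:`BundleError` on a missing manifest or a format-version
    mismatch.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise BundleError(f"no bundle manifest found at {path}")
    manifest = json.loads(manifest_path.read_text())
    version = manifest.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise BundleError(
            f"bundle format version {version} incompatible with {BUNDLE_FORMAT_VERSION}"
        )
    out = {"manifest": manifest}
    for name in ("models", "tallies", "reports"):
        f = path / f"{name}.joblib"
        out[name] = joblib.load(f) if f.exists() else None
    return out
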