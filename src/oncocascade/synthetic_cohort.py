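"""Synthetic liquid-biopsy cohorts with known ground truth.

Generates feature tables structurally shaped like the public multi-cancer
cohort the cascade targets: 1,817 samples across Normal plus seven cancer
classes, right-skewed non-negative biomarker concentrations (log-normal),
class-specific multiplicative shifts on *planted* informative markers,
demographics drawn from cohort-like marginals, and an omega score computed
from simulated sequencing wells.  Because the planted markers are known,
every downstream stage (selection, cascade training, evaluation) is
testable offline.

No attempt is made to match the real cohort's marginal concentration
distributions; only its structure (skew, non-negativity, class shifts,
class counts) is emulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .data_io import (
    BIOMARKERS,
    ETHNICITIES,
    FEATURES,
    LABEL,
    OMEGA,
    SAMPLE_ID,
    SEXES,
    DomainError,
    compute_omega_score,
    validate_feature_table,
)

__all__ = [
    "CohortConfig",
    "DEFAULT_CLASS_SIZES",
    "DEFAULT_INFORMATIVE_MAP",
    "generate_cohort",
    "inject_missingness",
    "impute_knn",
]

#: Default class counts: the published cohort's composition.
DEFAULT_CLASS_SIZES: dict[str, int] = {
    "Normal": 812,
    "Colorectum": 388,
    "Breast": 209,
    "UpperGI": 113,
    "Lung": 104,
    "Pancreas": 93,
    "Ovary": 54,
    "Liver": 44,
}

#: Five planted informative markers per cancer class (effect size in units
#: of the log-scale dispersion).  Marker choices follow clinical
#: associations (CEA/CA19-9 colorectal & GI, CA-125/HE4 ovarian, AFP
#: hepatic, CA 15-3/sHER2 breast, CYFRA 21-1/NSE lung) so synthetic runs
#: read plausibly, but nothing downstream depends on which markers are
#: planted.
DEFAULT_INFORMATIVE_MAP: dict[str, dict[str, float]] = {
    "Colorectum": {"CEA": 1.0, "CA19-9": 1.0, "TIMP-1": 1.0, "OPN": 1.0, "IL-8": 1.0},
    "Breast": {"CA 15-3": 1.0, "sHER2/sEGFR2/sErbB2": 1.0, "Prolactin": 1.0, "HE4": 1.0, "Midkine": 1.0},
    "UpperGI": {"Leptin": 1.0, "CA19-9": 1.0, "TIMP-2": 1.0, "Galectin-3": 1.0, "Mesothelin": 1.0},
    "Lung": {"CYFRA 21-1": 1.0, "NSE": 1.0, "IL-6": 1.0, "GDF15": 1.0, "sFas": 1.0},
    "Pancreas": {"CA19-9": 1.0, "Midkine": 1.0, "AXL": 1.0, "G-CSF": 1.0, "CEA": 1.0},
    "Ovary": {"CA-125": 1.0, "HE4": 1.0, "Follistatin": 1.0, "Kallikrein-6": 1.0, "Endoglin": 1.0},
    "Liver": {"AFP": 1.0, "OPG": 1.0, "HGF": 1.0, "Angiopoietin-2": 1.0, "DKK1": 1.0},
}

# demographic marginals shaped like the source cohort's summary table
_SEX_P_FEMALE = {"cancer": 543 / 1005, "normal": 378 / 812}
_ETHNICITY_P = {
    "cancer": np.array([675, 301, 14, 1, 14], dtype=float) / 1005,
    "normal": np.array([332, 22, 154, 76, 228], dtype=float) / 812,
}
_AGE = {"cancer": (63, 13.0, 22, 93), "normal": (49, 16.0, 17, 88)}


@dataclass
class CohortConfig:
    """Ground-truth parameterization of a synthetic cohort.

    Parameters
    ----------
    class_sizes
        Exact per-class row counts (not stochastic).
    informative_map
        label -> {marker: effect size}; each effect shifts that marker's
        log-scale location by ``effect * noise_sd`` for rows of that class.
    noise_sd
        Log-scale dispersion of every biomarker (1.0 gives realistic
        right skew for assay concentrations).
    omega_effect
        Mean of the exponential depression applied to cancer rows'
        normal-model well p-values; raises Ω for cancer in expectation.
    n_wells
        Sequencing wells simulated per sample.
    seed
        Fully determines the generated table.
    """

    class_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    informative_map: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INFORMATIVE_MAP.items()}
    )
    noise_sd: float = 1.0
    omega_effect: float = 1.5
    n_wells: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.class_sizes.items():
            if n < 0:
                raise DomainError(f"negative count {n} for class {label!r}")
        for label, markers in self.informative_map.items():
            for m, e in markers.items():
                if m not in BIOMARKERS:
                    raise DomainError(f"unknown biomarker {m!r} in informative_map")
                if not np.isfinite(e):
                    raise DomainError(f"non-finite effect size for {m!r}")
        if self.noise_sd <= 0:
            raise DomainError("noise_sd must be positive")

    def planted_features(self) -> dict[str, list[str]]:
        """Ground-truth sidecar: planted markers per class."""
        return {k: sorted(v) for k, v in self.informative_map.items()}


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort; see :class:`CohortConfig`.

    Biomarker concentrations are log-normal with per-marker baseline
    locations spread over a seeded range (so marker scales differ, as in
    real assay panels).  The omega score is computed per sample from
    simulated wells via :func:`oncocascade.data_io.compute_omega_score`:
    for cancer rows the well p-values under the normal MAF distribution
    are stochastically depressed, so Ω > 0 in expectation for cancer.
    """
    config = config or CohortConfig()
    active = {k: v for k, v in config.class_sizes.items() if v > 0}
    dropped = sorted(set(config.class_sizes) - set(active))
    if dropped:
        warnings.warn(f"dropping zero-count classes: {dropped}", stacklevel=2)
    if len(active) < 2:
        raise DomainError("need at least 2 classes with nonzero counts")

    rng = np.random.default_rng(config.seed)
    # per-marker baseline log-locations; fixed draw so scales are marker-specific
    base_mu = rng.uniform(0.0, 4.0, size=len(BIOMARKERS))

    labels = np.repeat(list(active), list(active.values()))
    n = labels.size
    is_cancer = labels != "Normal"

    # biomarkers: lognormal(base + planted shift, noise_sd)
    mu = np.tile(base_mu, (n, 1))
    marker_idx = {m: j for j, m in enumerate(BIOMARKERS)}
    for label, markers in config.informative_map.items():
        rows = labels == label
        if not rows.any():
            continue
        for m, effect in markers.items():
            mu[rows, marker_idx[m]] += effect * config.noise_sd
    conc = rng.lognormal(mean=mu, sigma=config.noise_sd)

    # demographics
    age = np.empty(n)
    sex = np.empty(n, dtype=object)
    eth = np.empty(n, dtype=object)
    for group, rows in (("cancer", is_cancer), ("normal", ~is_cancer)):
        k = int(rows.sum())
        mean, sd, lo, hi = _AGE[group]
        age[rows] = np.clip(np.round(rng.normal(mean, sd, k)), lo, hi)
        sex[rows] = np.where(rng.random(k) < _SEX_P_FEMALE[group], "female", "male")
        eth[rows] = rng.choice(ETHNICITIES, size=k, p=_ETHNICITY_P[group])
    # gynecological cancers occur in females
    sex[labels == "Ovary"] = "female"
    sex[(labels == "Breast") & (rng.random(n) < 0.99)] = "female"

    # omega score from simulated wells
    omega = np.empty(n)
    for i in range(n):
        uid = rng.integers(50, 150, size=config.n_wells)
        p_cancer = rng.uniform(0.2, 1.0, size=config.n_wells)
        p_normal = rng.uniform(0.2, 1.0, size=config.n_wells)
        if is_cancer[i]:
            p_normal = np.maximum(
                p_normal * np.exp(-rng.exponential(config.omega_effect, size=config.n_wells)),
                1e-6,
            )
        omega[i] = compute_omega_score(uid, p_cancer, p_normal)

    table = pd.DataFrame(conc, columns=list(BIOMARKERS))
    table["age"] = age
    table["sex"] = sex
    table["ethnicity"] = eth
    table[OMEGA] = omega
    table[LABEL] = labels
    table.insert(0, SAMPLE_ID, [f"SYN{i:05d}" for i in range(n)])
    return validate_feature_table(table)


def inject_missingness(table: pd.DataFrame, rate: float, seed: int = 0) -> pd.DataFrame:
    """Flag each biomarker cell missing (NaN) independently with
    probability ``rate`` — missing completely at random.  Demographics,
    omega score and labels are untouched."""
    if not 0 <= rate < 1:
        raise DomainError(f"missingness rate must be in [0, 1); got {rate}")
    out = table.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random((len(table), len(BIOMARKERS))) < rate
    values = out[list(BIOMARKERS)].to_numpy(dtype=float)
    values[mask] = np.nan
    out[list(BIOMARKERS)] = values
    return out


def impute_knn(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Replace missing biomarker cells by the mean of the feature over the
    ``k`` nearest rows (Euclidean distance on standardized observed
    features, mutually-missing coordinates ignored).

    Observed cells are never altered.  Raises :class:`DomainError` if a
    biomarker is missing in every row (no donor values exist).
    """
    if k < 1:
        raise DomainError("k must be >= 1")
    cols = list(BIOMARKERS)
    values = table[cols].to_numpy(dtype=float)
    all_missing = np.isnan(values).all(axis=0)
    if all_missing.any():
        name = cols[int(np.flatnonzero(all_missing)[0])]
        raise DomainError(f"feature {name!r} is missing in all rows; cannot impute")
    out = table.copy()
    if not np.isnan(values).any():
        return out
    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0)
    sd[sd == 0] = 1.0
    z = (values - mean) / sd
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    z_imputed = imputer.fit_transform(z)
    imputed = z_imputed * sd + mean
    # guarantee observed cells are bit-identical
    observed = ~np.isnan(values)
    imputed[observed] = values[observed]
    out[cols] = imputed
    return out
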