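import numpy as np
import pandas as pd
import pytest

from oncocascade.data_io import BIOMARKERS, LABEL, encode_features
from oncocascade.synthetic_cohort import CohortConfig, generate_cohort

#: quarter-scale class counts keep per-test work light while preserving the
#: cohort's imbalance structure
SMALL_SIZES = {
    "Normal": 203,
    "Colorectum": 97,
    "Breast": 52,
    "UpperGI": 28,
    "Lung": 26,
    "Pancreas": 23,
    "Ovary": 14,
    "Liver": 11,
}


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return generate_cohort(CohortConfig(class_sizes=SMALL_SIZES, seed=7))


@pytest.fixture(scope="session")
def small_encoded(small_cohort):
    X = encode_features(small_cohort)
    y = small_cohort[LABEL].astype(str).to_numpy()
    return X, y


@pytest.fixture(scope="session")
def planted_binary():
    """Binary selection problem with known informative features.

    12 features, 4 informative with a 1.5-sd mean shift in the positive
    class, 300 rows per class.
    """
    rng = np.random.default_rng(42)
    n = 300
    X = pd.DataFrame(
        rng.normal(size=(2 * n, 12)), columns=[f"f{i:02d}" for i in range(12)]
    )
    informative = ["f00", "f03", "f07", "f11"]
    y = np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)]
    X.loc[y == 1, informative] += 1.5
    X -= X.min().min()  # keep all features non-negative, like assay data
    return X, y, informative
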