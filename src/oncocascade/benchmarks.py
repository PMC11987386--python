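"""Published reference metric tables for the multi-level system.

These are the per-level evaluation results published with the multi-level
liquid-biopsy cancer classification study this package implements, bundled
as data: they are the inputs to the cross-level aggregation and the
rank-based method comparison (the metaheuristic selector baselines — EVO,
FLA, FOX, RIME — are consumed as metric tables only; the optimizers
themselves are out of scope).

All tables have one row per cascade level and the seven standard metric
columns (``Acc, Precision, Recall, F1, Specificity, BA, AUC``); threshold
and baseline tables carry the selected-feature count ``n_selected`` too.
Values are fractions in [0, 1] exactly as published.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "METRIC_COLUMNS",
    "LEVEL_NAMES",
    "level_test_metrics",
    "threshold_study",
    "baseline_selector_metrics",
    "missingness_metrics",
    "accuracy_matrix",
]

METRIC_COLUMNS = ("Acc", "Precision", "Recall", "F1", "Specificity", "BA", "AUC")

LEVEL_NAMES = (
    "Normal vs Cancer",
    "Colorectum vs Other",
    "Breast vs Other",
    "UpperGI vs Other",
    "Lung vs Other",
    "Pancreas vs Other",
    "Ovary vs Liver",
)


def _table(rows, n_selected=None) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(METRIC_COLUMNS),
                      index=pd.RangeIndex(1, 8, name="level"))
    if n_selected is not None:
        df.insert(0, "n_selected", n_selected)
    return df


def level_test_metrics() -> pd.DataFrame:
    """Held-out test metrics per level for the majority-vote system
    (selection threshold 3)."""
    return _table(
        [
            [1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000],
            [0.8812, 0.8906, 0.9194, 0.9048, 0.8205, 0.8699, 0.9421],
            [0.9355, 0.9512, 0.9512, 0.9512, 0.9048, 0.9280, 0.9628],
            [0.9512, 1.0000, 0.8182, 0.9000, 1.0000, 0.9091, 0.9788],
            [0.9667, 1.0000, 0.9474, 0.9730, 1.0000, 0.9737, 0.9904],
            [1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000],
            [1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000],
        ],
        n_selected=[24, 24, 23, 25, 22, 24, 24],
    )


def threshold_study(threshold: int) -> pd.DataFrame:
    """Per-level test metrics with the vote threshold set to 2 or 4
    (3 is the deployed default; see :func:`level_test_metrics`)."""
    if threshold == 3:
        return level_test_metrics()
    if threshold == 2:
        return _table(
            [
                [1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000],
                [0.8911, 0.9048, 0.9194, 0.9120, 0.8462, 0.8828, 0.9400],
                [0.9355, 0.9512, 0.9512, 0.9512, 0.9048, 0.9280, 0.9652],
                [0.9268, 1.0000, 0.7273, 0.8421, 1.0000, 0.8636, 0.9667],
                [0.9333, 0.9474, 0.9474, 0.9474, 0.9091, 0.9282, 0.9856],
                [0.8000, 0.8750, 0.7000, 0.7778, 0.9000, 0.8000, 0.9700],
                [1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000],
            ],
            n_selected=[28, 27, 33, 31, 31, 32, 28],
        )
    if threshold == 4:
        return _table(
            [
                [0.9945, 1.0000, 0.9901, 0.9951, 1.0000, 1.0000, 1.0000],
                [0.8515, 0.8730, 0.8871, 0.8800, 0.7949, 0.8410, 0.9218],
                [0.8548, 0.9211, 0.9211, 0.8861, 0.8571, 0.8554, 0.9384],
                [0.9024, 0.8889, 0.7273, 0.8000, 0.9667, 0.8470, 0.9394],
                [0.9667, 1.0000, 0.9474, 0.9730, 1.0000, 0.9737, 0.9856],
                [0.9500, 1.0000, 0.9000, 0.9474, 1.0000, 0.9500, 0.9900],
                [1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000],
            ],
            n_selected=[20, 21, 17, 18, 15, 17, 21],
        )
    raise KeyError(f"no threshold study published for threshold {threshold}")


def baseline_selector_metrics() -> dict[str, pd.DataFrame]:
    """Per-level test metrics of the four metaheuristic feature-selection
    baselines (EVO, FLA, FOX, RIME) under the same cascade and models."""
    return {
        "EVO": _table(
            [
                [0.9780, 0.9899, 0.9703, 0.9800, 0.9877, 0.9790, 0.9978],
                [0.8218, 0.8548, 0.8548, 0.8548, 0.7692, 0.8120, 0.9289],
                [0.9194, 0.9286, 0.9512, 0.9398, 0.8571, 0.9042, 0.9663],
                [0.9024, 0.8889, 0.7273, 0.8000, 0.9667, 0.8470, 0.9515],
                [0.8000, 0.8824, 0.7895, 0.8333, 0.8182, 0.8038, 0.9282],
                [0.8000, 0.7143, 1.0000, 0.8333, 0.6000, 0.8000, 0.9700],
                [1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000],
            ],
            n_selected=[22, 27, 21, 15, 22, 17, 19],
        ),
        "FLA": _table(
            [
                [0.9835, 0.9712, 1.0000, 0.9854, 0.9630, 0.9815, 0.9996],
                [0.8515, 0.8852, 0.8710, 0.8780, 0.8205, 0.8457, 0.9264],
                [0.9194, 0.9500, 0.9268, 0.9383, 0.9048, 0.9158, 0.9774],
                [0.9268, 1.0000, 0.7273, 0.8421, 1.0000, 0.8636, 0.9803],
                [0.9333, 0.9474, 0.9474, 0.9474, 0.9091, 0.9282, 0.9904],
                [0.6000, 0.7500, 0.3000, 0.4286, 0.9000, 0.6000, 0.8700],
                [1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000],
            ],
            n_selected=[17, 23, 20, 19, 16, 27, 24],
        ),
        "FOX": _table(
            [
                [0.9780, 0.9802, 0.9802, 0.9802, 0.9753, 0.9778, 0.9947],
                [0.8416, 0.8382, 0.9194, 0.8769, 0.7179, 0.8187, 0.9264],
                [0.9194, 0.9500, 0.9268, 0.9383, 0.9048, 0.9158, 0.9762],
                [0.8293, 1.0000, 0.3636, 0.5333, 1.0000, 0.6818, 0.9045],
                [0.8333, 0.8889, 0.8421, 0.8649, 0.8182, 0.8301, 0.9426],
                [0.8000, 0.8000, 0.8000, 0.8000, 0.8000, 0.8000, 0.8000],
                [1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000],
            ],
            n_selected=[23, 21, 27, 18, 21, 22, 24],
        ),
        "RIME": _table(
            [
                [0.9945, 0.9902, 1.0000, 0.9951, 0.9877, 0.9938, 0.9999],
                [0.8119, 0.8413, 0.8548, 0.8480, 0.7436, 0.7992, 0.9272],
                [0.8871, 0.9722, 0.8537, 0.9091, 0.9524, 0.9030, 0.9599],
                [0.9024, 0.8889, 0.7273, 0.8000, 0.9667, 0.8470, 0.9288],
                [0.8667, 0.8947, 0.8947, 0.8947, 0.8182, 0.8565, 0.9569],
                [0.7500, 0.8571, 0.6000, 0.7059, 0.9000, 0.7500, 0.9300],
                [1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000],
            ],
            n_selected=[22, 27, 17, 19, 25, 17, 21],
        ),
    }


def missingness_metrics() -> pd.DataFrame:
    """Per-level test metrics after 10% MCAR missingness + k-NN imputation."""
    return _table(
        [
            [0.9891, 1.0000, 0.9802, 0.9900, 1.0000, 0.9901, 1.0000],
            [0.8515, 0.8615, 0.9032, 0.8819, 0.7692, 0.8362, 0.9231],
            [0.9032, 0.9268, 0.9268, 0.9268, 0.8571, 0.8920, 0.9605],
            [0.9512, 1.0000, 0.8182, 0.9000, 1.0000, 0.9091, 0.9879],
            [0.9667, 1.0000, 0.9474, 0.9730, 1.0000, 0.9737, 0.9856],
            [0.8500, 0.8889, 0.8000, 0.8421, 0.9000, 0.8500, 0.9800],
            [1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000],
        ]
    )


def accuracy_matrix(metric: str = "Acc") -> pd.DataFrame:
    """Methods-by-levels matrix of one metric for the rank comparison:
    the majority-vote system against the four metaheuristic baselines."""
    rows = {"MajorityVoting": level_test_metrics()[metric]}
    for name, table in baseline_selector_metrics().items():
        rows[name] = table[metric]
    return pd.DataFrame(rows).T
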