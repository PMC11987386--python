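"""Multi-level binary cascade: class peeling, per-level splits, and routing.

The multi-class problem is decomposed into an ordered sequence of binary
contests.  Level 1 separates healthy controls from any cancer; each
subsequent level pits the most frequent remaining cancer against the pool
of the rest, removing the peeled class before the next level; the final
level is a head-to-head between the last two classes.  With the default
cohort composition this yields seven levels:

    1. Normal vs Cancer        5. Lung vs other
    2. Colorectum vs other     6. Pancreas vs other
    3. Breast vs other         7. Ovary vs Liver
    4. UpperGI vs other

At inference a sample descends the trained levels: it exits with a level's
positive label as soon as that level's positive-class probability reaches
the routing threshold, and the terminal level decides by argmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .data_io import FEATURES, LABEL, DomainError

__all__ = [
    "DEFAULT_MERGE_MAP",
    "DEFAULT_SPLIT_SEED",
    "CascadeLevel",
    "build_levels",
    "split_level",
    "route_predict",
    "CascadeClassifier",
]

#: Esophageal and gastric malignancies are pooled as upper-GI cancer.
DEFAULT_MERGE_MAP: dict[str, str] = {"Esophagus": "UpperGI", "Stomach": "UpperGI"}

#: Fixed default so the 90/10 split is reproducible without configuration.
DEFAULT_SPLIT_SEED = 17

#: Pseudo-label for the pooled cancer side of level 1.
CANCER_POOL = "Cancer"


@dataclass
class CascadeLevel:
    """One binary contest of the cascade.

    ``y`` is 1 for the positive class and 0 for the pooled remainder.
    ``train_idx``/``test_idx`` are positional row indices into ``table``
    (``None`` until :func:`split_level` is applied).
    """

    index: int
    positive_label: str
    negative_pool: frozenset[str]
    table: pd.DataFrame
    y: np.ndarray
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None

    @property
    def name(self) -> str:
        neg = "Normal" if self.index == 1 else (
            "/".join(sorted(self.negative_pool)) if len(self.negative_pool) == 1 else "Other"
        )
        return f"{self.positive_label} vs {neg}"

    def describe(self) -> dict:
        d = {
            "index": self.index,
            "positive_label": self.positive_label,
            "negative_pool": sorted(self.negative_pool),
            "n_rows": int(len(self.table)),
            "n_positive": int(self.y.sum()),
        }
        if self.train_idx is not None:
            d["n_train"] = int(len(self.train_idx))
            d["n_test"] = int(len(self.test_idx))
        return d


def build_levels(
    table: pd.DataFrame,
    merge_map: Mapping[str, str] | None = None,
) -> list[CascadeLevel]:
    """Peel a multi-class feature table into an ordered list of binary levels.

    Level 1 is Normal-vs-Cancer (positive side = pooled cancers); Normal
    rows are then removed and each later level peels the most frequent
    remaining class (count ties broken alphabetically for determinism);
    the final level is a two-class contest.  Classes with zero rows are
    dropped with a warning.
    """
    merge_map = DEFAULT_MERGE_MAP if merge_map is None else dict(merge_map)
    labels = table[LABEL].astype(str).replace(merge_map)
    counts = labels.value_counts()
    classes = [c for c in counts.index if counts[c] > 0]
    if len(classes) < 2:
        raise DomainError("cascade needs at least 2 non-empty classes")
    if len(classes) == 2:
        warnings.warn("only 2 classes present; building a single-level cascade", stacklevel=2)

    table = table.reset_index(drop=True)
    labels = labels.reset_index(drop=True)
    levels: list[CascadeLevel] = []

    remaining = labels.copy()
    index = 1
    if "Normal" in classes:
        y = (remaining != "Normal").to_numpy(dtype=int)
        levels.append(
            CascadeLevel(
                index=index,
                positive_label=CANCER_POOL,
                negative_pool=frozenset({"Normal"}),
                table=table.assign(**{LABEL: remaining.to_numpy()}),
                y=y,
            )
        )
        keep = remaining != "Normal"
        table = table.loc[keep].reset_index(drop=True)
        remaining = remaining.loc[keep].reset_index(drop=True)
        index += 1

    while True:
        counts = remaining.value_counts()
        # descending count, alphabetical tie-break
        order = sorted(counts.index, key=lambda c: (-counts[c], c))
        if len(order) < 2:
            break
        positive = order[0]
        pool = frozenset(order[1:])
        y = (remaining == positive).to_numpy(dtype=int)
        levels.append(
            CascadeLevel(
                index=index,
                positive_label=positive,
                negative_pool=pool,
                table=table.assign(**{LABEL: remaining.to_numpy()}),
                y=y,
            )
        )
        if len(order) == 2:
            break
        keep = remaining != positive
        table = table.loc[keep].reset_index(drop=True)
        remaining = remaining.loc[keep].reset_index(drop=True)
        index += 1

    return levels


def split_level(
    level: CascadeLevel,
    test_fraction: float = 0.10,
    seed: int = DEFAULT_SPLIT_SEED,
) -> CascadeLevel:
    """Stratified train/test partition of one level (default 90/10).

    Per-binary-class test counts land within +-1 of
    ``round(test_fraction * class size)``; the partition is deterministic
    under ``seed``.
    """
    for cls in (0, 1):
        if (level.y == cls).sum() < 2:
            raise DomainError(
                f"level {level.index}: binary class {cls} has < 2 rows; cannot split"
            )
    idx = np.arange(len(level.table))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=level.y, random_state=seed
    )
    return replace(level, train_idx=np.sort(train_idx), test_idx=np.sort(test_idx))


def route_predict(
    models: Sequence,
    levels_meta: Sequence[Mapping],
    X: pd.DataFrame,
    threshold: float = 0.5,
) -> tuple[np.ndarray, list[list[float]]]:
    """Route samples through trained level models.

    Parameters
    ----------
    models
        Fitted binary classifiers, one per level, each exposing
        ``predict_proba`` with classes ``[0, 1]`` (1 = positive class).
    levels_meta
        Per-level dicts with keys ``positive_label``, ``negative_pool``
        and ``features`` (the columns that level's model expects).
    X
        Feature rows to classify.
    threshold
        Intermediate-level decision threshold on the positive-class
        probability; the terminal level always decides by argmax.

    Returns
    -------
    labels, traces
        Predicted label per row, and per-row list of each visited level's
        positive-class probability.
    """
    n_levels = len(models)
    if n_levels != len(levels_meta):
        raise DomainError("models and levels_meta must align")
    probs = []
    for model, meta in zip(models, levels_meta):
        feats = list(meta["features"])
        missing = [f for f in feats if f not in X.columns]
        if missing:
            raise DomainError(
                f"level {meta.get('index', '?')}: sample is missing feature(s) {missing}"
            )
        p = np.asarray(model.predict_proba(X[feats]))[:, 1]
        probs.append(p)

    labels = np.empty(len(X), dtype=object)
    traces: list[list[float]] = []
    for i in range(len(X)):
        trace: list[float] = []
        decided = None
        for k in range(n_levels):
            p = float(probs[k][i])
            trace.append(p)
            meta = levels_meta[k]
            terminal = k == n_levels - 1
            if terminal:
                if p >= 0.5:
                    decided = meta["positive_label"]
                else:
                    (decided,) = set(meta["negative_pool"])
            elif k == 0 and p < threshold:
                decided = "Normal"
            elif k > 0 and p >= threshold:
                decided = meta["positive_label"]
            if decided is not None:
                break
        labels[i] = decided
        traces.append(trace)
    return labels, traces


class CascadeClassifier(ClassifierMixin, BaseEstimator):
    """Multi-class classifier built as a peeling cascade of binary models.

    ``fit`` builds the binary levels from the training data, optionally
    runs majority-vote feature selection per level, and fits each level's
    registry model (single algorithm or soft-voting ensemble).  ``predict``
    routes each sample down the cascade.

    Parameters
    ----------
    merge_map
        Label merges applied before peeling (default pools esophageal and
        gastric cancers as upper GI).
    vote_threshold
        Minimum selector votes (out of six) for a feature to enter a
        level's model; ``None`` disables selection (all features used).
    level_specs
        Optional overrides of the per-level model registry, mapping level
        index to a member tuple such as ``("qda", "xgb")``.
    route_threshold
        Intermediate-level routing threshold on P(positive).
    random_state
        Seeds selector forests and level models.

    Attributes
    ----------
    levels_ : list of dict
        Per-level metadata (positive label, pool, selected features).
    models_ : list
        Fitted per-level binary models.
    selectors_ : list
        Fitted per-level :class:`~oncocascade.vote_select.MajorityVoteSelector`
        instances (``None`` when selection is disabled).
    classes_ : ndarray
        All output labels, including ``"Normal"``.
    """

    def __init__(
        self,
        merge_map: Mapping[str, str] | None = None,
        vote_threshold: int | None = 3,
        level_specs: Mapping[int, tuple[str, ...]] | None = None,
        route_threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.merge_map = merge_map
        self.vote_threshold = vote_threshold
        self.level_specs = level_specs
        self.route_threshold = route_threshold
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "CascadeClassifier":
        from .level_models import make_level_model
        from .vote_select import MajorityVoteSelector

        X = pd.DataFrame(X).reset_index(drop=True)
        table = X.copy()
        table[LABEL] = np.asarray(y, dtype=object)
        levels = build_levels(table, self.merge_map)

        self.levels_, self.models_, self.selectors_ = [], [], []
        feature_cols = [c for c in X.columns]
        for level in levels:
            Xl = level.table[feature_cols]
            yl = level.y
            if self.vote_threshold is not None:
                selector = MajorityVoteSelector(
                    threshold=self.vote_threshold, random_state=self.random_state
                ).fit(Xl, yl)
                feats = list(selector.selected_features_)
            else:
                selector = None
                feats = list(feature_cols)
            model = clone(
                make_level_model(
                    level.index,
                    overrides=self.level_specs,
                    random_state=self.random_state,
                    fallback=("rf",),
                )
            )
            model.fit(Xl[feats], yl)
            self.selectors_.append(selector)
            self.models_.append(model)
            self.levels_.append(
                {
                    "index": level.index,
                    "positive_label": level.positive_label,
                    "negative_pool": sorted(level.negative_pool),
                    "features": feats,
                }
            )
        out_labels = {"Normal"} if levels[0].positive_label == CANCER_POOL else set()
        for meta in self.levels_[1:] if levels[0].positive_label == CANCER_POOL else self.levels_:
            out_labels.add(meta["positive_label"])
        out_labels.update(self.levels_[-1]["negative_pool"])
        self.classes_ = np.array(sorted(out_labels), dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "models_")
        labels, _ = route_predict(
            self.models_, self.levels_, pd.DataFrame(X), threshold=self.route_threshold
        )
        return labels

    def predict_trace(self, X: pd.DataFrame) -> tuple[np.ndarray, list[list[float]]]:
        """Predicted labels plus each sample's per-level probability trace."""
        check_is_fitted(self, "models_")
        return route_predict(
            self.models_, self.levels_, pd.DataFrame(X), threshold=self.route_threshold
        )
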