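"""Per-level classifier registry, soft voting, and cross-validated training.

Each cascade level gets the algorithm (or soft-voting pair) that proved
strongest for its contest:

====== ============================= =============================
level  contest                       model
====== ============================= =============================
1      Normal vs Cancer              gradient-boosted trees (GBT)
2      Colorectum vs other           soft vote: GBT + random forest
3      Breast vs other               soft vote: extra trees + RF
4      Upper GI vs other             extra trees
5      Lung vs other                 quadratic discriminant analysis
6      Pancreas vs other             soft vote: QDA + GBT
7      Ovary vs Liver                random forest
====== ============================= =============================

Hyperparameters are fixed: GBT uses 100 boosting rounds, learning rate
0.3, max depth 6, min child weight 1, base score 0.5 (logistic link on
summed leaf scores); the forests use 100 trees with Gini impurity (RF
bootstrapped, extra trees not, with random split thresholds); QDA uses no
covariance shrinkage (reg 0.0, tol 1e-4) with priors estimated from the
data.  Soft voting averages member class probabilities with equal weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier, VotingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .data_io import DomainError
from .evaluation import MetricsReport, metrics_from_predictions

__all__ = [
    "MEMBER_NAMES",
    "LEVEL_REGISTRY",
    "LevelModelSpec",
    "SafeQDA",
    "make_member",
    "make_level_model",
    "soft_vote_proba",
    "FoldMetrics",
    "crossvalidate",
]

MEMBER_NAMES = ("xgb", "rf", "et", "qda")

#: Default member composition per cascade level.
LEVEL_REGISTRY: dict[int, tuple[str, ...]] = {
    1: ("xgb",),
    2: ("xgb", "rf"),
    3: ("et", "rf"),
    4: ("et",),
    5: ("qda",),
    6: ("qda", "xgb"),
    7: ("rf",),
}


@dataclass(frozen=True)
class LevelModelSpec:
    """Which members serve a level, and how they combine."""

    index: int
    members: tuple[str, ...]

    @property
    def combination(self) -> str:
        return "soft-vote" if len(self.members) > 1 else "single"


class SafeQDA(ClassifierMixin, BaseEstimator):
    """QDA with a diagnostic fallback for singular class covariances.

    With ``reg_param=0.0`` a class whose covariance matrix is singular
    makes the discriminant ill-defined on small levels; rather than
    crashing, the fit is retried with ``fallback_reg`` shrinkage and a
    warning is emitted.
    """

    def __init__(self, reg_param: float = 0.0, tol: float = 1e-4, fallback_reg: float = 1e-6):
        self.reg_param = reg_param
        self.tol = tol
        self.fallback_reg = fallback_reg

    def fit(self, X, y):
        qda = QuadraticDiscriminantAnalysis(reg_param=self.reg_param, tol=self.tol)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                qda.fit(X, y)
            # singular covariance shows up as non-finite discriminant output
            if not np.isfinite(qda.predict_proba(X)).all():
                raise np.linalg.LinAlgError("non-finite discriminant values")
        except (np.linalg.LinAlgError, FloatingPointError):
            warnings.warn(
                f"singular class covariance with reg_param={self.reg_param}; "
                f"refitting with eigendecomposition and shrinkage {self.fallback_reg}",
                stacklevel=2,
            )
            # eigen solver tolerates rank deficiency once shrinkage lifts the
            # spectrum above the rank tolerance
            qda = QuadraticDiscriminantAnalysis(
                solver="eigen", shrinkage=self.fallback_reg,
                tol=min(self.tol, self.fallback_reg * 1e-3),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                qda.fit(X, y)
        self.model_ = qda
        self.classes_ = qda.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(X)


def make_member(name: str, random_state: int = 0) -> BaseEstimator:
    """Instantiate one registry member with its fixed hyperparameters."""
    if name == "xgb":
        return XGBClassifier(
            booster="gbtree",
            n_estimators=100,
            learning_rate=0.3,
            max_depth=6,
            min_child_weight=1,
            base_score=0.5,
            objective="binary:logistic",
            eval_metric="logloss",
            random_state=random_state,
            n_jobs=1,
            verbosity=0,
        )
    if name == "rf":
        return RandomForestClassifier(
            n_estimators=100,
            criterion="gini",
            min_samples_split=2,
            min_samples_leaf=1,
            bootstrap=True,
            random_state=random_state,
            n_jobs=1,
        )
    if name == "et":
        return ExtraTreesClassifier(
            n_estimators=100,
            criterion="gini",
            min_samples_split=2,
            min_samples_leaf=1,
            bootstrap=False,
            random_state=random_state,
            n_jobs=1,
        )
    if name == "qda":
        return SafeQDA(reg_param=0.0, tol=1e-4)
    raise DomainError(f"unknown member {name!r}; expected one of {MEMBER_NAMES}")


def make_level_model(
    index: int,
    overrides: Mapping[int, Sequence[str]] | None = None,
    random_state: int = 0,
    fallback: Sequence[str] | None = None,
) -> BaseEstimator:
    """Build the registry model for a level (soft-voting when the spec has
    several members).

    ``overrides`` replaces a level's member tuple; an index outside the
    registry raises unless ``fallback`` members are given.
    """
    members: Sequence[str] | None = None
    if overrides and index in overrides:
        members = tuple(overrides[index])
        if not members:
            raise DomainError(f"override for level {index} has an empty member list")
    elif index in LEVEL_REGISTRY:
        members = LEVEL_REGISTRY[index]
    elif fallback:
        warnings.warn(
            f"level {index} not in registry; using fallback members {tuple(fallback)}",
            stacklevel=2,
        )
        members = tuple(fallback)
    else:
        raise DomainError(f"no registry entry for level {index} and no override given")

    if len(members) == 1:
        return make_member(members[0], random_state)
    return VotingClassifier(
        estimators=[(m, make_member(m, random_state)) for m in members],
        voting="soft",
    )


def soft_vote_proba(members: Sequence, X) -> np.ndarray:
    """Unweighted arithmetic mean of fitted members' class probabilities.

    Raises :class:`~oncocascade.data_io.DomainError` if any member emits
    non-normalized probability rows.
    """
    if not members:
        raise DomainError("soft vote needs at least one fitted member")
    probas = []
    for m in members:
        p = np.asarray(m.predict_proba(X), dtype=float)
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
            raise DomainError(f"member {m!r} emitted non-normalized probabilities")
        probas.append(p)
    return np.mean(probas, axis=0)


@dataclass
class FoldMetrics:
    """Per-fold cross-validation metrics with their mean and std."""

    per_fold: pd.DataFrame  # one row per fold

    METRICS = ("Acc", "Precision", "Recall", "F1", "Specificity", "BA", "AUC")

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.mean()

    @property
    def std(self) -> pd.Series:
        return self.per_fold.std(ddof=1)

    def to_frame(self) -> pd.DataFrame:
        out = self.per_fold.copy()
        out.loc["Mean"] = self.mean
        out.loc["Std"] = self.std
        return out


def crossvalidate(
    model: BaseEstimator | int,
    X: pd.DataFrame,
    y: Sequence[int],
    k: int = 10,
    seed: int = 0,
    policy: str = "refit-all",
) -> tuple[FoldMetrics, BaseEstimator]:
    """Stratified k-fold cross-validation of a level model.

    ``model`` may be an estimator or a level index (resolved through the
    registry).  Per-fold metrics come from
    :func:`oncocascade.evaluation.metrics_from_predictions`.  The returned
    fitted model follows ``policy``:

    - ``"refit-all"`` (default): refit on all training rows;
    - ``"best-fold"``: keep the fold model with the highest AUC (ties by
      accuracy, then by fold index).
    """
    if isinstance(model, int):
        model = make_level_model(model, random_state=seed)
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.size < 2 or counts.min() < k:
        raise DomainError(
            f"cannot stratify {k} folds with class counts {counts.tolist()}; reduce k"
        )
    if policy not in ("refit-all", "best-fold"):
        raise DomainError(f"unknown refit policy {policy!r}")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows, fold_models = [], []
    X = pd.DataFrame(X).reset_index(drop=True)
    for train, test in skf.split(X, y):
        m = clone(model)
        m.fit(X.iloc[train], y[train])
        score = m.predict_proba(X.iloc[test])[:, 1]
        rep = metrics_from_predictions(y[test], m.predict(X.iloc[test]), score, scope="fold")
        nan_if_none = lambda v: np.nan if v is None else v  # undefined metric -> NaN in the fold table
        rows.append(
            {
                "Acc": nan_if_none(rep.acc),
                "Precision": nan_if_none(rep.precision),
                "Recall": nan_if_none(rep.recall),
                "F1": nan_if_none(rep.f1),
                "Specificity": nan_if_none(rep.specificity),
                "BA": nan_if_none(rep.balanced_accuracy),
                "AUC": nan_if_none(rep.auc),
            }
        )
        fold_models.append(m)

    per_fold = pd.DataFrame(rows, index=pd.RangeIndex(1, k + 1, name="fold"))
    if policy == "refit-all":
        final = clone(model).fit(X, y)
    else:
        ranked = sorted(
            range(k),
            key=lambda i: (-per_fold["AUC"].iloc[i], -per_fold["Acc"].iloc[i], i),
        )
        final = fold_models[ranked[0]]
    return FoldMetrics(per_fold), final
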