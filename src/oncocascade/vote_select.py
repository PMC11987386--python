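"""Majority-vote feature selection from six heterogeneous scorers.

Six selectors — information value (IV) with monotonic weight-of-evidence
binning, the 2x2 contingency chi-square, random-forest and extra-trees
importances, recursive feature elimination (RFE) on a logistic model, and
L1-penalized linear max-margin selection — each nominate the top half of
the features.  A feature enters a level's model when at least ``threshold``
selectors (default 3 of 6) nominate it.  Combining filter, embedded and
wrapper selectors this way damps the idiosyncrasies of any single method.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE, SelectorMixin, chi2 as _sk_chi2
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .data_io import DomainError

__all__ = [
    "BinTable",
    "VoteTally",
    "woe_iv",
    "iv_strength",
    "chi_square_scores",
    "forest_importance",
    "extra_trees_importance",
    "rfe_select",
    "l1_select",
    "majority_vote_select",
    "MajorityVoteSelector",
    "SCORER_NAMES",
]

SCORER_NAMES = ("iv", "chi2", "rf", "et", "rfe", "l1")


# ---------------------------------------------------------------------------
# information value with monotonic binning


@dataclass
class BinTable:
    """Per-bin weight-of-evidence table for one feature.

    ``c1``/``c2`` are the per-bin proportions of the positive and negative
    class (each sums to 1 over bins, after 0.5 smoothing of zero cells);
    ``woe = ln(c1/c2)``; ``iv = sum((c1 - c2) * woe)``.
    """

    edges: np.ndarray  # len(bins)+1 for interval bins; bin values for categorical bins
    pos: np.ndarray
    neg: np.ndarray
    c1: np.ndarray
    c2: np.ndarray
    woe: np.ndarray
    iv: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pos": self.pos, "neg": self.neg, "c1": self.c1, "c2": self.c2, "woe": self.woe}
        )


def _woe_from_counts(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # 0.5 smoothing of zero cells keeps logs finite without touching
    # populated cells
    p = np.where(pos == 0, 0.5, pos).astype(float)
    q = np.where(neg == 0, 0.5, neg).astype(float)
    c1 = p / p.sum()
    c2 = q / q.sum()
    return c1, c2, np.log(c1 / c2)


def _is_monotone(w: np.ndarray) -> bool:
    return bool(np.all(np.diff(w) >= 0) or np.all(np.diff(w) <= 0))


def woe_iv(
    x: Sequence[float],
    y: Sequence[int],
    cardinality: int = 5,
    bins: int = 3,
    max_bins: int = 20,
) -> tuple[float, BinTable]:
    """Information value of one feature against a binary label.

    Continuous features (>= ``cardinality`` distinct values) start from
    ``max_bins`` quantile bins; adjacent bins are merged greedily (the
    first monotonicity-violating pair each pass) until the per-bin WoE is
    monotone in bin order or only ``bins`` bins remain.  Features with
    fewer distinct values use one bin per distinct value, unbinned.

    Conventional reading of the score: IV < 0.02 useless, 0.02-0.1 weak,
    0.1-0.3 moderate, >= 0.3 strong discrimination (see
    :func:`iv_strength`).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise DomainError("feature and label lengths differ")
    classes = np.unique(y)
    if classes.size < 2:
        raise DomainError("IV undefined with a single class")

    distinct = np.unique(x)
    if distinct.size == 1:
        warnings.warn("constant feature: IV = 0", stacklevel=2)
        c1, c2, woe = _woe_from_counts(np.array([(y == 1).sum()]), np.array([(y == 0).sum()]))
        return 0.0, BinTable(distinct, np.array([(y == 1).sum()]), np.array([(y == 0).sum()]),
                             c1, c2, woe, 0.0)

    if distinct.size < cardinality:
        # low-cardinality: one bin per distinct value, no monotonic binning
        pos = np.array([((x == v) & (y == 1)).sum() for v in distinct])
        neg = np.array([((x == v) & (y == 0)).sum() for v in distinct])
        edges = distinct
    else:
        qs = np.quantile(x, np.linspace(0, 1, max_bins + 1))
        edges = np.unique(qs)
        if edges.size < 3:  # heavily tied feature; fall back to distinct cuts
            edges = np.unique(np.concatenate([distinct[:1], distinct]))
        # assign to bins [e0,e1], (e1,e2], ...
        idx = np.clip(np.searchsorted(edges, x, side="left") - 1, 0, edges.size - 2)
        nb = edges.size - 1
        pos = np.bincount(idx[y == 1], minlength=nb)
        neg = np.bincount(idx[y == 0], minlength=nb)
        # greedy adjacent merging until WoE monotone or floor reached
        while pos.size > bins:
            _, _, woe = _woe_from_counts(pos, neg)
            if _is_monotone(woe):
                break
            d = np.diff(woe)
            up, down = (d >= 0).sum(), (d <= 0).sum()
            sign = 1.0 if up >= down else -1.0
            viol = np.flatnonzero(sign * d < 0)
            j = int(viol[0])
            pos = np.concatenate([pos[:j], [pos[j] + pos[j + 1]], pos[j + 2:]])
            neg = np.concatenate([neg[:j], [neg[j] + neg[j + 1]], neg[j + 2:]])
            edges = np.concatenate([edges[: j + 1], edges[j + 2:]])

    c1, c2, woe = _woe_from_counts(pos, neg)
    iv = float(np.sum((c1 - c2) * woe))
    return iv, BinTable(edges, pos, neg, c1, c2, woe, iv)


def iv_strength(iv: float) -> str:
    """Conventional qualitative reading of an information value."""
    if iv < 0.02:
        return "useless"
    if iv < 0.1:
        return "weak"
    if iv < 0.3:
        return "moderate"
    return "strong"


def _iv_scores(X: pd.DataFrame, y: np.ndarray, **kw) -> pd.Series:
    vals = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for col in X.columns:
            vals[col], _ = woe_iv(X[col].to_numpy(), y, **kw)
    return pd.Series(vals)


# ---------------------------------------------------------------------------
# chi-square


def chi_square_scores(
    X: pd.DataFrame,
    y: Sequence[int],
    mode: str = "contingency",
) -> pd.Series:
    """Per-feature chi-square association with the binary label.

    ``mode="contingency"`` (default): each continuous feature is
    dichotomized at its median and the standard 2x2 observed-vs-expected
    chi-square (no continuity correction) is computed.  Degenerate margins
    (all rows in one cell of a margin) score 0 with a warning.

    ``mode="frequency"``: the scikit-learn convention that treats the
    non-negative feature values themselves as frequencies (features with
    negative values are shifted to zero first).
    """
    y = np.asarray(y, dtype=int)
    if mode == "frequency":
        vals = X.to_numpy(dtype=float)
        mins = vals.min(axis=0)
        vals = vals - np.minimum(mins, 0)  # shift-to-zero for negative columns
        scores, _ = _sk_chi2(vals, y)
        return pd.Series(scores, index=X.columns)
    if mode != "contingency":
        raise DomainError(f"unknown chi-square mode {mode!r}")
    out = {}
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        above = x > np.median(x)
        tbl = np.array(
            [
                [((above) & (y == 1)).sum(), ((above) & (y == 0)).sum()],
                [((~above) & (y == 1)).sum(), ((~above) & (y == 0)).sum()],
            ],
            dtype=float,
        )
        if (tbl.sum(axis=0) == 0).any() or (tbl.sum(axis=1) == 0).any():
            warnings.warn(f"degenerate margin for {col!r}: chi-square 0", stacklevel=2)
            out[col] = 0.0
            continue
        stat, _, _, _ = stats.chi2_contingency(tbl, correction=False)
        out[col] = float(stat)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# tree-ensemble importances


_FOREST_DEFAULTS = dict(
    n_estimators=100,
    criterion="gini",
    min_samples_split=2,
    min_samples_leaf=1,
)


def forest_importance(
    X: pd.DataFrame,
    y: Sequence[int],
    flavor: str = "impurity",
    seed: int = 0,
    **forest_kw,
) -> pd.Series:
    """Random-forest feature importance (100 trees, Gini, bootstrap).

    ``flavor="impurity"``: mean decrease in Gini impurity, normalized to
    sum to 1.  ``flavor="oob_permutation"``: per tree, the absolute change
    in out-of-bag error after permuting the feature within the OOB rows,
    averaged over trees — requires bootstrap sampling.
    """
    y = np.asarray(y, dtype=int)
    kw = {**_FOREST_DEFAULTS, **forest_kw}
    bootstrap = kw.pop("bootstrap", True)
    if flavor == "oob_permutation" and not bootstrap:
        raise DomainError("OOB permutation importance requires bootstrap sampling")
    forest = RandomForestClassifier(bootstrap=bootstrap, random_state=seed, n_jobs=1, **kw)
    forest.fit(X, y)
    if flavor == "impurity":
        return pd.Series(forest.feature_importances_, index=X.columns)
    if flavor != "oob_permutation":
        raise DomainError(f"unknown importance flavor {flavor!r}")

    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    n = len(y)
    deltas = np.zeros((len(forest.estimators_), X.shape[1]))
    for t, tree in enumerate(forest.estimators_):
        sampled = np.bincount(
            forest.estimators_samples_[t]
            if hasattr(forest, "estimators_samples_")
            else np.arange(n),
            minlength=n,
        )
        oob = np.flatnonzero(sampled == 0)
        if oob.size == 0:
            continue
        base_err = np.mean(tree.predict(Xv[oob]) != y[oob])
        for j in range(X.shape[1]):
            perm = Xv[oob].copy()
            perm[:, j] = rng.permutation(perm[:, j])
            deltas[t, j] = abs(np.mean(tree.predict(perm) != y[oob]) - base_err)
    return pd.Series(deltas.mean(axis=0), index=X.columns)


def extra_trees_importance(
    X: pd.DataFrame,
    y: Sequence[int],
    seed: int = 0,
    **forest_kw,
) -> pd.Series:
    """Extra-trees impurity importance: random split thresholds, no
    bootstrap, otherwise the random-forest configuration."""
    kw = {**_FOREST_DEFAULTS, **forest_kw}
    et = ExtraTreesClassifier(bootstrap=False, random_state=seed, n_jobs=1, **kw)
    et.fit(X, np.asarray(y, dtype=int))
    return pd.Series(et.feature_importances_, index=X.columns)


# ---------------------------------------------------------------------------
# model-based selectors


def rfe_select(
    X: pd.DataFrame,
    y: Sequence[int],
    n_keep: int = 21,
) -> tuple[list[str], list[str]]:
    """Recursive feature elimination with an L2 logistic model.

    Features are standardized; at each step the feature with the smallest
    coefficient magnitude is dropped (step 1; logistic regression with
    C=1.0, lbfgs, max_iter=100, tol=1e-4) until ``n_keep`` remain.

    Returns ``(selected, elimination_order)`` where ``elimination_order``
    lists features first-eliminated first.
    """
    cols = list(X.columns)
    if n_keep >= len(cols):
        warnings.warn("n_keep >= feature count: keeping all features", stacklevel=2)
        return cols, []
    Z = StandardScaler().fit_transform(X)
    # ridge (L2) logistic model; L2 is the estimator's default penalty
    est = LogisticRegression(C=1.0, solver="lbfgs", max_iter=100, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        rfe = RFE(est, n_features_to_select=n_keep, step=1).fit(Z, np.asarray(y, dtype=int))
    selected = [c for c, keep in zip(cols, rfe.support_) if keep]
    # ranking_: 1 for kept features, larger = eliminated earlier
    order = [c for _, c in sorted(zip(-rfe.ranking_, cols)) if not rfe.support_[cols.index(c)]]
    return selected, order


def l1_select(
    X: pd.DataFrame,
    y: Sequence[int],
    C: float = 0.01,
    n_keep: int = 21,
) -> tuple[list[str], pd.Series]:
    """L1-penalized linear max-margin selection.

    Fits a linear SVM (squared hinge, C=0.01, max_iter=1000, tol=1e-4) on
    standardized features; features are ranked by |coefficient| with
    exact zeros last (ties broken by name) and the top ``n_keep`` kept.

    Returns ``(selected, coefficient magnitudes)``.
    """
    cols = list(X.columns)
    Z = StandardScaler().fit_transform(X)
    svc = LinearSVC(
        penalty="l1", loss="squared_hinge", dual=False, C=C, max_iter=1000, tol=1e-4,
        random_state=0,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        svc.fit(Z, np.asarray(y, dtype=int))
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            warnings.warn(
                "L1 selector did not converge; using coefficients from the final iterate",
                stacklevel=2,
            )
    mags = pd.Series(np.abs(svc.coef_).ravel(), index=cols)
    if (mags == 0).all():
        warnings.warn(
            "all L1 coefficients are zero; selection degenerates to name order",
            stacklevel=2,
        )
    ranked = sorted(cols, key=lambda c: (-mags[c], c))
    return ranked[: min(n_keep, len(cols))], mags


# ---------------------------------------------------------------------------
# majority vote


@dataclass
class VoteTally:
    """Outcome of the six-selector vote for one binary dataset."""

    scores: pd.DataFrame  # feature x scorer raw scores (NaN for set-valued scorers)
    kept: pd.DataFrame  # feature x scorer boolean nominations
    votes: pd.Series  # nominations per feature, 0..6
    threshold: int
    selected: list[str]
    n_keep: int
    abstained: list[str]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_keep": self.n_keep,
            "abstained": list(self.abstained),
            "votes": {f: int(v) for f, v in self.votes.items()},
            "selected": list(self.selected),
            "scores": {
                m: {f: (None if pd.isna(v) else float(v)) for f, v in self.scores[m].items()}
                for m in self.scores.columns
            },
        }

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _top_half(scores: pd.Series, n_keep: int) -> list[str]:
    # descending absolute score, name tie-break
    ranked = sorted(scores.index, key=lambda c: (-abs(scores[c]), c))
    return ranked[:n_keep]


def majority_vote_select(
    X: pd.DataFrame,
    y: Sequence[int],
    threshold: int = 3,
    seed: int = 0,
    n_keep: int | None = None,
    chi2_mode: str = "contingency",
) -> VoteTally:
    """Run all six selectors and tally their nominations.

    IV, chi-square, forest and extra-trees scores are sorted by absolute
    value and the top ``n_keep`` (default ``floor(N/2)``) nominated; RFE
    and L1 contribute their ``n_keep``-sized sets directly.  A feature is
    selected when nominated by at least ``threshold`` scorers.  A scorer
    that raises abstains with a warning (reducing attainable votes); more
    than two abstentions abort the vote.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=int)
    if X.shape[1] < 2:
        raise DomainError("majority vote needs at least 2 features")
    cols = list(X.columns)
    if n_keep is None:
        n_keep = len(cols) // 2

    scores = pd.DataFrame(np.nan, index=cols, columns=list(SCORER_NAMES))
    kept = pd.DataFrame(False, index=cols, columns=list(SCORER_NAMES))
    abstained: list[str] = []

    def run(name, fn):
        try:
            fn()
        except Exception as exc:  # scorer abstains rather than sinking the vote
            abstained.append(name)
            warnings.warn(f"selector {name!r} abstained: {exc}", stacklevel=3)

    def _iv():
        s = _iv_scores(X, y)
        scores["iv"] = s
        kept.loc[_top_half(s, n_keep), "iv"] = True

    def _chi2():
        s = chi_square_scores(X, y, mode=chi2_mode)
        scores["chi2"] = s
        kept.loc[_top_half(s, n_keep), "chi2"] = True

    def _rf():
        s = forest_importance(X, y, flavor="impurity", seed=seed)
        scores["rf"] = s
        kept.loc[_top_half(s, n_keep), "rf"] = True

    def _et():
        s = extra_trees_importance(X, y, seed=seed)
        scores["et"] = s
        kept.loc[_top_half(s, n_keep), "et"] = True

    def _rfe():
        sel, _ = rfe_select(X, y, n_keep=n_keep)
        kept.loc[sel, "rfe"] = True

    def _l1():
        sel, mags = l1_select(X, y, n_keep=n_keep)
        scores["l1"] = mags
        kept.loc[sel, "l1"] = True

    for name, fn in (("iv", _iv), ("chi2", _chi2), ("rf", _rf),
                     ("et", _et), ("rfe", _rfe), ("l1", _l1)):
        run(name, fn)

    if len(abstained) > 2:
        raise DomainError(f"too many selectors abstained: {abstained}")

    votes = kept.sum(axis=1).astype(int)
    selected = [c for c in cols if votes[c] >= threshold]
    return VoteTally(
        scores=scores,
        kept=kept,
        votes=votes,
        threshold=threshold,
        selected=selected,
        n_keep=n_keep,
        abstained=abstained,
    )


class MajorityVoteSelector(SelectorMixin, BaseEstimator):
    """scikit-learn transformer wrapping :func:`majority_vote_select`.

    Parameters
    ----------
    threshold
        Minimum nominations (of six selectors) to keep a feature.
    n_keep
        Nomination-set size per selector; default ``floor(N/2)``.
    chi2_mode
        ``"contingency"`` (median-dichotomized 2x2 test) or
        ``"frequency"`` (values-as-frequencies convention).
    random_state
        Seeds the tree-ensemble scorers.

    Attributes
    ----------
    tally_ : VoteTally
    votes_ : pandas.Series
    selected_features_ : list of str
    support_ : ndarray of bool
    """

    def __init__(
        self,
        threshold: int = 3,
        n_keep: int | None = None,
        chi2_mode: str = "contingency",
        random_state: int = 0,
    ):
        self.threshold = threshold
        self.n_keep = n_keep
        self.chi2_mode = chi2_mode
        self.random_state = random_state

    def fit(self, X, y) -> "MajorityVoteSelector":
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.tally_ = majority_vote_select(
            X,
            y,
            threshold=self.threshold,
            seed=self.random_state,
            n_keep=self.n_keep,
            chi2_mode=self.chi2_mode,
        )
        self.votes_ = self.tally_.votes
        selected = list(self.tally_.selected)
        if not selected:
            # never emit an empty design matrix: fall back to the top-voted
            # features and say so
            top = int(self.votes_.max())
            selected = [c for c in X.columns if self.votes_[c] == top]
            warnings.warn(
                f"no feature reached {self.threshold} votes; "
                f"falling back to {len(selected)} feature(s) with {top} votes",
                stacklevel=2,
            )
        self.selected_features_ = selected
        self.support_ = np.asarray([c in set(selected) for c in X.columns])
        return self

    def _get_support_mask(self) -> np.ndarray:
        check = getattr(self, "support_", None)
        if check is None:
            raise RuntimeError("selector is not fitted")
        return self.support_
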