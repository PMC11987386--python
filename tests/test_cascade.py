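import numpy as np
import pandas as pd
import pytest

from oncocascade.cascade import (
    CascadeClassifier,
    build_levels,
    route_predict,
    split_level,
)
from oncocascade.data_io import LABEL, DomainError, encode_features
from oncocascade.synthetic_cohort import DEFAULT_CLASS_SIZES, CohortConfig, generate_cohort


@pytest.fixture(scope="module")
def default_levels():
    table = generate_cohort(CohortConfig(seed=21))
    cohort = encode_features(table).assign(**{LABEL: table[LABEL].astype(str).to_numpy()})
    return build_levels(cohort)


class TestBuildLevels:
    def test_default_cohort_gives_seven_levels_in_published_order(self, default_levels):
        positives = [lv.positive_label for lv in default_levels]
        assert positives == ["Cancer", "Colorectum", "Breast", "UpperGI", "Lung", "Pancreas", "Ovary"]
        assert sorted(default_levels[-1].negative_pool) == ["Liver"]

    def test_terminal_level_is_ovary_vs_liver_with_98_rows(self, default_levels):
        last = default_levels[-1]
        assert len(last.table) == 54 + 44
        assert set(last.table[LABEL].unique()) == {"Ovary", "Liver"}

    def test_positive_conservation_across_cancer_levels(self, default_levels):
        total_cancer = sum(v for k, v in DEFAULT_CLASS_SIZES.items() if k != "Normal")
        assert sum(int(lv.y.sum()) for lv in default_levels[1:]) + int(
            default_levels[-1].y.size - default_levels[-1].y.sum()
        ) == total_cancer
        # levels 2..6 peel the positives; the terminal level carries both
        peeled = sum(int(lv.y.sum()) for lv in default_levels[1:-1])
        last = default_levels[-1]
        assert peeled + len(last.table) == total_cancer

    def test_monotone_shrinkage(self, default_levels):
        sizes = [len(lv.table) for lv in default_levels]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))

    def test_merge_map_pools_upper_gi(self):
        df = pd.DataFrame({
            "x": np.arange(30, dtype=float),
            LABEL: ["Normal"] * 10 + ["Esophagus"] * 8 + ["Stomach"] * 7 + ["Liver"] * 5,
        })
        levels = build_levels(df)
        assert levels[1].positive_label == "UpperGI"
        assert int(levels[1].y.sum()) == 15

    def test_two_class_input_single_level_with_warning(self):
        df = pd.DataFrame({"x": np.arange(20, dtype=float),
                           LABEL: ["Breast"] * 12 + ["Lung"] * 8})
        with pytest.warns(UserWarning, match="single-level"):
            levels = build_levels(df, merge_map={})
        assert len(levels) == 1
        assert levels[0].positive_label == "Breast"  # larger class

    def test_count_ties_broken_alphabetically(self):
        df = pd.DataFrame({"x": np.arange(30, dtype=float),
                           LABEL: ["Lung"] * 10 + ["Breast"] * 10 + ["Liver"] * 10})
        levels = build_levels(df, merge_map={})
        assert [lv.positive_label for lv in levels] == ["Breast", "Liver"]

    def test_single_class_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], LABEL: ["Lung", "Lung"]})
        with pytest.raises(DomainError):
            build_levels(df, merge_map={})


class TestSplitLevel:
    def test_ten_percent_stratified_counts(self, default_levels):
        lv = split_level(default_levels[0], 0.10, seed=3)
        n_pos, n_neg = int(lv.y.sum()), int((lv.y == 0).sum())
        test_pos = int(lv.y[lv.test_idx].sum())
        test_neg = len(lv.test_idx) - test_pos
        assert abs(test_pos - round(0.10 * n_pos)) <= 1  # ~101 of 1005
        assert abs(test_neg - round(0.10 * n_neg)) <= 1  # ~81 of 812
        # partition property
        both = np.concatenate([lv.train_idx, lv.test_idx])
        assert np.array_equal(np.sort(both), np.arange(len(lv.table)))

    def test_deterministic_under_seed(self, default_levels):
        a = split_level(default_levels[2], seed=5)
        b = split_level(default_levels[2], seed=5)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)

    def test_exact_half_split_arithmetic(self):
        df = pd.DataFrame({"x": np.arange(20, dtype=float),
                           LABEL: ["Lung"] * 10 + ["Liver"] * 10})
        (lv,) = [build_levels(df, merge_map={})[0]]
        lv = split_level(lv, 0.5, seed=0)
        assert int(lv.y[lv.test_idx].sum()) == 5
        assert len(lv.test_idx) == 10

    def test_tiny_class_split_impossible(self):
        df = pd.DataFrame({"x": np.arange(11, dtype=float),
                           LABEL: ["Lung"] * 10 + ["Liver"]})
        lv = build_levels(df, merge_map={})[0]
        with pytest.raises(DomainError, match="cannot split"):
            split_level(lv)


class _FixedProba:
    """Stub binary model returning a fixed positive-class probability."""

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.column_stack([np.full(len(X), 1 - self.p), np.full(len(X), self.p)])


def _meta(index, positive, pool, features=("x",)):
    return {"index": index, "positive_label": positive,
            "negative_pool": list(pool), "features": list(features)}


@pytest.fixture
def seven_level_meta():
    metas = [
        _meta(1, "Cancer", ["Normal"]),
        _meta(2, "Colorectum", ["Breast", "UpperGI", "Lung", "Pancreas", "Ovary", "Liver"]),
        _meta(3, "Breast", ["UpperGI", "Lung", "Pancreas", "Ovary", "Liver"]),
        _meta(4, "UpperGI", ["Lung", "Pancreas", "Ovary", "Liver"]),
        _meta(5, "Lung", ["Pancreas", "Ovary", "Liver"]),
        _meta(6, "Pancreas", ["Ovary", "Liver"]),
        _meta(7, "Ovary", ["Liver"]),
    ]
    return metas


class TestRoutePredict:
    X = pd.DataFrame({"x": [0.0]})

    def route(self, probs, metas):
        models = [_FixedProba(p) for p in probs]
        labels, traces = route_predict(models, metas[: len(probs)], self.X)
        return labels[0], traces[0]

    def test_low_cancer_probability_exits_normal(self, seven_level_meta):
        label, trace = self.route([0.1] * 7, seven_level_meta)
        assert label == "Normal"
        assert len(trace) == 1

    def test_descends_to_breast(self, seven_level_meta):
        label, trace = self.route([0.9, 0.2, 0.8, 0.0, 0.0, 0.0, 0.0], seven_level_meta)
        assert label == "Breast"
        assert len(trace) == 3

    def test_terminal_argmax_prefers_liver(self, seven_level_meta):
        label, trace = self.route([0.9, 0.2, 0.2, 0.2, 0.2, 0.2, 0.3], seven_level_meta)
        assert label == "Liver"
        assert len(trace) == 7

    def test_exhaustive_and_exclusive_over_random_traces(self, seven_level_meta):
        rng = np.random.default_rng(0)
        valid = {"Normal", "Colorectum", "Breast", "UpperGI", "Lung", "Pancreas", "Ovary", "Liver"}
        for _ in range(200):
            label, _ = self.route(rng.random(7), seven_level_meta)
            assert label in valid

    def test_missing_feature_names_level(self, seven_level_meta):
        metas = [dict(seven_level_meta[0], features=["absent"])]
        with pytest.raises(DomainError, match="absent"):
            route_predict([_FixedProba(0.5)], metas, self.X)


class TestCascadeClassifier:
    def test_fit_predict_on_small_cohort(self, small_encoded):
        X, y = small_encoded
        clf = CascadeClassifier(vote_threshold=None, random_state=0)
        clf.fit(X, y)
        assert len(clf.models_) == 7
        pred = clf.predict(X.iloc[:50])
        assert set(pred) <= set(clf.classes_)
        # majority of training rows are routed to a sensible label
        acc = (clf.predict(X) == pd.Series(y).replace(
            {"Esophagus": "UpperGI", "Stomach": "UpperGI"}).to_numpy()).mean()
        assert acc > 0.8

    def test_trace_lengths_bounded_by_levels(self, small_encoded):
        X, y = small_encoded
        clf = CascadeClassifier(vote_threshold=None, random_state=0).fit(X, y)
        _, traces = clf.predict_trace(X.iloc[:20])
        assert all(1 <= len(t) <= 7 for t in traces)

    def test_sklearn_params_round_trip(self):
        clf = CascadeClassifier(vote_threshold=4, route_threshold=0.6)
        params = clf.get_params()
        assert params["vote_threshold"] == 4
        clone = CascadeClassifier(**params)
        assert clone.get_params() == params
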