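import warnings

import numpy as np
import pandas as pd
import pytest

from oncocascade.data_io import DomainError
from oncocascade.vote_select import (
    MajorityVoteSelector,
    chi_square_scores,
    extra_trees_importance,
    forest_importance,
    iv_strength,
    l1_select,
    majority_vote_select,
    rfe_select,
    woe_iv,
)


class TestWoeIV:
    def test_equal_class_proportions_give_zero_iv(self):
        # two bins, both with 50/50 class mix
        x = np.r_[np.zeros(100), np.ones(100)]
        y = np.r_[np.tile([0, 1], 50), np.tile([0, 1], 50)]
        iv, table = woe_iv(x, y)
        assert iv == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(table.woe, 0.0, atol=1e-12)

    def test_two_bin_hand_arithmetic(self):
        # bin A: 80 pos / 20 neg; bin B: 20 pos / 80 neg
        x = np.r_[np.zeros(100), np.ones(100)]
        y = np.r_[np.ones(80), np.zeros(20), np.ones(20), np.zeros(80)].astype(int)
        iv, table = woe_iv(x, y)
        expected = 0.6 * np.log(4) + (-0.6) * np.log(0.25)
        assert iv == pytest.approx(expected, rel=1e-12)
        assert iv == pytest.approx(1.6636, abs=1e-4)
        np.testing.assert_allclose(table.c1, [0.8, 0.2])
        np.testing.assert_allclose(table.c2, [0.2, 0.8])

    def test_bin_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=500)
        y = (rng.random(500) < 0.4).astype(int)
        _, table = woe_iv(x, y)
        assert table.c1.sum() == pytest.approx(1.0)
        assert table.c2.sum() == pytest.approx(1.0)

    def test_monotone_binning_respects_bounds(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        y = (rng.random(2000) < 1 / (1 + np.exp(-2 * x))).astype(int)
        _, table = woe_iv(x, y, bins=3, max_bins=20)
        assert 3 <= len(table.woe) <= 20
        d = np.diff(table.woe)
        assert np.all(d >= -1e-12) or np.all(d <= 1e-12)

    def test_iv_nonnegative_over_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x = rng.lognormal(size=300)
            y = (rng.random(300) < 0.5).astype(int)
            iv, _ = woe_iv(x, y)
            assert iv >= -1e-12

    def test_constant_feature_warns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            iv, _ = woe_iv(np.ones(50), np.r_[np.ones(25), np.zeros(25)].astype(int))
        assert iv == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            woe_iv(np.arange(10.0), np.ones(10, dtype=int))

    @pytest.mark.parametrize(
        "iv, strength",
        [(0.01, "useless"), (0.05, "weak"), (0.25, "moderate"), (0.5, "strong")],
    )
    def test_strength_bands(self, iv, strength):
        assert iv_strength(iv) == strength


class TestChiSquare:
    @staticmethod
    def _table_to_xy(T, V, Y, Z):
        # above-median cell layout: rows (above, below) x cols (pos, neg)
        x = np.r_[np.ones(T + V), np.zeros(Y + Z)]
        y = np.r_[np.ones(T), np.zeros(V), np.ones(Y), np.zeros(Z)].astype(int)
        return pd.DataFrame({"f": x}), y

    def test_perfect_association_equals_n(self):
        X, y = self._table_to_xy(50, 0, 0, 50)
        assert chi_square_scores(X, y)["f"] == pytest.approx(100.0)

    def test_independence_is_zero(self):
        X, y = self._table_to_xy(25, 25, 25, 25)
        assert chi_square_scores(X, y)["f"] == pytest.approx(0.0, abs=1e-12)

    def test_textbook_observed_vs_expected(self):
        T, V, Y, Z = 30, 10, 20, 40
        X, y = self._table_to_xy(T, V, Y, Z)
        obs = np.array([[T, V], [Y, Z]], dtype=float)
        rows, cols, n = obs.sum(1), obs.sum(0), obs.sum()
        exp = np.outer(rows, cols) / n
        oracle = ((obs - exp) ** 2 / exp).sum()
        assert chi_square_scores(X, y)["f"] == pytest.approx(oracle, rel=1e-12)

    def test_degenerate_margin_scores_zero_with_warning(self):
        X = pd.DataFrame({"f": np.zeros(20)})
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        with pytest.warns(UserWarning, match="degenerate"):
            assert chi_square_scores(X, y)["f"] == 0.0

    def test_frequency_mode_matches_sklearn_convention(self, planted_binary):
        from sklearn.feature_selection import chi2

        X, y, _ = planted_binary
        scores = chi_square_scores(X, y, mode="frequency")
        expected, _ = chi2(X, y)
        np.testing.assert_allclose(scores.to_numpy(), expected)


class TestForestImportances:
    def test_perfect_predictor_tops_both_flavors(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 400)
        X = pd.DataFrame(rng.normal(size=(400, 6)), columns=[f"f{i}" for i in range(6)])
        X["f3"] = y.astype(float)  # alone determines the label
        for scores in (
            forest_importance(X, y, flavor="impurity", seed=0),
            forest_importance(X, y, flavor="oob_permutation", seed=0),
            extra_trees_importance(X, y, seed=0),
        ):
            assert scores.idxmax() == "f3"

    def test_impurity_scores_sum_to_one(self, planted_binary):
        X, y, _ = planted_binary
        assert forest_importance(X, y, seed=1).sum() == pytest.approx(1.0)
        assert extra_trees_importance(X, y, seed=1).sum() == pytest.approx(1.0)

    def test_pure_noise_importances_near_uniform(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(2000, 10)), columns=[f"f{i}" for i in range(10)])
        y = rng.integers(0, 2, 2000)
        scores = forest_importance(X, y, seed=0)
        assert scores.max() / scores.min() < 3

    def test_seed_determinism(self, planted_binary):
        X, y, _ = planted_binary
        a = extra_trees_importance(X, y, seed=5)
        b = extra_trees_importance(X, y, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_forest_and_extra_trees_agree_on_strong_signal(self, planted_binary):
        X, y, informative = planted_binary
        agree = 0
        for seed in range(10):
            rf_top = set(forest_importance(X, y, seed=seed).nlargest(4).index)
            et_top = set(extra_trees_importance(X, y, seed=seed).nlargest(4).index)
            agree += rf_top == et_top == set(informative)
        assert agree >= 9

    def test_oob_requires_bootstrap(self, planted_binary):
        X, y, _ = planted_binary
        with pytest.raises(DomainError, match="bootstrap"):
            forest_importance(X, y, flavor="oob_permutation", bootstrap=False)


class TestModelSelectors:
    def test_rfe_keep_all_is_identity(self, planted_binary):
        X, y, _ = planted_binary
        with pytest.warns(UserWarning, match="keeping all"):
            selected, order = rfe_select(X, y, n_keep=X.shape[1])
        assert selected == list(X.columns)
        assert order == []

    def test_rfe_separator_survives_to_the_end(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 300)
        X = pd.DataFrame(rng.normal(size=(300, 8)), columns=[f"f{i}" for i in range(8)])
        X["f5"] = (y - 0.5) * 2 + rng.normal(scale=0.05, size=300)
        selected, _ = rfe_select(X, y, n_keep=1)
        assert selected == ["f5"]

    def test_rfe_first_elimination_matches_single_fit_oracle(self, planted_binary):
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler

        X, y, _ = planted_binary
        Z = StandardScaler().fit_transform(X)
        coefs = np.abs(
            LogisticRegression(C=1.0, solver="lbfgs", max_iter=100, tol=1e-4)
            .fit(Z, y).coef_.ravel()
        )
        oracle_first = X.columns[np.argmin(coefs)]
        _, order = rfe_select(X, y, n_keep=4)
        assert order[0] == oracle_first

    def test_l1_keeps_informative_features(self, planted_binary):
        X, y, informative = planted_binary
        selected, mags = l1_select(X, y, C=1.0, n_keep=4)
        assert set(selected) == set(informative)
        assert (mags[informative] > 0).all()

    def test_l1_sparsity_monotone_in_c(self, planted_binary):
        X, y, _ = planted_binary
        _, weak = l1_select(X, y, C=0.01)
        _, strong = l1_select(X, y, C=1.0)
        assert (weak > 0).sum() <= (strong > 0).sum()

    def test_l1_degenerate_c_warns(self, planted_binary):
        X, y, _ = planted_binary
        with pytest.warns(UserWarning, match="zero"):
            l1_select(X, y, C=1e-6)


class TestMajorityVote:
    def test_brute_force_tally_on_hand_fixture(self, planted_binary, monkeypatch):
        """Tally must equal exhaustive enumeration over hand-assigned
        nomination sets."""
        import oncocascade.vote_select as vs

        features = ["a", "b", "c", "d", "e"]
        X = pd.DataFrame(np.zeros((4, 5)), columns=features)
        y = np.array([0, 1, 0, 1])
        nominations = {
            "iv": {"a", "b"},
            "chi2": {"a", "c"},
            "rf": {"b", "c"},
            "et": {"a", "d"},
            "rfe": {"a", "e"},
            "l1": {"b", "e"},
        }
        score_sets = {
            name: pd.Series([1.0 if f in kept else 0.0 for f in features], index=features)
            for name, kept in nominations.items()
        }
        monkeypatch.setattr(vs, "_iv_scores", lambda X, y, **k: score_sets["iv"])
        monkeypatch.setattr(vs, "chi_square_scores", lambda X, y, **k: score_sets["chi2"])
        monkeypatch.setattr(vs, "forest_importance", lambda X, y, **k: score_sets["rf"])
        monkeypatch.setattr(vs, "extra_trees_importance", lambda X, y, **k: score_sets["et"])
        monkeypatch.setattr(vs, "rfe_select", lambda X, y, n_keep: (sorted(nominations["rfe"]), []))
        monkeypatch.setattr(
            vs, "l1_select", lambda X, y, n_keep: (sorted(nominations["l1"]), score_sets["l1"])
        )
        tally = vs.majority_vote_select(X, y, threshold=3, n_keep=2)

        # independent brute-force count
        expected_votes = {
            f: sum(f in kept for kept in nominations.values()) for f in features
        }
        assert tally.votes.to_dict() == expected_votes
        assert tally.selected == [f for f in features if expected_votes[f] >= 3]
        assert tally.selected == ["a", "b"]  # a: 4 votes, b: 3 votes

    def test_unanimously_ignored_feature_excluded_everywhere(self, planted_binary):
        X, y, informative = planted_binary
        tally = majority_vote_select(X, y, threshold=1, seed=0)
        never = tally.votes[tally.votes == 0].index
        assert set(never).isdisjoint(tally.selected)

    def test_selected_set_shrinks_with_threshold(self, planted_binary):
        X, y, _ = planted_binary
        tally = majority_vote_select(X, y, threshold=2, seed=0)
        sizes = [(tally.votes >= t).sum() for t in (2, 3, 4)]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_informative_features_selected(self, planted_binary):
        X, y, informative = planted_binary
        tally = majority_vote_select(X, y, threshold=3, seed=0)
        assert set(informative) <= set(tally.selected)

    def test_single_feature_rejected(self):
        with pytest.raises(DomainError):
            majority_vote_select(pd.DataFrame({"a": [1.0, 2.0]}), np.array([0, 1]))


class TestMajorityVoteSelector:
    def test_transform_keeps_selected_columns(self, planted_binary):
        X, y, informative = planted_binary
        sel = MajorityVoteSelector(threshold=3, random_state=0).fit(X, y)
        Xt = sel.transform(X)
        assert Xt.shape == (len(X), len(sel.selected_features_))
        assert set(informative) <= set(sel.selected_features_)

    def test_works_inside_sklearn_pipeline(self, planted_binary):
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import Pipeline

        X, y, _ = planted_binary
        pipe = Pipeline(
            [("select", MajorityVoteSelector(threshold=3, random_state=0)),
             ("clf", LogisticRegression(max_iter=200))]
        ).fit(X, y)
        assert pipe.score(X, y) > 0.8

    def test_get_support_matches_selected(self, planted_binary):
        X, y, _ = planted_binary
        sel = MajorityVoteSelector(threshold=4, random_state=0).fit(X, y)
        assert list(X.columns[sel.get_support()]) == sel.selected_features_
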