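"""Nested CV protocol: catalogue, metrics, guards, aggregation."""

import numpy as np
import pandas as pd
import pytest

from restalpha.classify import (
    FEATURE_NAMES,
    FeatureCombination,
    SearchGrid,
    _fast_linear_fit,
    _make_model,
    _run_outer_fold,
    _standardize,
    aggregate_roc,
    classification_metrics,
    default_grid,
    enumerate_combinations,
    nested_cv,
    ranking_report,
)


def toy_features(n=48, seed=0, separation=0.0, right_effect=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 14))
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    X += separation * y[:, None]
    for j, name in enumerate(FEATURE_NAMES):
        if name.endswith("_R"):
            X[:, j] += right_effect * y
    df = pd.DataFrame(X, columns=FEATURE_NAMES)
    df["group"] = np.where(y == 1, "HSG", "LSG")
    df["subject_id"] = [f"s{i:02d}" for i in range(n)]
    return df


class TestCombinations:
    def test_default_catalogue_size(self):
        assert len(enumerate_combinations()) == 15

    def test_right_only_posterior_activity(self):
        combos = {c.name: c for c in enumerate_combinations()}
        c = combos["R:posterior-activity"]
        assert set(c.features) == {"iaf_posterior_R", "amp_posterior_R"}

    def test_no_contralateral_leakage(self):
        for c in enumerate_combinations():
            if c.scope == "R":
                assert not any(f.endswith("_L") for f in c.features)
            if c.scope == "L":
                assert not any(f.endswith("_R") for f in c.features)

    def test_inter_features_only_in_designated_sets(self):
        for c in enumerate_combinations():
            has_inter = any(f.endswith("_inter") for f in c.features)
            assert has_inter == (c.family_set == "all-activity+intra+inter")

    def test_lateralized_feature_in_wrong_scope_rejected(self):
        with pytest.raises(ValueError):
            FeatureCombination("bad", "R", "posterior-activity",
                               ("iaf_posterior_L",))

    def test_empty_catalogue_rejected(self):
        with pytest.raises(ValueError):
            enumerate_combinations(scopes=())
        with pytest.raises(ValueError):
            SearchGrid(combinations=[])


class TestMetrics:
    def test_perfect_confusion(self):
        m = classification_metrics(3, 0, 2, 0)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0
        assert m["balanced_accuracy"] == 1.0

    def test_reported_consistency_identity(self):
        m = classification_metrics(788, 212, 697, 303)
        assert m["balanced_accuracy"] * 100 == pytest.approx(74.25)

    def test_tied_scores_auc_half(self):
        m = classification_metrics(1, 1, 1, 1,
                                   y_true=np.array([1, 1, 0, 0]),
                                   scores=np.zeros(4))
        assert m["auc"] == pytest.approx(0.5)

    def test_single_class_fold_missing(self):
        m = classification_metrics(2, 0, 0, 0)
        assert np.isnan(m["specificity"]) and np.isnan(m["balanced_accuracy"])


class TestFastFitEquivalence:
    """The inner-loop solver path must agree with the public estimators."""

    @pytest.mark.parametrize("family", ["svm", "logreg"])
    @pytest.mark.parametrize("first_label", [0, 1])
    def test_decision_function_matches_public(self, family, first_label):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((30, 6))
        y = np.array(([first_label, 1 - first_label] * 15))
        Xv = rng.standard_normal((8, 6))
        for C in (0.1, 0.2, 0.3):
            w, b = _fast_linear_fit(family, C, X, y)
            ref = _make_model(family, C).fit(X, y)
            np.testing.assert_allclose(
                Xv @ w + b, ref.decision_function(Xv), atol=1e-4
            )


class TestStandardization:
    def test_training_statistics_only(self):
        rng = np.random.default_rng(2)
        train = rng.standard_normal((20, 3))
        test = rng.standard_normal((5, 3)) + 100.0  # gross outlier fold
        tr, te = _standardize(train, test)
        np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(tr.std(axis=0), 1.0, atol=1e-12)
        # test rows keep their offset: scaled by train statistics only
        assert te.mean() > 50.0


class TestNestedCV:
    def _small_grid(self):
        combos = enumerate_combinations(
            scopes=("R", "L"), family_sets=("posterior-activity",)
        )
        return SearchGrid(combinations=combos)

    def test_separable_cohort_perfect_scores(self):
        df = toy_features(seed=1, separation=6.0)
        rep = nested_cv(df, grid=self._small_grid(), n_repeats=2, seed=0)
        assert rep.summary["balanced_accuracy_mean"] == 1.0
        assert rep.summary["auc_mean"] == 1.0

    def test_reproducible_given_seed(self):
        df = toy_features(seed=2)
        g = self._small_grid()
        a = nested_cv(df, grid=g, n_repeats=2, seed=7)
        b = nested_cv(df, grid=g, n_repeats=2, seed=7)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.roc, b.roc)

    def test_null_features_chance_level(self):
        """Label-independent features: mean BA within 3 SD of chance."""
        df = toy_features(seed=3)
        rep = nested_cv(df, grid=self._small_grid(), n_repeats=20, seed=1)
        ba = rep.per_repetition["balanced_accuracy"]
        assert abs(ba.mean() - 0.5) < 3 * max(ba.std(ddof=1), 1e-6)

    def test_right_effect_prefers_right_combinations(self):
        df = toy_features(seed=4, right_effect=2.0)
        rep = nested_cv(df, grid=self._small_grid(), n_repeats=5, seed=2)
        freq = dict(zip(rep.selection_freq["combination"],
                        rep.selection_freq["selection_freq_pct"]))
        assert freq["R:posterior-activity"] > freq["L:posterior-activity"]

    def test_selection_frequencies_sum_to_100(self):
        df = toy_features(seed=5)
        rep = nested_cv(df, grid=self._small_grid(), n_repeats=3, seed=3)
        assert rep.selection_freq["selection_freq_pct"].sum() == pytest.approx(100.0)

    def test_single_combination_grid_full_frequency(self):
        combos = enumerate_combinations(scopes=("R",),
                                        family_sets=("posterior-activity",))
        df = toy_features(seed=6)
        rep = nested_cv(df, grid=SearchGrid(combinations=combos),
                        n_repeats=2, seed=4)
        table = ranking_report(rep)
        assert len(table) == 1
        assert table["selection_freq_pct"].iloc[0] == pytest.approx(100.0)

    def test_both_classes_required(self):
        df = toy_features(seed=7)
        df["group"] = "HSG"
        with pytest.raises(ValueError):
            nested_cv(df, grid=self._small_grid(), n_repeats=1, seed=0)

    def test_balanced_accuracy_identity_per_fold(self):
        df = toy_features(seed=8, separation=1.0)
        rep = nested_cv(df, grid=self._small_grid(), n_repeats=2, seed=5)
        r = rep.records.dropna(subset=["sensitivity", "specificity"])
        np.testing.assert_allclose(
            r["balanced_accuracy"],
            (r["sensitivity"] + r["specificity"]) / 2,
        )


class TestNoPeeking:
    def test_selection_blind_to_test_fold_features(self):
        df = toy_features(seed=9, separation=1.0)
        X = df[list(FEATURE_NAMES)].to_numpy()
        y = (df["group"] == "HSG").to_numpy().astype(int)
        fidx = {f: i for i, f in enumerate(FEATURE_NAMES)}
        grid = default_grid()
        test_idx = np.arange(0, 5)
        train_idx = np.arange(5, 48)
        sel_a, _, _, _ = _run_outer_fold(X, y, train_idx, test_idx, grid,
                                         fidx, 10, seed=123)
        X_corrupt = X.copy()
        X_corrupt[test_idx] = 1e6  # arbitrary garbage in the held-out fold
        sel_b, _, _, _ = _run_outer_fold(X_corrupt, y, train_idx, test_idx,
                                         grid, fidx, 10, seed=123)
        assert sel_a[0].name == sel_b[0].name
        assert sel_a[1] == sel_b[1] and sel_a[2] == sel_b[2]

    def test_outlier_in_test_fold_does_not_move_scaler(self):
        df = toy_features(seed=10, separation=1.0)
        X = df[list(FEATURE_NAMES)].to_numpy()
        y = (df["group"] == "HSG").to_numpy().astype(int)
        fidx = {f: i for i, f in enumerate(FEATURE_NAMES)}
        grid = default_grid()
        test_idx = np.arange(0, 5)
        train_idx = np.arange(5, 48)
        _, metrics_a, _, scores_a = _run_outer_fold(
            X, y, train_idx, test_idx, grid, fidx, 10, seed=55)
        X_shift = X.copy()
        X_shift[train_idx] += 0.0  # unchanged training rows
        X_shift[test_idx] += 1e3   # shifted test rows
        _, metrics_b, _, scores_b = _run_outer_fold(
            X_shift, y, train_idx, test_idx, grid, fidx, 10, seed=55)
        # scaling fitted on training rows only: shifted test scores move by a
        # deterministic offset, while the trained model itself is unchanged
        assert metrics_a != metrics_b or not np.allclose(scores_a, scores_b)
        _, metrics_c, _, scores_c = _run_outer_fold(
            X, y, train_idx, test_idx, grid, fidx, 10, seed=55)
        np.testing.assert_allclose(scores_a, scores_c)


class TestRocAggregation:
    def _plateau_fold(self, tpr_level):
        """A fold whose ROC has TPR == tpr_level for FPR in [0.4, 0.6]."""
        n_pos = 10
        k = int(round(tpr_level * n_pos))
        y, s = [], []
        score = 100.0
        for _ in range(4):            # 4 negatives first (FPR ramps to 0.4)
            y.append(0); s.append(score); score -= 1
        for _ in range(k):            # positives: TPR reaches tpr_level
            y.append(1); s.append(score); score -= 1
        for _ in range(6):            # remaining negatives
            y.append(0); s.append(score); score -= 1
        for _ in range(n_pos - k):    # remaining positives
            y.append(1); s.append(score); score -= 1
        return np.array(y), np.array(s)

    def test_identical_folds_zero_sd(self):
        fold = self._plateau_fold(0.5)
        roc = aggregate_roc([fold, fold, fold])
        np.testing.assert_allclose(roc["tpr_sd"], 0.0, atol=1e-12)

    def test_hand_computed_mean_and_sd(self):
        roc = aggregate_roc([self._plateau_fold(0.2), self._plateau_fold(0.8)])
        at_half = roc[np.isclose(roc["fpr"], 0.5)].iloc[0]
        assert at_half["tpr_mean"] == pytest.approx(0.5, abs=1e-9)
        assert at_half["tpr_sd"] == pytest.approx(np.std([0.2, 0.8], ddof=1), abs=1e-9)

    def test_separable_fold_passes_origin_corner(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        s = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        roc = aggregate_roc([(y, s), (y, s)])
        near_zero = roc[roc["fpr"] > 0].iloc[0]
        assert near_zero["tpr_mean"] == pytest.approx(1.0)

    def test_single_class_folds_skipped(self):
        good = self._plateau_fold(0.5)
        bad = (np.ones(5), np.arange(5.0))
        roc = aggregate_roc([good, good, bad])
        assert roc.attrs["n_curves"] == 2
        assert roc.attrs["n_skipped"] == 1
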