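"""Label derivation, nested-CV training, frozen bundles and rank statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucmorph import subtype as st
from nucmorph.subtype import ClassifierBundle, FoldModel, MarkerStatus

POS, NEG, UNK = "positive", "negative", "unknown"


class TestLabelDerivation:
    @pytest.mark.parametrize(
        "her2,er,pr,expected",
        [
            (POS, POS, POS, "HER2+"),
            (POS, NEG, NEG, "HER2+"),
            (NEG, NEG, POS, "HR+"),
            (NEG, POS, NEG, "HR+"),
            (NEG, POS, POS, "HR+"),
            (NEG, NEG, NEG, "TNBC"),
            (UNK, POS, POS, None),
            (NEG, UNK, UNK, None),
            (NEG, POS, UNK, "HR+"),  # ER+ alone suffices under HER2-
        ],
    )
    def test_three_class_rules(self, her2, er, pr, expected):
        assert st.derive_subtype3(MarkerStatus(her2, er, pr)) == expected

    @pytest.mark.parametrize(
        "her2,er,expected",
        [
            (POS, POS, "TPBC"),
            (POS, NEG, "HER2+"),
            (NEG, POS, "HR+"),
            (NEG, NEG, "TNBC"),
            (UNK, POS, None),
            (POS, UNK, None),
        ],
    )
    def test_four_class_rules(self, her2, er, expected):
        assert st.derive_subtype4(MarkerStatus(her2, er, NEG)) == expected

    def test_vectorized_derivation_matches_scalar(self):
        rows = list(itertools.product([POS, NEG], repeat=3))
        clinical = pd.DataFrame(rows, columns=["her2", "er", "pr"])
        labels = st.derive_labels(clinical, scheme=3)
        for (her2, er, pr), label in zip(rows, labels):
            assert label == st.derive_subtype3(MarkerStatus(her2, er, pr))


class TestAuc:
    def test_perfect_separation(self):
        assert st.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_interleaved_hand_value(self):
        assert st.auc([0.8, 0.6, 0.4, 0.2], [1, 0, 1, 0]) == 0.75

    def test_all_tied_scores(self):
        assert st.auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            st.auc([0.1, 0.2], [1, 1])

    def test_agrees_with_all_pairs_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.uniform(size=n), 2)  # force some ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = sum(
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg
            )
            assert st.auc(scores, labels) == pytest.approx(
                wins / (len(pos) * len(neg)), abs=1e-12
            )


class TestNestedCv:
    def _separable(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame({"f": y + rng.normal(0, 0.01, n), "noise": rng.normal(size=n)})
        return X, y

    def test_perfectly_separable_oof_auc_one(self):
        X, y = self._separable()
        _, oof = st.nested_cv_train(X, y, seed=0)
        assert st.auc(oof, y) == 1.0

    def test_oof_vector_is_a_complete_partition(self):
        X, y = self._separable(n=60)
        _, oof = st.nested_cv_train(X, y, seed=1)
        assert len(oof) == 60
        assert not np.isnan(oof).any()

    def test_single_class_raises(self):
        X, _ = self._separable()
        with pytest.raises(ValueError, match="both classes"):
            st.nested_cv_train(X, np.zeros(len(X)), seed=0)

    def test_bundle_has_five_fold_models(self):
        X, y = self._separable()
        bundle, _ = st.nested_cv_train(X, y, seed=0)
        assert len(bundle.folds) == 5
        assert all(
            (f.feature_min <= f.feature_max).all() for f in bundle.folds
        )

    def test_no_leakage_from_held_out_folds(self):
        """Perturbing the test-fold feature values must leave every trained
        fold model bit-identical (scaling and C depend on training data only)."""
        X, y = self._separable(n=80, seed=3)
        bundle, _ = st.nested_cv_train(X, y, seed=7)
        from sklearn.model_selection import StratifiedKFold

        # same deterministic outer split the trainer uses
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=7)
        X2 = X.copy()
        _, test0 = next(iter(skf.split(np.zeros(len(y)), y)))
        X2.iloc[test0] = 1e6  # arbitrary perturbation of fold-0 test samples
        bundle2, _ = st.nested_cv_train(X2, y, seed=7)
        f1, f2 = bundle.folds[0], bundle2.folds[0]
        np.testing.assert_array_equal(f1.coef, f2.coef)
        np.testing.assert_array_equal(f1.feature_min, f2.feature_min)
        assert f1.intercept == f2.intercept and f1.C == f2.C

    def test_determinism_same_seed_same_bundle(self):
        X, y = self._separable(n=50, seed=4)
        b1, oof1 = st.nested_cv_train(X, y, seed=5)
        b2, oof2 = st.nested_cv_train(X, y, seed=5)
        np.testing.assert_array_equal(oof1, oof2)
        for f1, f2 in zip(b1.folds, b2.folds):
            np.testing.assert_array_equal(f1.coef, f2.coef)

    def test_bundle_json_round_trip(self, tmp_path):
        X, y = self._separable(n=50, seed=4)
        bundle, _ = st.nested_cv_train(X, y, seed=5, subtype="HER2+")
        path = tmp_path / "bundle.json"
        bundle.to_json(path)
        back = ClassifierBundle.from_json(path)
        assert back.subtype == "HER2+" and back.features == list(X.columns)
        scores1 = st.predict_external(bundle, X)
        scores2 = st.predict_external(back, X)
        np.testing.assert_array_equal(scores1, scores2)


class TestPredictExternal:
    def _bundle(self, folds):
        return ClassifierBundle(subtype="s", features=["a", "b"], folds=folds)

    def _fold(self, coef=(1.0, -1.0), intercept=0.5):
        return FoldModel(
            feature_min=np.zeros(2),
            feature_max=np.ones(2),
            coef=np.asarray(coef, dtype=float),
            intercept=intercept,
            C=1.0,
        )

    def test_identical_folds_equal_single_model(self):
        X = pd.DataFrame({"a": [0.2, 0.8], "b": [0.1, 0.9]})
        five = self._bundle([self._fold()] * 5)
        one = self._bundle([self._fold()])
        np.testing.assert_allclose(
            st.predict_external(five, X), st.predict_external(one, X)
        )

    def test_zero_model_scores_half(self):
        X = pd.DataFrame({"a": [0.0, 5.0], "b": [-3.0, 1.0]})
        bundle = self._bundle([self._fold(coef=(0, 0), intercept=0.0)] * 5)
        np.testing.assert_array_equal(st.predict_external(bundle, X), [0.5, 0.5])

    def test_out_of_range_inputs_are_clamped(self):
        bundle = self._bundle([self._fold(coef=(1.0, 0.0), intercept=0.0)])
        X_far = pd.DataFrame({"a": [100.0], "b": [0.5]})
        X_edge = pd.DataFrame({"a": [1.0], "b": [0.5]})
        np.testing.assert_allclose(
            st.predict_external(bundle, X_far), st.predict_external(bundle, X_edge)
        )

    def test_missing_feature_named_in_error(self):
        bundle = self._bundle([self._fold()])
        with pytest.raises(KeyError, match="b"):
            st.predict_external(bundle, pd.DataFrame({"a": [1.0]}))

    def test_repeat_application_bit_identical(self):
        X = pd.DataFrame({"a": [0.3, 0.6], "b": [0.4, 0.2]})
        bundle = self._bundle([self._fold(), self._fold(coef=(2.0, 0.5))])
        np.testing.assert_array_equal(
            st.predict_external(bundle, X), st.predict_external(bundle, X)
        )


class TestAssignSubtype:
    def test_argmax(self):
        labels, ties = st.assign_subtype(
            {"HER2+": [0.9], "HR+": [0.3], "TNBC": [0.1]}
        )
        assert labels == ["HER2+"] and not ties[0]

    def test_tie_goes_to_declared_order_with_flag(self):
        labels, ties = st.assign_subtype(
            {"HER2+": [0.5], "HR+": [0.5], "TNBC": [0.2]},
            order=["HER2+", "HR+", "TNBC"],
        )
        assert labels == ["HER2+"] and ties[0]

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            st.assign_subtype({"a": [0.1, 0.2], "b": [0.3]})


class TestFeatureImportance:
    def _bundle_with_coefs(self, rows):
        folds = [
            FoldModel(np.zeros(1), np.ones(1), np.array([c], dtype=float), 0.0, 1.0)
            for c in rows
        ]
        return ClassifierBundle(subtype="s", features=["f"], folds=folds)

    def test_constant_coefficients_zero_width(self):
        imp = st.feature_importance(self._bundle_with_coefs([1, 1, 1, 1, 1]))
        assert imp.loc["f", "mean"] == 1.0
        assert imp.loc["f", "ci_lower"] == imp.loc["f", "ci_upper"] == 1.0

    def test_negative_sign(self):
        imp = st.feature_importance(self._bundle_with_coefs([-1] * 5))
        assert imp.loc["f", "sign"] == -1.0

    def test_t_interval_matches_direct_computation(self):
        coefs = [0.0, 0.0, 0.0, 0.0, 5.0]
        imp = st.feature_importance(self._bundle_with_coefs(coefs))
        mean = np.mean(coefs)
        half = stats.t.ppf(0.975, 4) * np.std(coefs, ddof=1) / np.sqrt(5)
        assert imp.loc["f", "ci_lower"] == pytest.approx(mean - half, abs=1e-9)
        assert imp.loc["f", "ci_upper"] == pytest.approx(mean + half, abs=1e-9)
        assert imp.loc["f", "ci_lower"] <= imp.loc["f", "mean"] <= imp.loc["f", "ci_upper"]


class TestAssociateFeatures:
    def test_fully_separated_groups_give_extreme_r(self):
        X = pd.DataFrame({"f": [1, 2, 3, 4, 5, 6]})
        out = st.associate_features(X, [True, True, True, False, False, False])
        assert out.loc["f", "rank_biserial"] == pytest.approx(-1.0)
        out = st.associate_features(X, [False, False, False, True, True, True])
        assert out.loc["f", "rank_biserial"] == pytest.approx(+1.0)

    def test_identical_groups_give_zero(self):
        X = pd.DataFrame({"f": [1, 2, 3, 1, 2, 3]})
        out = st.associate_features(X, [True, True, True, False, False, False])
        assert out.loc["f", "rank_biserial"] == pytest.approx(0.0)

    def test_r_matches_pair_enumeration(self, rng):
        for _ in range(10):
            a = rng.integers(0, 10, size=8).astype(float)
            b = rng.integers(0, 10, size=6).astype(float)
            X = pd.DataFrame({"f": np.concatenate([a, b])})
            mask = np.r_[np.ones(8, bool), np.zeros(6, bool)]
            u = sum(
                1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b
            )
            expected = 2 * u / (len(a) * len(b)) - 1
            out = st.associate_features(X, mask)
            assert out.loc["f", "rank_biserial"] == pytest.approx(expected, abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            st.associate_features(pd.DataFrame({"f": [1.0, 2.0]}), [True, True])
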