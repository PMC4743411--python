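"""Powerset encoding, binary relevance, classifiers chain and the CV harness."""

import numpy as np
import pandas as pd
import pytest

from selprof.collate import LabelMatrix
from selprof.multilabel import (PowersetEncoding, assign_folds, cross_validate,
                                cross_validate_powerset, fit_binary_relevance,
                                fit_classifiers_chain, fit_label_powerset,
                                powerset_encode, predict, subset_classes)
from selprof.synthetic import GeneratorSpec, generate_labels


def _dense(rows, columns=("P-gp", "BCRP")):
    return LabelMatrix(labels=pd.DataFrame(rows, columns=list(columns),
                                           dtype=float))


def _separable(n=120, seed=0):
    """Two labels, each perfectly determined by its own feature."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=(n, 2)).astype(float)
    X = pd.DataFrame({"f0": y[:, 0] + 0.01 * rng.random(n),
                      "f1": y[:, 1] + 0.01 * rng.random(n)})
    return X, _dense(y)


class TestPowerset:
    @pytest.mark.parametrize("labels,expected", [
        ((0, 0), 0),   # non-inhibitors
        ((1, 0), 1),   # P-gp-selective
        ((0, 1), 2),   # BCRP-selective
        ((1, 1), 3)])  # dual
    def test_class_table(self, labels, expected):
        enc = PowersetEncoding(("P-gp", "BCRP"))
        assert enc.class_of(labels) == expected

    def test_round_trip_all_tuples(self):
        enc = PowersetEncoding(("a", "b", "c"))
        for cls in range(8):
            assert enc.class_of(enc.decode(cls)) == cls

    def test_all_combinations_give_four_classes(self):
        classes, _ = powerset_encode(_dense([[0, 0], [1, 0], [0, 1], [1, 1]]))
        assert sorted(set(classes)) == [0, 1, 2, 3]

    def test_missing_cell_rejected(self):
        with pytest.raises(ValueError, match="dense"):
            powerset_encode(_dense([[1, np.nan]]))


class TestSubsetClasses:
    def test_published_dense_counts(self):
        # class balance 27/48/39/47; dropping the non-inhibitors leaves 134
        classes = np.repeat([0, 1, 2, 3], [27, 48, 39, 47])
        assert subset_classes(classes, {1, 2, 3}).size == 134

    def test_keep_all_identity(self):
        classes = np.array([0, 1, 2, 3, 2])
        assert np.array_equal(subset_classes(classes, {0, 1, 2, 3}), classes)

    def test_selective_only(self):
        classes = np.array([0, 1, 2, 3])
        kept, X = subset_classes(classes, {1, 2}, np.arange(4))
        assert kept.tolist() == [1, 2] and X.tolist() == [1, 2]

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            subset_classes(np.array([0, 0]), {3})


class TestBinaryRelevance:
    def test_one_submodel_per_label(self):
        X, Y = _separable()
        model = fit_binary_relevance(X, Y, "logreg")
        assert set(model.submodels) == {"P-gp", "BCRP"}

    def test_missing_rows_masked(self):
        X, Y = _separable()
        Y.labels.iloc[:40, 1] = np.nan
        model = fit_binary_relevance(X, Y, "logreg")
        scores, labels = predict(model, X)
        # the model still trains and predicts for every compound
        assert labels.shape == (len(X), 2)

    def test_separable_data_learned_perfectly(self):
        X, Y = _separable()
        model = fit_binary_relevance(X, Y, "rf", seed=0)
        _, labels = predict(model, X)
        assert (labels.to_numpy() == Y.labels.to_numpy()).all()

    def test_single_class_label_is_an_error(self):
        X, Y = _separable()
        Y.labels["BCRP"] = 1.0
        with pytest.raises(ValueError, match="BCRP"):
            fit_binary_relevance(X, Y, "logreg")


class TestClassifiersChain:
    def test_second_model_gets_one_extra_feature(self):
        X, Y = _separable()
        model = fit_classifiers_chain(X, Y, "logreg", seed=0,
                                      chain_order=("P-gp", "BCRP"))
        first = model.submodels["P-gp"]
        second = model.submodels["BCRP"]
        assert second.n_features_in_ == first.n_features_in_ + 1

    def test_single_label_chain_equals_binary_relevance(self):
        X, Y = _separable()
        Y1 = LabelMatrix(labels=Y.labels[["P-gp"]])
        cc = fit_classifiers_chain(X, Y1, "rf", seed=7)
        br = fit_binary_relevance(X, Y1, "rf", seed=7)
        s_cc, _ = predict(cc, X)
        s_br, _ = predict(br, X)
        assert np.array_equal(s_cc.to_numpy(), s_br.to_numpy())

    def test_chain_order_recorded_and_replayed(self):
        X, Y = _separable()
        model = fit_classifiers_chain(X, Y, "logreg", seed=3)
        assert sorted(model.chain_order) == ["BCRP", "P-gp"]
        s1, _ = predict(model, X)
        s2, _ = predict(model, X)
        assert np.array_equal(s1.to_numpy(), s2.to_numpy())


class TestPredict:
    def test_threshold_at_half(self):
        X, Y = _separable()
        model = fit_binary_relevance(X, Y, "logreg")
        scores, labels = predict(model, X)
        assert ((scores >= 0.5).astype(int) == labels).all().all()

    def test_repeat_predictions_identical(self):
        X, Y = _separable()
        model = fit_binary_relevance(X, Y, "rf", seed=1)
        a = predict(model, X)[0].to_numpy()
        b = predict(model, X)[0].to_numpy()
        assert np.array_equal(a, b)

    def test_powerset_prediction_decodes_to_valid_tuple(self):
        X, Y = _separable()
        model = fit_label_powerset(X, Y, "rf", seed=0)
        scores, labels = predict(model, X)
        assert set(np.unique(labels.to_numpy())) <= {0, 1}
        assert scores.to_numpy().min() >= 0 and scores.to_numpy().max() <= 1

    def test_schema_mismatch_rejected(self):
        X, Y = _separable()
        model = fit_binary_relevance(X, Y, "logreg")
        with pytest.raises(ValueError, match="schema|feature count"):
            predict(model, X.iloc[:, :1])


class TestCrossValidate:
    def test_perfect_predictor_scores_one(self):
        X, Y = _separable(n=200)
        report = cross_validate(X, Y, "binary_relevance", "rf", folds=5,
                                seed=0)
        assert report.macro_accuracy == pytest.approx(1.0)
        assert report.macro_mcc == pytest.approx(1.0)

    def test_label_permutation_null_has_no_signal(self):
        rng = np.random.default_rng(0)
        X, Y = _separable(n=400, seed=1)
        Y.labels.iloc[:, 0] = rng.permutation(Y.labels.iloc[:, 0].to_numpy())
        Y.labels.iloc[:, 1] = rng.permutation(Y.labels.iloc[:, 1].to_numpy())
        report = cross_validate(X, Y, "binary_relevance", "logreg", folds=5,
                                seed=0)
        assert abs(report.macro_mcc) < 0.15
        assert report.macro_auc == pytest.approx(0.5, abs=0.1)

    def test_repeats_record_their_seeds(self):
        X, Y = _separable()
        report = cross_validate(X, Y, "binary_relevance", "logreg", folds=4,
                                repeats=2, seed=5)
        assert report.cv_spec["repeat_seeds"] == [5, 1005]

    def test_folds_identical_across_strategies(self):
        X, Y = _separable(n=100)
        f1 = assign_folds(Y, 5, seed=9)
        f2 = assign_folds(Y, 5, seed=9)
        assert np.array_equal(f1, f2)

    def test_compound_entirely_in_one_fold(self):
        X, Y = _separable(n=60)
        folds = assign_folds(Y, 6, seed=0)
        assert folds.shape == (60,) and set(folds) == set(range(6))

    def test_macro_is_mean_of_per_label(self):
        X, Y = _separable(n=150, seed=3)
        report = cross_validate(X, Y, "binary_relevance", "logreg", folds=5,
                                seed=2)
        expected = np.mean([report.per_label[lab]["auc"]
                            for lab in ("P-gp", "BCRP")])
        assert report.macro_auc == pytest.approx(expected)


class TestSubsetAccuracyProperty:
    def test_exact_match_stricter_than_macro_accuracy(self):
        """Powerset (exact-match) accuracy never exceeds the macro-averaged
        per-label accuracy of the same predictions."""
        rng = np.random.default_rng(4)
        truth = rng.integers(0, 2, size=(500, 2))
        pred = truth.copy()
        flip = rng.random((500, 2)) < 0.2
        pred[flip] = 1 - pred[flip]
        exact = (truth == pred).all(axis=1).mean()
        macro = (truth == pred).mean(axis=0).mean()
        assert exact <= macro + 1e-12

    def test_powerset_cv_on_generator_classes(self):
        spec = GeneratorSpec(n_compounds=200)
        truth, classes = generate_labels(spec, seed=0)
        from selprof.synthetic import generate_descriptors

        X = generate_descriptors(classes, seed=1)
        out = cross_validate_powerset(X, classes, "rf", folds=5, seed=0)
        assert 0.0 <= out["accuracy"] <= 1.0 and out["auc"] > 0.6
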