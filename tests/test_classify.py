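"""Classification-harness arithmetic, calibration and SVM interpretation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from entrotext.classify import (
    FAMILIES,
    BinaryEvalResult,
    FamilyReport,
    SplitSpec,
    evaluate_all,
    linear_svm_coefficients,
    mean_boundary_distance,
    rank_coefficients,
    stratified_split,
    train_eval_pair,
)
from entrotext.features import FEATURE_COLUMNS


def make_table(n_per_class, means, sd=1.0, seed=0):
    """Gaussian six-feature table with per-class mean vectors."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, mu in means.items():
        X = rng.normal(loc=mu, scale=sd, size=(n_per_class, 6))
        for i, x in enumerate(X):
            rows.append({"doc_id": f"{label}/{i}", "class_label": label,
                         **dict(zip(FEATURE_COLUMNS, x))})
    return pd.DataFrame(rows)


class TestStratifiedSplit:
    def test_840_rows_split_630_210(self):
        table = make_table(420, {"a": np.zeros(6), "b": np.ones(6)})
        train, test = stratified_split(table, SplitSpec(seed=3))
        assert len(train) == 630
        assert len(test) == 210
        assert set(train.index).isdisjoint(test.index)
        assert train["class_label"].value_counts()["a"] == 315

    def test_same_seed_identical(self):
        table = make_table(20, {"a": np.zeros(6), "b": np.ones(6)})
        t1, _ = stratified_split(table, SplitSpec(seed=7))
        t2, _ = stratified_split(table, SplitSpec(seed=7))
        assert list(t1.index) == list(t2.index)

    def test_fraction_one_rejected(self):
        with pytest.raises(ValueError, match="train_fraction"):
            SplitSpec(train_fraction=1.0)

    def test_tiny_class_rejected(self):
        table = make_table(3, {"a": np.zeros(6), "b": np.ones(6)})
        with pytest.raises(ValueError, match="< 4 rows"):
            stratified_split(table, SplitSpec())


class TestTrainEvalPair:
    def test_well_separated_classes_near_perfect(self):
        """Classes 5+ pooled SDs apart on one feature: accuracy >= 0.99.

        At 6 sigma separation the Bayes error is ~Phi(-3) = 0.0013 per test
        point, so every family should clear 0.99 with 200 test points.
        """
        mu_b = np.zeros(6)
        mu_b[0] = 6.0
        table = make_table(400, {"a": np.zeros(6), "b": mu_b}, sd=1.0, seed=1)
        train, test = stratified_split(table, SplitSpec(seed=1))
        for family in FAMILIES:
            result = train_eval_pair(train, test, family, seed=1)
            assert result.accuracy >= 0.99, family
            assert result.auc >= 0.99, family

    def test_perfectly_separable_1d_auc_one(self):
        table = make_table(30, {"a": np.zeros(6), "b": np.zeros(6)}, sd=0.0)
        table.loc[table["class_label"] == "a", "word_h1"] = np.linspace(0, 1, 30)
        table.loc[table["class_label"] == "b", "word_h1"] = np.linspace(2, 3, 30)
        train, test = stratified_split(table, SplitSpec(seed=2))
        result = train_eval_pair(train, test, "svm", seed=2)
        assert result.auc == 1.0

    def test_null_classes_near_chance(self):
        """Identically distributed classes: mean accuracy/AUC ~ 0.5 over seeds."""
        accs, aucs = [], []
        for seed in range(20):
            table = make_table(60, {"a": np.zeros(6), "b": np.zeros(6)}, seed=seed)
            train, test = stratified_split(table, SplitSpec(seed=seed))
            r = train_eval_pair(train, test, "logistic", seed=seed)
            accs.append(r.accuracy)
            aucs.append(r.auc)
        assert abs(np.mean(accs) - 0.5) <= 0.07
        assert abs(np.mean(aucs) - 0.5) <= 0.08

    def test_single_class_train_rejected(self):
        table = make_table(10, {"a": np.zeros(6)})
        with pytest.raises(ValueError, match="exactly 2"):
            train_eval_pair(table, table, "svm")


class TestEvaluateAll:
    def test_family_means_are_exact_pair_means(self):
        table = make_table(
            30,
            {"a": np.zeros(6), "b": np.ones(6) * 2, "c": np.ones(6) * 4},
            seed=5,
        )
        reports, results = evaluate_all(table, ("svm", "knn"), SplitSpec(seed=5))
        for report in reports:
            pair_aucs = [r.auc for r in results if r.family == report.family]
            assert report.mean_auc == pytest.approx(np.mean(pair_aucs), abs=1e-15)
            assert len(report.pair_results) == 3

    def test_mean_arithmetic(self):
        rs = [
            BinaryEvalResult(("a", "b"), "svm", 0.9, 0.9),
            BinaryEvalResult(("a", "c"), "svm", 0.8, 0.8),
            BinaryEvalResult(("b", "c"), "svm", 0.7, 0.7),
        ]
        mean = float(np.mean([r.auc for r in rs]))
        assert mean == pytest.approx(0.8, abs=1e-15)


class TestCoefficients:
    # printed coefficients of a learner-vs-translated linear SVM, used as a
    # fixed input to the ranking rule
    TABLE3 = {
        "pos_h2": 1.31993,
        "word_h3": -0.91945,
        "pos_h3": -0.53208,
        "word_h2": -0.45514,
        "pos_h1": -0.33885,
        "word_h1": 0.26481,
    }

    def test_reference_coefficients_rank_1_to_6(self):
        ranks = rank_coefficients(self.TABLE3)
        assert ranks == {
            "pos_h2": 1, "word_h3": 2, "pos_h3": 3,
            "word_h2": 4, "pos_h1": 5, "word_h1": 6,
        }

    def test_tied_magnitudes_use_fixed_feature_order(self):
        coefs = {f: (-1.0) ** i for i, f in enumerate(FEATURE_COLUMNS)}
        ranks = rank_coefficients(coefs)
        assert [f for f, _ in sorted(ranks.items(), key=lambda kv: kv[1])] == list(
            FEATURE_COLUMNS
        )

    def test_single_informative_feature_dominates(self):
        mu_b = np.zeros(6)
        mu_b[0] = 3.0
        table = make_table(100, {"a": np.zeros(6), "b": mu_b}, seed=3)
        train, test = stratified_split(table, SplitSpec(seed=3))
        _, model = train_eval_pair(train, test, "svm", seed=3, return_model=True)
        report = linear_svm_coefficients(model, ("a", "b"))
        assert report.importance_rank["word_h1"] == 1
        assert abs(report.coefficients["word_h1"]) > max(
            abs(report.coefficients[f]) for f in FEATURE_COLUMNS[1:]
        )
        # class "a" sits at lower word_h1, so positive coefficients (which
        # predict "a") must be negative on word_h1
        assert report.positive_class == "a"
        assert report.coefficients["word_h1"] < 0

    def test_ranks_are_permutation(self):
        ranks = rank_coefficients(self.TABLE3)
        assert sorted(ranks.values()) == [1, 2, 3, 4, 5, 6]

    def test_nonlinear_model_rejected(self):
        model = Pipeline([("s", StandardScaler()), ("clf", SVC(kernel="rbf"))])
        X = np.random.default_rng(0).normal(size=(20, 6))
        y = np.array(["a"] * 10 + ["b"] * 10)
        model.fit(X, y)
        with pytest.raises(ValueError, match="linear"):
            linear_svm_coefficients(model, ("a", "b"))


class TestBoundaryDistance:
    @staticmethod
    def _fixed_model(w, b):
        class Linear:
            coef_ = np.array([w])
            intercept_ = np.array([b])

            def decision_function(self, X):
                return X @ np.asarray(w) + b

        return Linear()

    def test_unit_geometry(self):
        w = [1.0, 0, 0, 0, 0, 0]
        model = self._fixed_model(w, 0.0)
        pts = pd.DataFrame(
            [dict(zip(FEATURE_COLUMNS, [1, 0, 0, 0, 0, 0])),
             dict(zip(FEATURE_COLUMNS, [-1, 0, 0, 0, 0, 0]))]
        )
        report = mean_boundary_distance(model, pts, ("a", "b"))
        assert report.mean_distance == pytest.approx(1.0)

    def test_points_on_hyperplane(self):
        model = self._fixed_model([0, 1.0, 0, 0, 0, 0], 0.0)
        pts = pd.DataFrame([dict(zip(FEATURE_COLUMNS, np.zeros(6)))] * 3)
        report = mean_boundary_distance(model, pts, ("a", "b"))
        assert report.mean_distance == 0.0

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        pts = pd.DataFrame(rng.normal(size=(15, 6)), columns=list(FEATURE_COLUMNS))
        w = [0.3, -1.2, 0.5, 0.0, 2.0, -0.7]
        d1 = mean_boundary_distance(self._fixed_model(w, 0.4), pts, ("a", "b"))
        w10 = [10 * v for v in w]
        d2 = mean_boundary_distance(self._fixed_model(w10, 4.0), pts, ("a", "b"))
        assert d1.mean_distance == pytest.approx(d2.mean_distance, rel=1e-12)

    def test_zero_weight_rejected(self):
        model = self._fixed_model([0.0] * 6, 0.0)
        pts = pd.DataFrame([dict(zip(FEATURE_COLUMNS, np.zeros(6)))])
        with pytest.raises(ValueError, match="w"):
            mean_boundary_distance(model, pts, ("a", "b"))

    def test_midway_class_geometry(self):
        """B midway between A and C: the extreme pair has the largest distance."""
        from entrotext.classify import svm_pair_analysis

        table = make_table(
            50,
            {"A": np.zeros(6), "B": np.ones(6) * 1.5, "C": np.ones(6) * 3.0},
            seed=6,
        )
        _, dists = svm_pair_analysis(table, SplitSpec(seed=6))
        d = {r.pair: r.mean_distance for r in dists}
        assert d[("A", "C")] > d[("A", "B")]
        assert d[("A", "C")] > d[("B", "C")]
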