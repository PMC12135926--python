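"""Pairwise classification harness: five model families over the six features.

For every pair of class labels the feature table is split 75/25 (stratified),
a model of each family is fit on the training split and scored on the test
split (accuracy and ROC AUC of its continuous score), and the per-family
report averages the pairwise scores. The linear-kernel SVM additionally
yields per-feature signed coefficients — |coefficient| ranks feature
importance, the sign points at the class it predicts — and the mean Euclidean
distance of all points to its separating hyperplane, |w·x + b| / ‖w‖, a
geometric measure of how separated a pair is.

Features are standardized (zero mean, unit variance, fit on the training
split only) for the margin/distance-based families (SVM, logistic, k-NN) and
left raw for the axis-aligned tree and forest. Hyperparameters default to
C = 1 (SVM), k = 5 (k-NN) and 100 trees (forest); all are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from entrotext.features import FEATURE_COLUMNS

FAMILIES: tuple[str, ...] = (
    "svm", "logistic", "knn", "random_forest", "decision_tree",
)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split parameters (75/25, stratified, seeded)."""

    train_fraction: float = 0.75
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )


@dataclass
class BinaryEvalResult:
    pair: tuple[str, str]
    family: str
    auc: float
    accuracy: float

    def __post_init__(self) -> None:
        for name, v in (("auc", self.auc), ("accuracy", self.accuracy)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FamilyReport:
    """Mean AUC/accuracy of one model family over all class pairs."""

    family: str
    mean_auc: float
    mean_accuracy: float
    pair_results: list[BinaryEvalResult] = field(default_factory=list)


@dataclass
class CoefficientReport:
    """Signed linear-SVM coefficients and |coefficient| importance ranks.

    Positive coefficients predict ``positive_class`` (by convention the
    lexicographically first label of the pair). Ranks are 1 = largest
    |coefficient|; ties break by the fixed feature order.
    """

    pair: tuple[str, str]
    positive_class: str
    coefficients: dict[str, float]
    importance_rank: dict[str, int]


@dataclass
class BoundaryDistanceReport:
    pair: tuple[str, str]
    mean_distance: float


def _model(family: str, seed: int, hyperparameters: dict | None = None):
    hp = dict(hyperparameters or {})
    if family == "svm":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", SVC(kernel="linear", C=hp.pop("C", 1.0), **hp)),
        ])
    if family == "logistic":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=hp.pop("max_iter", 1000), **hp)),
        ])
    if family == "knn":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5), **hp)),
        ])
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100), random_state=seed, **hp
        )
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    raise ValueError(f"unknown model family {family!r} (choose from {FAMILIES})")


def _pair_table(table: pd.DataFrame, pair: tuple[str, str]) -> pd.DataFrame:
    sub = table[table["class_label"].isin(pair)]
    present = set(sub["class_label"])
    if present != set(pair):
        raise ValueError(f"labels {set(pair) - present} absent from the table")
    return sub


def stratified_split(
    table: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a (pair-restricted) feature table into train and test rows.

    Disjoint and exhaustive; stratification keeps per-class proportions
    within one row of ``train_fraction``; reproducible under the seed.
    """
    counts = table["class_label"].value_counts()
    if (counts < 4).any():
        small = counts[counts < 4].index.tolist()
        raise ValueError(f"class(es) {small} have < 4 rows; cannot split")
    stratify = table["class_label"] if spec.stratified else None
    train, test = train_test_split(
        table,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=stratify,
        shuffle=True,
    )
    return train, test


def _score_for(model, X: np.ndarray, positive_class: str) -> np.ndarray:
    """Continuous score oriented so larger means 'more positive_class'."""
    clf = model.steps[-1][1] if isinstance(model, Pipeline) else model
    classes = list(clf.classes_)
    if hasattr(model, "decision_function"):
        score = model.decision_function(X)
        # sklearn orients decision values toward classes_[1]
        return score if classes[1] == positive_class else -score
    proba = model.predict_proba(X)
    return proba[:, classes.index(positive_class)]


def train_eval_pair(
    train: pd.DataFrame,
    test: pd.DataFrame,
    family: str,
    seed: int = 0,
    hyperparameters: dict | None = None,
    return_model: bool = False,
):
    """Fit one family on a pair's training rows and score the test rows.

    Accuracy is the fraction of correct test labels; AUC is the area under
    the ROC of the family's continuous score (decision value, class
    probability or vote fraction), with the lexicographically first label of
    the pair as the positive class.
    """
    labels = sorted(set(train["class_label"]))
    if len(labels) != 2:
        raise ValueError(f"training rows must contain exactly 2 classes, got {labels}")
    if set(test["class_label"]) - set(labels):
        raise ValueError("test rows contain labels unseen in training")
    pair = (labels[0], labels[1])
    positive = pair[0]

    X_train = train.loc[:, list(FEATURE_COLUMNS)].to_numpy()
    X_test = test.loc[:, list(FEATURE_COLUMNS)].to_numpy()
    y_train = train["class_label"].to_numpy()
    y_test = test["class_label"].to_numpy()

    model = _model(family, seed, hyperparameters)
    model.fit(X_train, y_train)
    accuracy = float(accuracy_score(y_test, model.predict(X_test)))
    auc = float(roc_auc_score(y_test == positive, _score_for(model, X_test, positive)))
    result = BinaryEvalResult(pair=pair, family=family, auc=auc, accuracy=accuracy)
    if return_model:
        return result, model
    return result


def evaluate_all(
    table: pd.DataFrame,
    families: tuple[str, ...] = FAMILIES,
    spec: SplitSpec = SplitSpec(),
    hyperparameters: dict[str, dict] | None = None,
) -> tuple[list[FamilyReport], list[BinaryEvalResult]]:
    """All families on all class pairs; one report per family.

    The family report's means are the exact arithmetic means of its pairwise
    scores (three pairs in the three-class design).
    """
    labels = sorted(table["class_label"].unique())
    if len(labels) < 2:
        raise ValueError(f"need >= 2 class labels, got {labels}")
    pairs = list(combinations(labels, 2))
    reports: list[FamilyReport] = []
    all_results: list[BinaryEvalResult] = []
    for family in families:
        hp = (hyperparameters or {}).get(family)
        results = []
        for pair in pairs:
            sub = _pair_table(table, pair)
            train, test = stratified_split(sub, spec)
            results.append(train_eval_pair(train, test, family, spec.seed, hp))
        reports.append(
            FamilyReport(
                family=family,
                mean_auc=float(np.mean([r.auc for r in results])),
                mean_accuracy=float(np.mean([r.accuracy for r in results])),
                pair_results=results,
            )
        )
        all_results.extend(results)
    return reports, all_results


def rank_coefficients(coefficients: dict[str, float]) -> dict[str, int]:
    """Importance ranks 1..k by descending |coefficient|.

    Ties break by the fixed feature order (word_h1 … pos_h3) for
    determinism.
    """
    order = sorted(
        coefficients,
        key=lambda f: (-abs(coefficients[f]), FEATURE_COLUMNS.index(f)),
    )
    return {feat: rank for rank, feat in enumerate(order, start=1)}


def linear_svm_coefficients(model, pair: tuple[str, str]) -> CoefficientReport:
    """Signed coefficient report of a fitted linear-SVM pipeline.

    Coefficients are reported in the standardized feature space and oriented
    so positive values predict the pair's first label.
    """
    svc = model.steps[-1][1] if isinstance(model, Pipeline) else model
    if not isinstance(svc, SVC) or svc.kernel != "linear":
        raise ValueError("coefficient report requires a linear-kernel SVM")
    positive = pair[0]
    w = svc.coef_[0].astype(float)
    # sklearn's w points toward classes_[1]; flip if that is not `positive`
    if list(svc.classes_)[1] != positive:
        w = -w
    coefficients = dict(zip(FEATURE_COLUMNS, w))
    return CoefficientReport(
        pair=pair,
        positive_class=positive,
        coefficients=coefficients,
        importance_rank=rank_coefficients(coefficients),
    )


def mean_boundary_distance(model, points: pd.DataFrame, pair: tuple[str, str]) -> BoundaryDistanceReport:
    """Mean Euclidean distance of points to a linear decision boundary.

    distance(x) = |w·x + b| / ‖w‖, evaluated in the (standardized) space the
    SVM was fit in; invariant to rescaling (w, b) by a positive constant.
    """
    svc = model.steps[-1][1] if isinstance(model, Pipeline) else model
    if not hasattr(svc, "coef_"):
        raise ValueError("boundary distance requires a linear decision function")
    w = np.asarray(svc.coef_[0], dtype=float)
    norm = float(np.linalg.norm(w))
    if norm == 0.0:
        raise ValueError("degenerate hyperplane: ||w|| = 0")
    X = points.loc[:, list(FEATURE_COLUMNS)].to_numpy()
    distances = np.abs(model.decision_function(X)) / norm
    return BoundaryDistanceReport(pair=pair, mean_distance=float(distances.mean()))


def svm_pair_analysis(
    table: pd.DataFrame,
    spec: SplitSpec = SplitSpec(),
    C: float = 1.0,
) -> tuple[list[CoefficientReport], list[BoundaryDistanceReport]]:
    """Linear-SVM coefficients and boundary distances for every class pair.

    The boundary distance averages over *all* points of the pair (train and
    test), matching its use as a class-separation measure.
    """
    labels = sorted(table["class_label"].unique())
    coef_reports: list[CoefficientReport] = []
    dist_reports: list[BoundaryDistanceReport] = []
    for pair in combinations(labels, 2):
        sub = _pair_table(table, pair)
        train, test = stratified_split(sub, spec)
        _, model = train_eval_pair(
            train, test, "svm", spec.seed, {"C": C}, return_model=True
        )
        coef_reports.append(linear_svm_coefficients(model, pair))
        dist_reports.append(mean_boundary_distance(model, sub, pair))
    return coef_reports, dist_reports
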