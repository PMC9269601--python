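"""Subject-wise leave-one-out classification of dyslexic vs control trials.

The protocol: each trial is one observation (14 features, labeled control or
dyslexic); cross-validation folds are *subjects*, so all trials of one
subject form the test set of exactly one fold and identity never leaks into
training.  Within each fold the training set is standardized (columns to
mean 0, population std 1; zero-variance columns centered only) and the same
parameters are applied to the test set.  Test-fold predictions and
positive-class probabilities are pooled over all folds before computing
accuracy, sensitivity, specificity, F1 and AUROC, with *dyslexic* as the
positive class.

Four classifiers are supported with fixed hyperparameters: logistic
regression (l2, C=1, lbfgs, 100 iterations), RBF-kernel SVM (C=1, with
probability calibration), 5-nearest-neighbors (Euclidean) and a
100-tree Gini random forest (no depth limit, all features per split,
bootstrap resampling).
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import ALL_FEATURES, CONVENTIONAL_FEATURES, PROPOSED_FEATURES
from .trials import GROUP_CONTROL, GROUP_DYSLEXIC

ALGORITHMS = ("lr", "svm", "knn", "rf")

POSITIVE_CLASS = GROUP_DYSLEXIC


@dataclasses.dataclass(frozen=True)
class InputOption:
    """A named subset of the 14 features used as classifier input."""

    name: str
    feature_names: tuple[str, ...]


def input_options() -> dict[str, InputOption]:
    """The 17 predefined input options: 3 feature sets + 14 singletons."""
    options = {
        "conventional": InputOption("conventional", tuple(CONVENTIONAL_FEATURES)),
        "proposed": InputOption("proposed", tuple(PROPOSED_FEATURES)),
        "all": InputOption("all", tuple(ALL_FEATURES)),
    }
    for name in ALL_FEATURES:
        options[name] = InputOption(name, (name,))
    return options


INPUT_OPTIONS = input_options()


@dataclasses.dataclass
class EvaluationResult:
    """Pooled test-fold predictions and metrics for one classifier x option."""

    algorithm: str
    option: InputOption
    pooled_labels: np.ndarray
    pooled_predictions: np.ndarray
    pooled_probabilities: np.ndarray  # P(dyslexic)
    acc: float
    se: float
    sp: float
    f1: float
    auroc: float


def make_classifier(algorithm: str, seed: int | None = 0):
    """A fresh classifier with the protocol's fixed hyperparameters."""
    if algorithm == "lr":
        # l2 penalty is sklearn's default; naming it explicitly is deprecated
        return LogisticRegression(C=1.0, solver="lbfgs", max_iter=100)
    if algorithm == "svm":
        return SVC(C=1.0, kernel="rbf", probability=True, random_state=seed)
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=5, algorithm="auto", p=2)
    if algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=100, criterion="gini", max_depth=None,
            max_features=None, bootstrap=True, random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def classifier_params(algorithm: str, seed: int | None = 0) -> dict:
    """Effective hyperparameter dump for reproducibility logging."""
    return make_classifier(algorithm, seed).get_params()


def make_subject_folds(subject_ids: Sequence[str]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-subject-out folds over trial-level subject ids.

    Returns one ``(train_idx, test_idx)`` pair per unique subject (in sorted
    subject order); each test set is exactly that subject's trials, so train
    and test subject sets are disjoint and the folds cover every trial.
    """
    ids = np.asarray(subject_ids)
    subjects = np.unique(ids)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    folds = []
    for subject in subjects:
        test = np.flatnonzero(ids == subject)
        train = np.flatnonzero(ids != subject)
        folds.append((train, test))
    return folds


def standardize(train_matrix, test_matrix):
    """Column-standardize train (mean 0, population std 1) and apply to test.

    Zero-variance columns are centered but not scaled.  Returns the two
    transformed matrices and the fitted parameters ``{"mean", "scale"}``.
    """
    scaler = StandardScaler()  # population std; zero variance -> scale 1
    train = scaler.fit_transform(np.asarray(train_matrix, dtype=float))
    test = scaler.transform(np.asarray(test_matrix, dtype=float))
    return train, test, {"mean": scaler.mean_, "scale": scaler.scale_}


def _pooled_metrics(y_true, y_pred, y_proba):
    pos = y_true == POSITIVE_CLASS
    pred_pos = y_pred == POSITIVE_CLASS
    tp = int(np.sum(pos & pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    acc = (tp + tn) / len(y_true)
    se = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    auroc = float(roc_auc_score(pos.astype(int), y_proba))
    return acc, se, sp, f1, auroc


def train_eval(
    frame: pd.DataFrame,
    algorithm: str,
    option: InputOption | str,
    seed: int = 0,
) -> EvaluationResult:
    """Run the full leave-one-subject-out protocol for one classifier x option.

    ``frame`` is the feature table produced by
    :func:`gazedys.features.features_from_trials` (metadata columns plus the
    14 features).  Raises if any training fold contains a single class,
    naming the held-out subject.
    """
    if isinstance(option, str):
        option = INPUT_OPTIONS[option]
    X = frame[list(option.feature_names)].to_numpy(dtype=float)
    y = frame["group"].to_numpy()
    subjects = frame["subject_id"].to_numpy()
    if set(np.unique(y)) - {GROUP_CONTROL, GROUP_DYSLEXIC}:
        raise ValueError("groups must be 'control' or 'dyslexic' for evaluation")

    folds = make_subject_folds(subjects)
    n = len(frame)
    pooled_pred = np.empty(n, dtype=object)
    pooled_proba = np.empty(n, dtype=float)
    for train_idx, test_idx in folds:
        if len(np.unique(y[train_idx])) < 2:
            held_out = subjects[test_idx][0]
            raise ValueError(
                f"training fold for held-out subject {held_out!r} contains a single class"
            )
        model = Pipeline([
            ("standardize", StandardScaler()),
            ("classify", make_classifier(algorithm, seed)),
        ])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            # sklearn emits API-evolution notices for deliberately pinned
            # protocol settings (e.g. SVC probability calibration)
            warnings.simplefilter("ignore", FutureWarning)
            model.fit(X[train_idx], y[train_idx])
            pooled_pred[test_idx] = model.predict(X[test_idx])
            classes = list(model.named_steps["classify"].classes_)
            pos_col = classes.index(POSITIVE_CLASS)
            pooled_proba[test_idx] = model.predict_proba(X[test_idx])[:, pos_col]

    acc, se, sp, f1, auroc = _pooled_metrics(y, pooled_pred, pooled_proba)
    return EvaluationResult(
        algorithm=algorithm, option=option,
        pooled_labels=y, pooled_predictions=pooled_pred.astype(str),
        pooled_probabilities=pooled_proba,
        acc=acc, se=se, sp=sp, f1=f1, auroc=auroc,
    )


def evaluate_grid(
    frame: pd.DataFrame,
    algorithms: Sequence[str] = ALGORITHMS,
    options: Sequence[str] = ("conventional", "proposed", "all"),
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate a grid of classifiers x input options; one row per cell."""
    rows = []
    for algorithm in algorithms:
        for option in options:
            res = train_eval(frame, algorithm, option, seed=seed)
            rows.append({
                "algorithm": algorithm, "option": res.option.name,
                "acc": res.acc, "se": res.se, "sp": res.sp,
                "f1": res.f1, "auroc": res.auroc,
            })
    return pd.DataFrame(rows, columns=["algorithm", "option", "acc", "se", "sp", "f1", "auroc"])


def rf_feature_importance(
    frame: pd.DataFrame, seed: int = 0, feature_names: Sequence[str] = tuple(ALL_FEATURES)
) -> list[tuple[str, float]]:
    """Mean-decrease-in-impurity feature ranking from a random forest.

    The forest (100 Gini trees) is fit on the full standardized dataset; the
    returned importances are non-negative, sum to 1 and are sorted
    descending.
    """
    X = frame[list(feature_names)].to_numpy(dtype=float)
    y = frame["group"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("feature ranking needs both classes present")
    X = StandardScaler().fit_transform(X)
    forest = make_classifier("rf", seed).fit(X, y)
    ranking = sorted(
        zip(feature_names, forest.feature_importances_),
        key=lambda pair: pair[1], reverse=True,
    )
    return [(name, float(score)) for name, score in ranking]
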