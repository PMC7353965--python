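"""Supervised protein structural classification protocol.

The protocol, shared by every hand-crafted feature: assemble labelled PSN
sets (every retained class has >= 30 members and a set needs >= 2 classes),
then run outer stratified 10-fold cross-validation with an inner 10-fold
search over the regularization grid [2^-2, 2^-1, 1, 2, 4], one-vs-rest
L2-regularized logistic regression, optional SMOTE balancing of training
folds, and per-fold accuracy (%) and multiclass Matthews correlation.

The public surface follows the Model/Results convention:
``PSNClassificationModel(features, labels).fit(seed)`` returns a
:class:`ClassificationResults` carrying per-fold metrics, the selected
hyper-parameters, fold assignments and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix
from .structure_io import LabelTable

#: Regularization hyper-parameter search grid.
HYPERPARAMETER_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)

#: Minimum class size for a sub-class to enter a PSN set.
MIN_CLASS_SIZE = 30


@dataclass
class LabelledPSNSet:
    """Items of one classification task: (protein_id, class_label) pairs."""

    name: str
    protein_ids: list
    labels: list

    def __post_init__(self):
        if len(self.protein_ids) != len(self.labels):
            raise ValueError("ids and labels length mismatch")

    def __len__(self):
        return len(self.protein_ids)

    @property
    def classes(self):
        return sorted(set(self.labels))


def assemble_psn_sets(label_table: LabelTable, hierarchy_level: int = 0,
                      min_class_size: int = MIN_CLASS_SIZE) -> list:
    """Group hierarchical labels into classification tasks.

    ``hierarchy_level`` is the number of leading dot-separated label
    components that define the parent class (0 = single root set).  Child
    classes are the labels truncated to ``hierarchy_level + 1`` components.
    A set is emitted only for parents with at least two children of at
    least ``min_class_size`` members; items of smaller children are dropped.
    """
    parents = {}
    for domain_id, label in label_table.entries.items():
        parts = label.split(".")
        if len(parts) < hierarchy_level + 1:
            continue
        parent = ".".join(parts[:hierarchy_level]) if hierarchy_level else "root"
        child = ".".join(parts[: hierarchy_level + 1])
        parents.setdefault(parent, []).append((domain_id, child))

    sets = []
    for parent in sorted(parents):
        by_child = {}
        for domain_id, child in parents[parent]:
            by_child.setdefault(child, []).append(domain_id)
        retained = {c: ids for c, ids in by_child.items() if len(ids) >= min_class_size}
        if len(retained) < 2:
            continue
        ids, labels = [], []
        for child in sorted(retained):
            for domain_id in retained[child]:
                ids.append(domain_id)
                labels.append(child)
        sets.append(LabelledPSNSet(parent, ids, labels))
    return sets


def stratified_folds(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per item).

    Fold sizes differ by at most one and per-class proportions are
    preserved up to integer rounding.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= {k} members for {k}-fold stratification")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        assignment[test_idx] = fold
    return assignment


def smote_oversample(X, y, seed: int = 0, k_neighbors: int = 5):
    """Balance classes by synthetic minority oversampling.

    Every class is brought up to the majority count; each synthetic point is
    v + u (w - v) with u ~ U(0, 1) and w one of the k nearest same-class
    neighbours of a randomly drawn minority point v.  Originals are kept
    unchanged and returned first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("SMOTE requires at least two classes")
    if counts.min() < 2:
        raise ValueError("SMOTE cannot oversample a class with a single member")
    rng = np.random.default_rng(seed)
    target = counts.max()
    new_X, new_y = [X], [y]
    for cls, count in zip(classes, counts):
        deficit = target - count
        if deficit == 0:
            continue
        Xc = X[y == cls]
        k = min(k_neighbors, len(Xc) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        neighbors = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, len(Xc), size=deficit)
        pick = rng.integers(0, k, size=deficit)
        u = rng.random(deficit)
        v = Xc[base]
        w = Xc[neighbors[base, pick]]
        new_X.append(v + u[:, None] * (w - v))
        new_y.append(np.full(deficit, cls, dtype=y.dtype))
    return np.vstack(new_X), np.concatenate(new_y)


def train_ovr_logistic(X, y, hyperparameter: float = 1.0, seed: int = 0):
    """One-vs-rest L2-regularized logistic regression."""
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    # lbfgs default penalty is L2; C is the inverse regularization strength
    model = OneVsRestClassifier(
        LogisticRegression(C=hyperparameter, solver="lbfgs", max_iter=2000, random_state=seed)
    )
    return model.fit(np.asarray(X, dtype=float), np.asarray(y))


def accuracy(predictions, truths) -> float:
    """Percentage of correctly classified items, in [0, 100]."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if len(predictions) != len(truths):
        raise ValueError("length mismatch")
    if len(truths) == 0:
        raise ValueError("empty input")
    return 100.0 * float(np.mean(predictions == truths))


def mcc(predictions, truths) -> float:
    """Multiclass Matthews correlation coefficient (Gorodkin); 0 when degenerate."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if len(predictions) != len(truths):
        raise ValueError("length mismatch")
    if len(truths) == 0:
        raise ValueError("empty input")
    return float(matthews_corrcoef(truths, predictions))


def _fit_on_training(X_train, y_train, hyperparameter, mode, seed):
    """Scale, optionally SMOTE-balance, and fit on training data only."""
    scaler = StandardScaler().fit(X_train)
    Xs = scaler.transform(X_train)
    ys = y_train
    if mode == "proportional+smote":
        Xs, ys = smote_oversample(Xs, ys, seed=seed)
    model = train_ovr_logistic(Xs, ys, hyperparameter, seed=seed)
    return scaler, model


def select_hyperparameter(X_train, y_train, grid=HYPERPARAMETER_GRID, seed: int = 0,
                          mode: str = "proportional", inner_k: int = 10) -> float:
    """Inner stratified CV over the grid; ties broken toward the smallest value.

    The inner folds replicate the outer treatment: scaling (and SMOTE, if
    the mode asks for it) is fit on inner training folds only.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    _, counts = np.unique(y_train, return_counts=True)
    k = min(inner_k, int(counts.min()))
    if k < 2:
        return grid[0]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(X_train, y_train))
    best_value, best_score = None, -np.inf
    for value in grid:
        scores = []
        for train_idx, val_idx in splits:
            scaler, model = _fit_on_training(X_train[train_idx], y_train[train_idx], value, mode, seed)
            pred = model.predict(scaler.transform(X_train[val_idx]))
            scores.append(accuracy(pred, y_train[val_idx]))
        score = float(np.mean(scores))
        if score > best_score + 1e-12:  # strict improvement: ties keep the smaller value
            best_value, best_score = value, score
    return best_value


@dataclass
class CVResult:
    """Per-fold outcome of the cross-validated protocol."""

    set_name: str
    feature_name: str
    mode: str
    seed: int
    fold_assignments: np.ndarray
    fold_accuracies: np.ndarray
    fold_mccs: np.ndarray
    chosen_hyperparameters: list
    train_indices: list = field(default_factory=list)
    test_indices: list = field(default_factory=list)

    @property
    def n_folds(self):
        return len(self.fold_accuracies)

    @property
    def accuracy_mean(self):
        return float(np.mean(self.fold_accuracies))

    @property
    def accuracy_std(self):
        return float(np.std(self.fold_accuracies))

    @property
    def mcc_mean(self):
        return float(np.mean(self.fold_mccs))

    @property
    def mcc_std(self):
        return float(np.std(self.fold_mccs))

    def to_dict(self):
        return {
            "set_name": self.set_name,
            "feature_name": self.feature_name,
            "mode": self.mode,
            "seed": self.seed,
            "fold_assignments": self.fold_assignments.tolist(),
            "fold_accuracies": self.fold_accuracies.tolist(),
            "fold_mccs": self.fold_mccs.tolist(),
            "chosen_hyperparameters": list(self.chosen_hyperparameters),
            "accuracy_mean": self.accuracy_mean,
            "mcc_mean": self.mcc_mean,
        }


def run_protocol(X, y, mode: str = "proportional", seed: int = 0, n_folds: int = 10,
                 grid=HYPERPARAMETER_GRID, set_name: str = "", feature_name: str = "") -> CVResult:
    """Outer stratified k-fold CV with inner hyper-parameter selection.

    For each outer fold the hyper-parameter is chosen on the training folds
    only, SMOTE (if requested) balances the training data only, and metrics
    are computed on the untouched held-out fold.
    """
    if mode not in ("proportional", "proportional+smote"):
        raise ValueError(f"unknown mode: {mode}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    assignment = stratified_folds(y, k=n_folds, seed=seed)
    accs, mccs, chosen, train_idx_list, test_idx_list = [], [], [], [], []
    for fold in range(n_folds):
        test_mask = assignment == fold
        train_idx = np.nonzero(~test_mask)[0]
        test_idx = np.nonzero(test_mask)[0]
        value = select_hyperparameter(X[train_idx], y[train_idx], grid=grid, seed=seed, mode=mode)
        scaler, model = _fit_on_training(X[train_idx], y[train_idx], value, mode, seed)
        pred = model.predict(scaler.transform(X[test_idx]))
        accs.append(accuracy(pred, y[test_idx]))
        mccs.append(mcc(pred, y[test_idx]))
        chosen.append(value)
        train_idx_list.append(train_idx)
        test_idx_list.append(test_idx)
    return CVResult(
        set_name=set_name,
        feature_name=feature_name,
        mode=mode,
        seed=seed,
        fold_assignments=assignment,
        fold_accuracies=np.array(accs),
        fold_mccs=np.array(mccs),
        chosen_hyperparameters=chosen,
        train_indices=train_idx_list,
        test_indices=test_idx_list,
    )


class ClassificationResults:
    """Results object wrapping a :class:`CVResult` with a summary table."""

    def __init__(self, cv_result: CVResult):
        self.cv = cv_result

    @property
    def accuracy_mean(self):
        return self.cv.accuracy_mean

    @property
    def mcc_mean(self):
        return self.cv.mcc_mean

    def per_fold(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fold": np.arange(self.cv.n_folds),
            "accuracy": self.cv.fold_accuracies,
            "mcc": self.cv.fold_mccs,
            "hyperparameter": self.cv.chosen_hyperparameters,
        })

    def summary(self) -> str:
        cv = self.cv
        lines = [
            "Protein structural classification (cross-validated)",
            "=" * 52,
            f"PSN set:        {cv.set_name or '-'}",
            f"Feature:        {cv.feature_name or '-'}",
            f"Training mode:  {cv.mode}",
            f"Folds:          {cv.n_folds}    Seed: {cv.seed}",
            "-" * 52,
            f"Accuracy (%):   {cv.accuracy_mean:8.3f} +/- {cv.accuracy_std:.3f}",
            f"MCC:            {cv.mcc_mean:8.3f} +/- {cv.mcc_std:.3f}",
            "-" * 52,
            self.per_fold().to_string(index=False),
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<ClassificationResults accuracy={self.accuracy_mean:.2f}% "
                f"mcc={self.mcc_mean:.3f} folds={self.cv.n_folds}>")


class PSNClassificationModel:
    """Cross-validated one-vs-rest logistic-regression model over a feature matrix.

    Parameters
    ----------
    features : FeatureMatrix or ndarray
        Per-protein descriptors (rows = proteins).
    labels : sequence of str
        Structural class label per row.
    mode : {"proportional", "proportional+smote"}
        Whether training folds are SMOTE-balanced.
    n_folds : int
        Outer (and inner) cross-validation folds.
    grid : sequence of float
        Regularization hyper-parameter candidates.
    """

    def __init__(self, features, labels, mode="proportional", n_folds=10,
                 grid=HYPERPARAMETER_GRID, set_name=""):
        if isinstance(features, FeatureMatrix):
            self.feature_name = features.feature_name
            self.X = features.values
            if len(labels) != len(features.protein_ids):
                raise ValueError("labels must match feature matrix rows")
        else:
            self.feature_name = ""
            self.X = np.asarray(features, dtype=float)
        self.y = np.asarray(list(labels))
        if len(self.y) != len(self.X):
            raise ValueError("labels must match feature rows")
        self.mode = mode
        self.n_folds = n_folds
        self.grid = tuple(grid)
        self.set_name = set_name

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "class", **kwargs):
        """Build from a DataFrame whose non-label columns are feature components."""
        y = df[label_col].to_numpy()
        X = df.drop(columns=[label_col]).to_numpy(dtype=float)
        model = cls(X, y, **kwargs)
        model.feature_name = kwargs.get("feature_name", "")
        return model

    def fit(self, seed: int = 0) -> ClassificationResults:
        cv = run_protocol(
            self.X, self.y, mode=self.mode, seed=seed, n_folds=self.n_folds,
            grid=self.grid, set_name=self.set_name, feature_name=self.feature_name,
        )
        return ClassificationResults(cv)
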