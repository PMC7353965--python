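"""Deep feed-forward classification of weighted PSNs (distance matrices).

The weighted counterpart of the hand-crafted pipeline: the residue-residue
minimum-distance matrix is padded/truncated to a fixed size, its upper
triangle flattened, and fed to a feed-forward network with one input layer,
seven hidden layers (ReLU) and a softmax output trained with cross-entropy.
The fold discipline is the same stratified 10-fold protocol as the
logistic-regression path, proportional training only.

The network is built on scikit-learn's multilayer perceptron (Adam
optimizer, early stopping on a validation split of the training data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .classify import CVResult, ClassificationResults, accuracy, mcc, stratified_folds
from .psn import DistanceMatrix

#: Distance assigned to padded (absent-residue) positions; larger than any
#: plausible intra-domain distance so padding is unambiguous.
PAD_SENTINEL = 999.0


@dataclass
class DLConfig:
    """Architecture and optimization settings for the distance-matrix network.

    Defaults are implementation choices sized to 100-130 residue domains:
    pad size 128 (8128 input components) and geometrically decaying hidden
    widths 256..4 — exactly seven hidden layers.
    """

    pad_size: int = 128
    hidden_layers: tuple = (256, 128, 64, 32, 16, 8, 4)
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 16
    early_stopping: bool = True
    validation_fraction: float = 0.1
    sentinel: float = PAD_SENTINEL

    def __post_init__(self):
        if self.pad_size < 2:
            raise ValueError("pad_size must be >= 2")
        if len(self.hidden_layers) < 1 or any(w < 1 for w in self.hidden_layers):
            raise ValueError("hidden layer widths must be >= 1")

    @property
    def input_dim(self):
        return self.pad_size * (self.pad_size - 1) // 2


def encode_distance_matrix(dm, pad_size: int, sentinel: float = PAD_SENTINEL) -> np.ndarray:
    """Flatten the upper triangle of D, padded or truncated to pad_size.

    Positions involving absent residues (n < pad_size) get the sentinel
    value; residues beyond pad_size are dropped.  Length is
    pad_size*(pad_size-1)/2, independent of n.
    """
    if pad_size < 2:
        raise ValueError("pad_size must be >= 2")
    values = dm.values if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    n = values.shape[0]
    padded = np.full((pad_size, pad_size), sentinel)
    m = min(n, pad_size)
    padded[:m, :m] = values[:m, :m]
    np.fill_diagonal(padded, 0.0)
    return padded[np.triu_indices(pad_size, k=1)]


def encode_dataset(matrices, config: DLConfig) -> np.ndarray:
    return np.vstack([encode_distance_matrix(dm, config.pad_size, config.sentinel) for dm in matrices])


def build_network(config: DLConfig, seed: int = 0) -> MLPClassifier:
    """Feed-forward net: 7 hidden ReLU layers, softmax output, cross-entropy."""
    return MLPClassifier(
        hidden_layer_sizes=tuple(config.hidden_layers),
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        batch_size=config.batch_size,
        max_iter=config.epochs,
        early_stopping=config.early_stopping,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=10,
        random_state=seed,
    )


def train_dl(X, y, config: DLConfig, seed: int = 0):
    """Train the network on encoded (and standardized) training data only."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    scaler = StandardScaler().fit(X)
    model = build_network(config, seed=seed)
    model.fit(scaler.transform(X), y)
    return scaler, model


def evaluate_dl(model_pair, X_test, y_test):
    """Accuracy (%) and MCC of a trained network on held-out data."""
    scaler, model = model_pair
    pred = model.predict(scaler.transform(X_test))
    return accuracy(pred, y_test), mcc(pred, y_test)


def run_dl_protocol(matrices, labels, config: DLConfig = None, seed: int = 0,
                    n_folds: int = 10, set_name: str = "") -> CVResult:
    """Stratified k-fold CV of the distance-matrix network (proportional only)."""
    config = config or DLConfig()
    X = encode_dataset(matrices, config)
    y = np.asarray(list(labels))
    assignment = stratified_folds(y, k=n_folds, seed=seed)
    accs, mccs, train_idx_list, test_idx_list = [], [], [], []
    for fold in range(n_folds):
        test_mask = assignment == fold
        train_idx = np.nonzero(~test_mask)[0]
        test_idx = np.nonzero(test_mask)[0]
        pair = train_dl(X[train_idx], y[train_idx], config, seed=seed)
        a, m = evaluate_dl(pair, X[test_idx], y[test_idx])
        accs.append(a)
        mccs.append(m)
        train_idx_list.append(train_idx)
        test_idx_list.append(test_idx)
    return CVResult(
        set_name=set_name,
        feature_name="distance-matrix",
        mode="proportional",
        seed=seed,
        fold_assignments=assignment,
        fold_accuracies=np.array(accs),
        fold_mccs=np.array(mccs),
        chosen_hyperparameters=[None] * n_folds,
        train_indices=train_idx_list,
        test_indices=test_idx_list,
    )


class DistanceMatrixDLModel:
    """Model object for the weighted-PSN deep-learning path.

    ``fit(seed)`` runs the stratified cross-validation protocol and returns
    the same :class:`ClassificationResults` as the logistic-regression path.
    """

    def __init__(self, matrices, labels, config: DLConfig = None, n_folds: int = 10, set_name: str = ""):
        self.matrices = list(matrices)
        self.labels = list(labels)
        if len(self.matrices) != len(self.labels):
            raise ValueError("matrices and labels length mismatch")
        self.config = config or DLConfig()
        self.n_folds = n_folds
        self.set_name = set_name

    def fit(self, seed: int = 0) -> ClassificationResults:
        cv = run_dl_protocol(self.matrices, self.labels, self.config, seed=seed,
                             n_folds=self.n_folds, set_name=self.set_name)
        return ClassificationResults(cv)
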