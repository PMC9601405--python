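"""Two-class feed-forward outcome classifier.

A small fully-connected network (1-3 hidden layers) maps experiment features
to a success score in [0, 1].  Hyperparameters are chosen by seeded random
search over a declared space, each candidate evaluated by stratified inner
3-fold cross-validation on binary accuracy at the 0.5 cutoff.  Shuffled-label
("random") twins of every model provide the permutation-null baseline against
which real predictive signal is judged.

All stochastic elements — weight initialisation, fold assignment, trial
sampling, label shuffling — derive from explicit integer seeds, so any run
is replayable bit for bit.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .errors import (
    DegenerateTrainingError,
    IncompatibleFeaturesError,
)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one feed-forward network.

    ``alpha`` is the L2 weight-decay strength, the regulariser standing in
    for dropout in this implementation.
    """

    n_hidden_layers: int = 1
    units: int = 32
    activation: str = "relu"
    alpha: float = 1e-4
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden_layers not in (1, 2, 3):
            raise ValueError("n_hidden_layers must be 1, 2 or 3")
        if self.units < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("units, epochs and batch_size must be >= 1")
        if not (0 < self.learning_rate < 1):
            raise ValueError("learning_rate out of range")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    def parameter_count(self, n_features: int) -> int:
        """Number of trainable weights + biases at a given input width."""
        sizes = [n_features] + [self.units] * self.n_hidden_layers + [1]
        return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


@dataclass
class TrainedClassifier:
    """A fitted network plus the provenance needed to reuse it safely."""

    estimator: MLPClassifier
    config: ModelConfig
    n_features: int
    feature_set: str = ""
    standardizer: object | None = None
    training_fingerprint: tuple[str, int] = ("", 0)
    training_campaign: str | None = None

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return predict_scores(self, X)


@dataclass(frozen=True)
class MetricReport:
    """Confusion counts at a score cutoff plus threshold-free ROC AUC.

    ``precision`` is TP/(TP+FP) — the fraction of predicted successes that
    really succeeded, the quantity a prioritised experiment list cares
    about; ``recall`` is TP/(TP+FN); ``accuracy`` is (TP+TN)/n.  A metric is
    ``nan`` when its denominator is zero (flagged, not raised).
    """

    TP: int
    FP: int
    TN: int
    FN: int
    precision: float
    recall: float
    accuracy: float
    roc_auc: float
    cutoff: float


def _data_fingerprint(X: np.ndarray, y: np.ndarray) -> tuple[str, int]:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return (h.hexdigest()[:16], len(y))


def train_classifier(X: np.ndarray, y: np.ndarray, config: ModelConfig) -> TrainedClassifier:
    """Fit the network. Deterministic given (data, config, config.seed)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if len(y) < 2:
        raise ValueError("need at least 2 training rows")
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    if np.isnan(X).any():
        raise ValueError("NaN in feature matrix")
    est = MLPClassifier(
        hidden_layer_sizes=(config.units,) * config.n_hidden_layers,
        activation=config.activation,
        alpha=config.alpha,
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        batch_size=min(config.batch_size, len(y)),
        solver="adam",
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return TrainedClassifier(
        estimator=est,
        config=config,
        n_features=X.shape[1],
        training_fingerprint=_data_fingerprint(X, y),
    )


def predict_scores(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Success scores in [0, 1] (probability of the successful class)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise IncompatibleFeaturesError(
            f"expected {model.n_features} features, got {X.shape}"
        )
    classes = list(model.estimator.classes_)
    scores = model.estimator.predict_proba(X)[:, classes.index(1)]
    return np.clip(scores, 0.0, 1.0)


def evaluate_metrics(
    y_true: np.ndarray,
    scores: np.ndarray,
    cutoff: float = 0.5,
    with_auc: bool = True,
) -> MetricReport:
    """Confusion counts at ``cutoff`` (score >= cutoff predicts success),
    precision/recall/accuracy, and rank-statistic ROC AUC over all cutoffs."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(scores):
        raise ValueError("length mismatch")
    pred = scores >= cutoff
    pos = y_true == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    accuracy = (tp + tn) / len(y_true)
    if with_auc and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
    else:
        auc = float("nan")  # undefined for one-class truth; flagged as nan
    return MetricReport(
        TP=tp, FP=fp, TN=tn, FN=fn,
        precision=precision, recall=recall, accuracy=accuracy,
        roc_auc=auc, cutoff=cutoff,
    )


def shuffle_labels(y: np.ndarray, seed: int) -> np.ndarray:
    """Seeded permutation of the label vector (class counts preserved)."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty label vector")
    rng = np.random.default_rng(seed)
    return y[rng.permutation(len(y))]


#: Default hyperparameter search space.
DEFAULT_SEARCH_SPACE: dict = {
    "n_hidden_layers": [1, 2, 3],
    "units": [16, 32, 64, 128],
    "alpha": [0.0, 1e-4, 1e-3],
    "learning_rate": ("log_uniform", 1e-4, 1e-2),
    "epochs": [20, 50, 100],
    "batch_size": [16, 32, 64],
}


def sample_config(search_space: dict, rng: np.random.Generator, seed: int) -> ModelConfig:
    """Draw one configuration from the space (lists uniform; log_uniform tuples)."""
    kwargs = {}
    for key, choices in search_space.items():
        if isinstance(choices, tuple) and choices[0] == "log_uniform":
            lo, hi = choices[1], choices[2]
            kwargs[key] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            kwargs[key] = choices[int(rng.integers(len(choices)))]
    return ModelConfig(seed=seed, **kwargs)


@dataclass
class TrialLog:
    """One tuning trial: the sampled config and its mean inner-fold accuracy."""

    trial: int
    config: ModelConfig
    inner_accuracy: float


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    search_space: dict | None = None,
    budget: int = 1000,
    inner_k: int = 3,
    seed: int = 0,
) -> tuple[ModelConfig, list[TrialLog]]:
    """Random search with stratified inner k-fold selection on binary accuracy.

    Returns the best configuration and the full trial log.  Ties are broken
    by smaller parameter count, then earlier trial.  If some inner fold comes
    out single-class the folding is retried with a fresh seed, erroring after
    three attempts.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("tuning needs both classes")
    search_space = search_space if search_space is not None else DEFAULT_SEARCH_SPACE

    folds = None
    for attempt in range(3):
        skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed + attempt)
        candidate = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in candidate):
            folds = candidate
            break
    if folds is None:
        raise DegenerateTrainingError("could not build two-class inner folds")

    rng = np.random.default_rng(seed)
    log: list[TrialLog] = []
    best: TrialLog | None = None
    best_params = None
    for trial in range(budget):
        config = sample_config(search_space, rng, seed=int(rng.integers(2**31)))
        accs = []
        for tr, te in folds:
            model = train_classifier(X[tr], y[tr], config)
            rep = evaluate_metrics(y[te], predict_scores(model, X[te]), with_auc=False)
            accs.append(rep.accuracy)
        entry = TrialLog(trial=trial, config=config, inner_accuracy=float(np.mean(accs)))
        log.append(entry)
        params = config.parameter_count(X.shape[1])
        if (
            best is None
            or entry.inner_accuracy > best.inner_accuracy
            or (entry.inner_accuracy == best.inner_accuracy and params < best_params)
        ):
            best, best_params = entry, params
    return best.config, log
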