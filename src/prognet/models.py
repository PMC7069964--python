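"""Model specifications, training wrappers and benchmark classifiers.

The expression ("microarray") and clinical branches default to four ReLU
layers of 40 and 18 units respectively; the bimodal network concatenates
their last hidden layers (58 units) and stacks two 32-unit layers before
the logistic output. Branch pre-training: each branch is first trained as
a unimodal classifier, then its weights seed the bimodal network which is
fine-tuned on both modalities jointly. Benchmarks (KNN, RF, SVM) select
hyper-parameters by 10-fold cross-validated AUC: KNN considers up to 30
Euclidean neighbours, the SVM uses an RBF kernel over penalty and kernel
width grids, and the random forest caps tree depth at one third of the
input dimension while varying the number of trees.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .nn import BimodalNet, FeedForward, TrainHistory, train_network

__all__ = [
    "BranchSpec", "BimodalSpec", "TrainSpec", "TrainedModel",
    "build_network", "train_unimodal", "train_bimodal", "predict_risk",
    "train_benchmark", "BENCHMARK_KINDS",
]

BENCHMARK_KINDS = ("knn", "rf", "svm")


@dataclass(frozen=True)
class BranchSpec:
    """One feed-forward branch: ReLU hidden stack plus (for unimodal use)
    a logistic head."""

    input_dim: int
    hidden_widths: tuple[int, ...] = (40, 40, 40, 40)
    activation: str = "relu"
    l2_penalty: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not self.hidden_widths or any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden_widths must be nonempty and positive")


@dataclass(frozen=True)
class BimodalSpec:
    """Merged two-branch network; merged width is the sum of the two last
    hidden widths (58 for the defaults 40 + 18)."""

    microarray_branch: BranchSpec
    clinical_branch: BranchSpec
    post_merge_widths: tuple[int, ...] = (32, 32)
    l2_penalty: float = 1e-4
    seed: int = 0

    @property
    def merged_width(self) -> int:
        return (self.microarray_branch.hidden_widths[-1]
                + self.clinical_branch.hidden_widths[-1])


def default_bimodal_spec(micro_dim: int = 15, clin_dim: int = 7,
                         seed: int = 0) -> BimodalSpec:
    return BimodalSpec(
        BranchSpec(micro_dim, (40, 40, 40, 40), seed=seed),
        BranchSpec(clin_dim, (18, 18, 18, 18), seed=seed + 1),
        seed=seed,
    )


@dataclass(frozen=True)
class TrainSpec:
    """Optimization settings (Nadam, lr 0.006, batch 20, at most 100
    epochs, early stopping after 30 stagnant validation epochs)."""

    optimizer: str = "nadam"
    learning_rate: float = 0.006
    max_epochs: int = 100
    batch_size: int = 20
    early_stop_patience: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.early_stop_patience > self.max_epochs and self.max_epochs > 0:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class TrainedModel:
    kind: str  # micro | clinical | bimodal | knn | rf | svm
    spec: object
    model: object
    history: TrainHistory | None = None
    cv_results: dict = field(default_factory=dict)

    @property
    def best_epoch(self) -> int:
        return self.history.best_epoch if self.history is not None else -1


def build_network(spec):
    """Instantiate an untrained network with seeded deterministic weights."""
    if isinstance(spec, BranchSpec):
        return FeedForward(spec.input_dim, spec.hidden_widths, seed=spec.seed,
                           l2=spec.l2_penalty)
    if isinstance(spec, BimodalSpec):
        return BimodalNet(spec.microarray_branch.input_dim,
                          spec.microarray_branch.hidden_widths,
                          spec.clinical_branch.input_dim,
                          spec.clinical_branch.hidden_widths,
                          spec.post_merge_widths, seed=spec.seed,
                          l2=spec.l2_penalty)
    raise TypeError(f"unknown spec type {type(spec).__name__}")


def _check_labels(y):
    y = np.asarray(y)
    classes = set(np.unique(y))
    if not classes <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")


def train_unimodal(spec: BranchSpec, X, y, X_val, y_val,
                   tspec: TrainSpec = TrainSpec(),
                   kind: str = "micro") -> TrainedModel:
    """Train one branch as a standalone classifier (pre-training stage)."""
    _check_labels(y)
    net = build_network(spec)
    hist = train_network(net, np.asarray(X, float), y,
                         np.asarray(X_val, float), y_val,
                         learning_rate=tspec.learning_rate,
                         max_epochs=tspec.max_epochs,
                         batch_size=tspec.batch_size,
                         patience=tspec.early_stop_patience,
                         seed=tspec.seed)
    return TrainedModel(kind, spec, net, hist)


def train_bimodal(micro_model: TrainedModel, clin_model: TrainedModel,
                  X_micro, X_clin, y, Xv_micro, Xv_clin, y_val,
                  bspec: BimodalSpec | None = None,
                  tspec: TrainSpec = TrainSpec()) -> TrainedModel:
    """Build the merged network from the pre-trained branches and
    fine-tune all weights with both inputs fed simultaneously.

    With ``max_epochs=0`` the branch weights remain exactly the unimodal
    weights (initialization contract).
    """
    _check_labels(y)
    if bspec is None:
        bspec = BimodalSpec(micro_model.spec, clin_model.spec,
                            seed=tspec.seed)
    net = build_network(bspec)
    net.load_branches(micro_model.model, clin_model.model)
    X = (np.asarray(X_micro, float), np.asarray(X_clin, float))
    Xv = (np.asarray(Xv_micro, float), np.asarray(Xv_clin, float))
    if tspec.max_epochs > 0:
        hist = train_network(net, X, y, Xv, y_val,
                             learning_rate=tspec.learning_rate,
                             max_epochs=tspec.max_epochs,
                             batch_size=tspec.batch_size,
                             patience=min(tspec.early_stop_patience,
                                          tspec.max_epochs),
                             seed=tspec.seed)
    else:
        hist = TrainHistory()
    return TrainedModel("bimodal", bspec, net, hist)


def predict_risk(model, X) -> np.ndarray:
    """Per-sample predicted death probability in [0, 1]."""
    m = model.model if isinstance(model, TrainedModel) else model
    if isinstance(m, (FeedForward, BimodalNet)):
        return m.predict_proba(X)
    return m.predict_proba(np.asarray(X, float))[:, 1]


def _benchmark_grid(kind: str, input_dim: int, seed: int):
    if kind == "knn":
        return (KNeighborsClassifier(metric="euclidean"),
                {"n_neighbors": list(range(1, 31))})
    if kind == "rf":
        return (RandomForestClassifier(
                    max_depth=math.ceil(input_dim / 3), random_state=seed),
                {"n_estimators": [50, 100, 200, 400]})
    if kind == "svm":
        return (SVC(kernel="rbf", probability=True, random_state=seed),
                {"C": [0.1, 1.0, 10.0, 100.0],
                 "gamma": ["scale", 0.001, 0.01, 0.1, 1.0]})
    raise ValueError(f"unknown benchmark kind {kind!r}")


def train_benchmark(kind: str, X, y, cv_folds: int = 10,
                    seed: int = 0) -> TrainedModel:
    """Fit a benchmark classifier with 10-fold CV hyper-parameter search
    (stratified folds, selection by mean CV AUC)."""
    _check_labels(y)
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if len(y) < cv_folds:
        raise ValueError("fewer samples than CV folds")
    est, grid = _benchmark_grid(kind, X.shape[1], seed)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(est, grid, scoring="roc_auc", cv=cv, n_jobs=None)
    search.fit(X, y)
    return TrainedModel(kind, search.best_params_, search.best_estimator_,
                        None, {"best_score": float(search.best_score_),
                               "best_params": dict(search.best_params_)})
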