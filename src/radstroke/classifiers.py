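"""Binary classifiers over feature matrices, plus the recurrent document model.

Families: L1-penalized logistic regression (lasso), k-nearest neighbors,
CART, random forest (all via scikit-learn), and a hierarchical LSTM that
consumes embedded token sequences directly (see :mod:`radstroke.hlstm`).
Logistic regression and k-NN standardize features internally (statistics
fitted on the training data only) because both are scale-sensitive.

Hyperparameters are tuned by stratified k-fold grid search on validation
AUC; ties go to the simpler specification (larger penalty, smaller depth,
smaller k).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .featurize import FeatureMatrix
from .hlstm import HierarchicalLSTM, RNNSpec
from .io import EmbeddingFile
from .preprocess import TokenDoc

__all__ = [
    "LogRegSpec",
    "KNNSpec",
    "CartSpec",
    "RFSpec",
    "RNNSpec",
    "TrainedModel",
    "train",
    "predict_proba",
    "train_rnn_document_model",
    "grid_search_cv",
    "save_model",
    "load_model",
]


@dataclass
class LogRegSpec:
    """Lasso logistic regression: penalty weight lam, 1000 iters, tol 0.01."""

    lam: float = 1.0
    max_iter: int = 1000
    tol: float = 0.01
    kind: str = field(default="logreg_l1", init=False)

    def complexity(self) -> float:
        return 1.0 / self.lam  # larger penalty = simpler model


@dataclass
class KNNSpec:
    k: int = 5
    kind: str = field(default="knn", init=False)

    def complexity(self) -> float:
        return float(self.k)


@dataclass
class CartSpec:
    max_depth: int = 5
    min_bucket: int = 1
    criterion: str = "gini"  # or "entropy"
    kind: str = field(default="cart", init=False)

    def __post_init__(self) -> None:
        if not 1 <= self.max_depth <= 10 or not 1 <= self.min_bucket <= 10:
            raise ValueError("max_depth and min_bucket must be in 1..10")

    def complexity(self) -> float:
        return self.max_depth + 1.0 / self.min_bucket


@dataclass
class RFSpec:
    n_trees: int = 200
    max_depth: int | None = None
    min_bucket: int = 1
    seed: int = 0
    kind: str = field(default="rf", init=False)

    def complexity(self) -> float:
        depth = self.max_depth if self.max_depth is not None else 50
        return self.n_trees * depth


ClassifierSpec = LogRegSpec | KNNSpec | CartSpec | RFSpec | RNNSpec


@dataclass
class TrainedModel:
    """A fitted classifier plus its feature contract."""

    spec: ClassifierSpec
    estimator: object
    scaler: StandardScaler | None
    n_features: int

    def predict_proba(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        return predict_proba(self, X)


def _as_array(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def _lasso_logreg(spec: "LogRegSpec") -> LogisticRegression:
    import sklearn

    kwargs = dict(
        C=1.0 / spec.lam,
        solver="liblinear",
        max_iter=spec.max_iter,
        tol=spec.tol,
        random_state=0,  # liblinear shuffles internally
    )
    major, minor = (int(v) for v in sklearn.__version__.split(".")[:2])
    if (major, minor) >= (1, 8):  # penalty= deprecated in favor of l1_ratio=
        kwargs["l1_ratio"] = 1.0
    else:
        kwargs["penalty"] = "l1"
    return LogisticRegression(**kwargs)


def train(X: FeatureMatrix | np.ndarray, y, spec: ClassifierSpec) -> TrainedModel:
    """Fit one classifier; deterministic given any seed carried by the spec."""
    Xa = _as_array(X)
    y = np.asarray(y, dtype=int)
    if Xa.shape[0] != len(y):
        raise ValueError("X and y disagree on the number of rows")
    if np.isnan(Xa).any():
        raise ValueError("features contain NaN")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    scaler = None
    if spec.kind == "logreg_l1":
        scaler = StandardScaler().fit(Xa)
        est = _lasso_logreg(spec).fit(scaler.transform(Xa), y)
    elif spec.kind == "knn":
        scaler = StandardScaler().fit(Xa)
        est = KNeighborsClassifier(n_neighbors=spec.k).fit(scaler.transform(Xa), y)
    elif spec.kind == "cart":
        est = DecisionTreeClassifier(
            max_depth=spec.max_depth,
            min_samples_leaf=spec.min_bucket,
            criterion=spec.criterion,
            random_state=0,
        ).fit(Xa, y)
    elif spec.kind == "rf":
        est = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_depth=spec.max_depth,
            min_samples_leaf=spec.min_bucket,
            random_state=spec.seed,
        ).fit(Xa, y)
    else:
        raise ValueError(
            f"spec kind {spec.kind!r} not trainable from a feature matrix "
            "(the rnn kind consumes token documents; use train_rnn_document_model)"
        )
    return TrainedModel(spec=spec, estimator=est, scaler=scaler, n_features=Xa.shape[1])


def predict_proba(model: TrainedModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Probability of the positive class per row."""
    Xa = _as_array(X)
    if Xa.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {Xa.shape[1]} does not match the model contract "
            f"({model.n_features})"
        )
    if model.scaler is not None:
        Xa = model.scaler.transform(Xa)
    est = model.estimator
    classes = list(est.classes_)
    return est.predict_proba(Xa)[:, classes.index(1)]


def train_rnn_document_model(
    docs: list[TokenDoc], emb: EmbeddingFile, y, spec: RNNSpec | None = None
) -> HierarchicalLSTM:
    """Fit the hierarchical LSTM on embedded token documents."""
    if spec is None:
        spec = RNNSpec()
    if not docs:
        raise ValueError("empty training corpus")
    return HierarchicalLSTM(emb, spec).fit(docs, np.asarray(y, dtype=float))


def grid_search_cv(
    X: FeatureMatrix | np.ndarray,
    y,
    spec_grid: list[ClassifierSpec],
    folds: int = 10,
    seed: int = 0,
) -> tuple[ClassifierSpec, pd.DataFrame]:
    """Stratified k-fold grid search maximizing mean validation AUC.

    Ties are resolved toward the simpler spec (``spec.complexity()``).
    Returns the winning spec and the full CV table.
    """
    from .evaluation import roc_and_auc  # local import to avoid a cycle

    if not spec_grid:
        raise ValueError("empty specification grid")
    Xa = _as_array(X)
    y = np.asarray(y, dtype=int)
    if folds > len(y):
        raise ValueError(f"folds={folds} exceeds the number of samples ({len(y)})")
    minority = int(min(np.sum(y == 0), np.sum(y == 1)))
    if folds > minority:
        raise ValueError(f"folds={folds} exceeds the minority-class count ({minority})")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xa, y))
    rows = []
    for gi, spec in enumerate(spec_grid):
        fold_aucs = []
        for tr, va in splits:
            model = train(Xa[tr], y[tr], spec)
            p = predict_proba(model, Xa[va])
            _, auc = roc_and_auc(y[va], p)
            fold_aucs.append(auc)
        rows.append(
            {
                "grid_index": gi,
                "kind": spec.kind,
                "spec": str(spec),
                "mean_auc": float(np.mean(fold_aucs)),
                "sd_auc": float(np.std(fold_aucs, ddof=1)) if folds > 1 else 0.0,
                "complexity": spec.complexity(),
            }
        )
    table = pd.DataFrame(rows)
    best_i = int(
        table.sort_values(
            ["mean_auc", "complexity", "grid_index"], ascending=[False, True, True]
        ).iloc[0]["grid_index"]
    )
    return spec_grid[best_i], table


def save_model(model: TrainedModel | HierarchicalLSTM, path: str | Path) -> None:
    """Persist a fitted model (spec + fitted state) to a joblib archive."""
    if isinstance(model, HierarchicalLSTM):
        payload = {"format": "radstroke-rnn", "spec": asdict(model.spec), "model": model}
    else:
        payload = {"format": "radstroke-model", "spec": asdict(model.spec), "model": model}
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel | HierarchicalLSTM:
    payload = joblib.load(path)
    if payload.get("format") not in ("radstroke-model", "radstroke-rnn"):
        raise ValueError(f"{path} is not a radstroke model archive")
    return payload["model"]
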