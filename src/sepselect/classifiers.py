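"""The five classifier families under one fit/predict contract.

Four are standard algorithms delegated to scikit-learn (random forest,
decision tree, RBF-kernel SVM on PCA-reduced input with one-vs-rest
multiclass handling) or to the package's own NumPy LSTM; the fifth —
``linear_onehot`` — is the one-hot least-squares multiclass classifier
implemented from scratch: fit an ordinary least-squares regression of the
one-hot label matrix Y on X, predict by argmax_c of x @ beta_c + beta0_c,
ties broken by the lowest class code.

Every kind is deterministic given (data, seed) and every
:class:`FittedModel` predicts through the same interface, so pipeline code
never branches on the model family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import DomainError, ShapeError
from .io_expression import ClassMap, ExpressionMatrix
from .lstm import LSTMClassifier

__all__ = [
    "MODEL_KINDS",
    "ModelConfig",
    "OneHotLinearModel",
    "FittedModel",
    "fit",
    "predict",
    "apply_pca",
]

MODEL_KINDS = ("random_forest", "decision_tree", "linear_onehot", "svm_pca", "lstm")

_DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "random_forest": {"n_trees": 100, "class_weight": None},
    "decision_tree": {"criterion": "gini", "class_weight": None},
    "linear_onehot": {"variant": "least_squares"},  # or "logistic"
    "svm_pca": {"kernel": "rbf", "C": 1.0, "variance_fraction": 0.95,
                "class_weight": None},
    "lstm": {
        "hidden_size": 64,
        "epochs": 100,
        "learning_rate": 1e-3,
        "batch_size": 8,
        "sequence_mode": "per_feature",
    },
}


@dataclass(frozen=True)
class ModelConfig:
    """A classifier family plus its hyperparameters and seed."""

    kind: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise DomainError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")
        unknown = set(self.hyperparameters) - set(_DEFAULT_HYPERPARAMETERS[self.kind])
        if unknown:
            raise DomainError(f"unknown hyperparameters for {self.kind}: {sorted(unknown)}")

    def resolved_hyperparameters(self) -> dict[str, Any]:
        merged = dict(_DEFAULT_HYPERPARAMETERS[self.kind])
        merged.update(self.hyperparameters)
        return merged

    def as_dict(self) -> dict[str, Any]:
        return {
            "kind": self.kind,
            "hyperparameters": self.resolved_hyperparameters(),
            "seed": self.seed,
        }


@dataclass
class OneHotLinearModel:
    """Least-squares one-hot multiclass model: coefficients beta (p x c)
    and intercepts beta0 (length c)."""

    beta: np.ndarray
    beta0: np.ndarray
    codes: np.ndarray  # class codes in column order

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) @ self.beta + self.beta0

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_values(X)
        # argmax returns the first maximum; codes are sorted ascending, so
        # ties resolve to the lowest class code
        return self.codes[np.argmax(scores, axis=1)]


def _fit_linear_onehot(X: np.ndarray, codes: np.ndarray) -> OneHotLinearModel:
    classes = np.unique(codes)
    Y = (codes[:, None] == classes[None, :]).astype(np.float64)
    A = np.column_stack([np.ones(X.shape[0]), X])
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    return OneHotLinearModel(beta=coef[1:], beta0=coef[0], codes=classes)


@dataclass
class FittedModel:
    """Opaque trained classifier with a uniform predict contract."""

    config: ModelConfig
    class_map: ClassMap
    n_features: int
    _state: Any = field(repr=False, default=None)
    _pca: PCA | None = field(repr=False, default=None)

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ShapeError(
                f"model was trained on {self.n_features} features, got "
                f"{X.shape[1] if X.ndim == 2 else '?'}"
            )
        if self._pca is not None:
            X = self._pca.transform(X)
        if isinstance(self._state, OneHotLinearModel):
            return self._state.predict_codes(X)
        return np.asarray(self._state.predict(X), dtype=np.int64)

    def predict(self, matrix_or_values) -> np.ndarray:
        """Predict class names for an ExpressionMatrix or raw value array."""
        X = (
            matrix_or_values.values
            if isinstance(matrix_or_values, ExpressionMatrix)
            else matrix_or_values
        )
        codes = self.predict_codes(X)
        names = np.array(self.class_map.names, dtype=object)
        return names[codes - 1]


def apply_pca(
    train_values: np.ndarray, variance_fraction: float = 0.95
) -> tuple[np.ndarray, PCA]:
    """Fit PCA on training rows, keeping the minimal number of components
    whose cumulative explained variance reaches ``variance_fraction``.

    Returns the transformed training matrix and the fitted projection (to be
    reused unchanged on test rows).  ``variance_fraction=1.0`` keeps the
    complete min(n-1, p) basis.
    """
    if not 0.0 < variance_fraction <= 1.0:
        raise DomainError("variance_fraction must be in (0, 1]")
    X = np.asarray(train_values, dtype=np.float64)
    if variance_fraction == 1.0:
        n_components: int | float = min(X.shape[0] - 1, X.shape[1])
    else:
        n_components = variance_fraction
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(X), pca


def fit(matrix: ExpressionMatrix, config: ModelConfig) -> FittedModel:
    """Train one classifier on ``matrix`` (already restricted to the
    selected genes); deterministic given (data, config.seed)."""
    codes = matrix.label_codes
    if np.unique(codes).size < 2:
        raise DomainError("training data contains a single class")
    X = matrix.values
    hp = config.resolved_hyperparameters()
    pca = None

    if config.kind == "random_forest":
        state = RandomForestClassifier(
            n_estimators=hp["n_trees"], class_weight=hp["class_weight"],
            random_state=config.seed,
        ).fit(X, codes)
    elif config.kind == "decision_tree":
        state = DecisionTreeClassifier(
            criterion=hp["criterion"], class_weight=hp["class_weight"],
            random_state=config.seed,
        ).fit(X, codes)
    elif config.kind == "linear_onehot":
        if hp["variant"] == "least_squares":
            state = _fit_linear_onehot(X, codes)
        elif hp["variant"] == "logistic":
            state = LogisticRegression(max_iter=5000, random_state=config.seed).fit(
                X, codes
            )
        else:
            raise DomainError(f"unknown linear_onehot variant {hp['variant']!r}")
    elif config.kind == "svm_pca":
        Xp, pca = apply_pca(X, hp["variance_fraction"])
        state = OneVsRestClassifier(
            SVC(kernel=hp["kernel"], C=hp["C"],
                class_weight=hp["class_weight"], random_state=config.seed)
        ).fit(Xp, codes)
    elif config.kind == "lstm":
        state = LSTMClassifier(
            hidden_size=hp["hidden_size"],
            epochs=hp["epochs"],
            learning_rate=hp["learning_rate"],
            batch_size=hp["batch_size"],
            sequence_mode=hp["sequence_mode"],
            seed=config.seed,
        ).fit(X, codes)
    else:  # pragma: no cover - guarded by ModelConfig
        raise DomainError(config.kind)

    return FittedModel(
        config=config,
        class_map=matrix.class_map,
        n_features=X.shape[1],
        _state=state,
        _pca=pca,
    )


def predict(model: FittedModel, matrix: ExpressionMatrix) -> np.ndarray:
    """Predict class names for every row of ``matrix``."""
    return model.predict(matrix)
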