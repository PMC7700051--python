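"""Single-hidden-layer multilayer perceptron classifier.

The network follows the reference configuration: one hidden layer of
floor((n_inputs + n_classes) / 2) logistic units, plain gradient descent at
a constant learning rate of 0.3 for 500 epochs, no momentum and no weight
decay.  Inputs are standardized per feature (statistics from the training
data only) because a 0.3 learning rate diverges on raw tripeptide-frequency
scales.  Training is deterministic given (data, config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of the single-hidden-layer perceptron.

    ``hidden_units`` defaults to floor((n_inputs + n_classes) / 2); the
    learning rate and epoch count default to 0.3 and 500.
    """

    n_inputs: int
    n_classes: int = 2
    hidden_units: int | None = None
    learning_rate: float = 0.3
    epochs: int = 500
    seed: int = 0
    momentum: float = 0.0

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if self.hidden_units is not None and self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def resolved_hidden_units(self) -> int:
        if self.hidden_units is not None:
            return self.hidden_units
        return (self.n_inputs + self.n_classes) // 2


def build_config(n_inputs: int, **overrides) -> MLPConfig:
    """Apply the sizing rule and defaults, then any overrides."""
    return replace(MLPConfig(n_inputs=n_inputs), **overrides)


class AmyloidMLP(ClassifierMixin, BaseEstimator):
    """scikit-learn classifier wrapping the standardizer + MLP.

    Parameters
    ----------
    hidden_units : int or None
        Hidden-layer width; None applies the floor((d + 2) / 2) rule at fit
        time.
    learning_rate : float, default 0.3
    epochs : int, default 500
        Number of full-batch gradient-descent passes.
    momentum : float, default 0.0
    standardize : bool, default True
        Standardize features using training statistics.
    random_state : int, default 0
        Seeds weight initialization; fitting is deterministic.

    Attributes (after fit)
    ----------------------
    classes_ : ndarray of the two class labels
    config_ : MLPConfig actually used
    scaler_ : fitted StandardScaler (or None)
    net_ : fitted sklearn MLPClassifier
    feature_names_ : set when fit is given explicit names
    """

    def __init__(
        self,
        hidden_units: int | None = None,
        learning_rate: float = 0.3,
        epochs: int = 500,
        momentum: float = 0.0,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.momentum = momentum
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y, feature_names=None):
        X, y = validate_data(self, X, y, dtype=float, reset=True)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"need exactly 2 classes in y, got {self.classes_.size}"
            )
        if feature_names is not None:
            self.feature_names_ = np.asarray(feature_names, dtype=object)
            if self.feature_names_.size != X.shape[1]:
                raise ValueError("feature_names length does not match X")
        self.config_ = MLPConfig(
            n_inputs=X.shape[1],
            hidden_units=self.hidden_units,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            seed=self.random_state,
            momentum=self.momentum,
        )
        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            X = self.scaler_.transform(X)
        else:
            self.scaler_ = None
        self.net_ = MLPClassifier(
            hidden_layer_sizes=(self.config_.resolved_hidden_units,),
            activation="logistic",
            solver="sgd",
            alpha=0.0,
            batch_size=X.shape[0],
            learning_rate="constant",
            learning_rate_init=self.learning_rate,
            max_iter=self.epochs,
            shuffle=False,
            random_state=self.random_state,
            momentum=self.momentum,
            nesterovs_momentum=False,
            n_iter_no_change=self.epochs,
            early_stopping=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.net_.fit(X, y)
        if not np.all(np.isfinite(self.net_.loss_curve_)):
            raise RuntimeError("training diverged: non-finite loss")
        return self

    def _prepare(self, X, feature_names=None) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = validate_data(self, X, dtype=float, reset=False)
        if feature_names is not None:
            expected = getattr(self, "feature_names_", None)
            if expected is None or list(expected) != list(feature_names):
                raise ValueError("feature names/order do not match training")
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        return X

    def predict(self, X, feature_names=None) -> np.ndarray:
        return self.net_.predict(self._prepare(X, feature_names))

    def predict_proba(self, X, feature_names=None) -> np.ndarray:
        return self.net_.predict_proba(self._prepare(X, feature_names))

    def predict_score(self, X, feature_names=None) -> np.ndarray:
        """Positive-class score in [0, 1], used for ROC curves."""
        proba = self.predict_proba(X, feature_names)
        pos_col = int(np.flatnonzero(self.classes_ == self.classes_.max())[0])
        return proba[:, pos_col]


def train(X, y, config: MLPConfig | None = None, feature_names=None) -> AmyloidMLP:
    """Fit an :class:`AmyloidMLP` from an optional :class:`MLPConfig`."""
    if config is None:
        config = build_config(np.asarray(X).shape[1])
    model = AmyloidMLP(
        hidden_units=config.hidden_units,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        momentum=config.momentum,
        random_state=config.seed,
    )
    return model.fit(X, y, feature_names=feature_names)


def save_model(model: AmyloidMLP, path) -> None:
    """Persist a fitted model (config, feature names, scaler stats, weights)."""
    check_is_fitted(model, "net_")
    joblib.dump(model, path)


def load_model(path) -> AmyloidMLP:
    model = joblib.load(path)
    if not isinstance(model, AmyloidMLP):
        raise TypeError(f"{path} does not contain an AmyloidMLP model")
    return model
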