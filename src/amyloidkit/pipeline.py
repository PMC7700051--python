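"""End-to-end classifier over precomputed encoder blocks.

:class:`AmyloidPipeline` bundles MRMD selection of the 188-dim CTD block,
binomial-distribution selection of the tripeptide block, and the MLP into
one scikit-learn classifier.  Its input is the column-wise concatenation
``[188D | TPC counts | TPC frequencies]`` (188 + 8000 + 8000 columns),
which :func:`stack_blocks` builds from raw records.  Because selection is
part of ``fit``, cross-validating this estimator re-ranks features inside
every training fold — the selected subsets never see test labels, so
cross-validation accuracy is free of feature-selection bias (ranking the
full dataset first and cross-validating after inflates accuracy on
label-free data).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .features import SVMProt188Encoder, TripeptideEncoder
from .model import AmyloidMLP
from .selection import BinomialSelector, MRMDSelector

N_188 = 188
N_TPC = 8000
STACKED_WIDTH = N_188 + 2 * N_TPC


def stack_blocks(records) -> np.ndarray:
    """(n, 16188) array: SVMProt-188D, TPC counts, TPC frequencies."""
    x188 = SVMProt188Encoder().fit(records).transform(records)
    counts = TripeptideEncoder(output="count").fit(records).transform(records)
    freq = TripeptideEncoder(output="frequency").fit(records).transform(records)
    return np.hstack([x188, counts, freq])


class AmyloidPipeline(ClassifierMixin, BaseEstimator):
    """Select-then-classify pipeline as a single estimator.

    Parameters
    ----------
    k_188 : int, default 121
        CTD features kept by MRMD.
    k_tpc : int, default 425
        Tripeptides kept by binomial-distribution ranking.
    metric : {"ED", "COS", "TC", "MEAN"}, default "ED"
        MRMD distance function.
    epochs, learning_rate, hidden_units, random_state
        Passed to :class:`~amyloidkit.model.AmyloidMLP`.
    """

    def __init__(
        self,
        k_188: int = 121,
        k_tpc: int = 425,
        metric: str = "ED",
        epochs: int = 500,
        learning_rate: float = 0.3,
        hidden_units: int | None = None,
        random_state: int = 0,
    ):
        self.k_188 = k_188
        self.k_tpc = k_tpc
        self.metric = metric
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.hidden_units = hidden_units
        self.random_state = random_state

    def _split(self, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if X.shape[1] != STACKED_WIDTH:
            raise ValueError(
                f"expected {STACKED_WIDTH} stacked columns "
                f"(188D | TPC counts | TPC frequencies), got {X.shape[1]}"
            )
        return (
            X[:, :N_188],
            X[:, N_188 : N_188 + N_TPC],
            X[:, N_188 + N_TPC :],
        )

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float, reset=True)
        x188, counts, freq = self._split(X)
        self.mrmd_ = MRMDSelector(k=self.k_188, metric=self.metric).fit(x188, y)
        self.bd_ = BinomialSelector(k=self.k_tpc).fit(counts, y)
        self.classes_ = np.unique(y)
        Xsel = np.hstack([self.mrmd_.transform(x188), self.bd_.transform(freq)])
        self.mlp_ = AmyloidMLP(
            hidden_units=self.hidden_units,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            random_state=self.random_state,
        ).fit(Xsel, y)
        return self

    def _select(self, X) -> np.ndarray:
        check_is_fitted(self, "mlp_")
        X = validate_data(self, X, dtype=float, reset=False)
        x188, _, freq = self._split(X)
        return np.hstack([self.mrmd_.transform(x188), self.bd_.transform(freq)])

    def predict(self, X) -> np.ndarray:
        return self.mlp_.predict(self._select(X))

    def predict_proba(self, X) -> np.ndarray:
        return self.mlp_.predict_proba(self._select(X))

    def predict_score(self, X) -> np.ndarray:
        return self.mlp_.predict_score(self._select(X))
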