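"""k-nearest-neighbor regression on the standardized phasor features.

The simpler comparator: a query decay's (a1, tau1, tau2) is the unweighted
mean of the parameter triples of its k nearest training decays under
Euclidean distance in standardized feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import KNeighborsRegressor

from .exceptions import ConfigurationError
from .features import FeatureScaler, apply_scaler, fit_scaler

__all__ = ["KNNModel", "knn_fit", "knn_predict"]


@dataclass
class KNNModel:
    regressor: KNeighborsRegressor
    scaler: FeatureScaler
    k: int


def knn_fit(
    features: np.ndarray,
    params: np.ndarray,
    k: int = 5,
    scaler: FeatureScaler | None = None,
) -> KNNModel:
    """Index training features (standardized internally) for k-NN regression.

    Distance ties are broken by training index order.  ``scaler`` may be
    supplied to reuse the network's standardization; otherwise one is fit
    on ``features``.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    Y = np.atleast_2d(np.asarray(params, dtype=float))
    if X.shape[0] == 0:
        raise ConfigurationError("empty training set")
    if Y.shape[0] != X.shape[0]:
        raise ConfigurationError("features and params must have equal length")
    if not (1 <= k <= X.shape[0]):
        raise ConfigurationError(f"k must be in [1, {X.shape[0]}]")
    scaler = scaler or fit_scaler(X)
    reg = KNeighborsRegressor(n_neighbors=k, weights="uniform", algorithm="brute")
    reg.fit(apply_scaler(X, scaler), Y)
    return KNNModel(reg, scaler, k)


def knn_predict(model: KNNModel, features: np.ndarray) -> np.ndarray:
    """Predicted (a1, tau1, tau2) rows, lifetimes sorted (a1 complemented on swap)."""
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    out = model.regressor.predict(apply_scaler(np.atleast_2d(X), model.scaler))
    swap = out[:, 1] > out[:, 2]
    out[swap, 0] = 1.0 - out[swap, 0]
    out[swap, 1:] = out[swap, 1:][:, ::-1]
    return out[0] if single else out
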