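"""Random-forest and support-vector regression wrappers (scikit-learn)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR

from ..data_io import Dataset
from .base import check_train


@dataclass
class SkModelFit:
    tag: str
    estimator: object
    marker_names: list
    use_replicate: bool = True

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        want = self.estimator.n_features_in_
        if X.shape[1] > want:
            X = X[:, :want]
        return self.estimator.predict(X)

    def predict(self, d: Dataset) -> np.ndarray:
        return self.predict_matrix(d.features(use_replicate=self.use_replicate))


def fit_rf(train: Dataset, n_trees: int = 1000, seed: int = 0,
           use_replicate: bool = True, max_depth: int | None = None,
           **kwargs) -> SkModelFit:
    """Regression forest with ``n_trees`` trees; all other settings at
    scikit-learn defaults. Deterministic given the seed."""
    check_train(train, min_records=1)
    est = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                max_depth=max_depth, n_jobs=1, **kwargs)
    est.fit(train.features(use_replicate=use_replicate), train.y)
    return SkModelFit("RF", est, list(train.marker_names), use_replicate)


def fit_svr(train: Dataset, use_replicate: bool = True, **kwargs) -> SkModelFit:
    """Epsilon-insensitive SVR with an RBF kernel at library defaults."""
    check_train(train, min_records=1)
    est = SVR(kernel="rbf", **kwargs)
    est.fit(train.features(use_replicate=use_replicate), train.y)
    return SkModelFit("SVR", est, list(train.marker_names), use_replicate)
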