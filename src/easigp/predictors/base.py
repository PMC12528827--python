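from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

from ..data_io import Dataset


@runtime_checkable
class FittedModel(Protocol):
    """Common surface of all fitted genomic prediction models."""

    tag: str
    use_replicate: bool

    def predict(self, d: Dataset) -> np.ndarray: ...

    def predict_matrix(self, X: np.ndarray) -> np.ndarray: ...


def dataset_features(d: Dataset, use_replicate: bool) -> np.ndarray:
    return d.features(use_replicate=use_replicate)


def check_train(d: Dataset, min_records: int = 2) -> None:
    if d.n_records < min_records:
        raise ValueError(f"need at least {min_records} training records, got {d.n_records}")
    if d.n_markers < 1:
        raise ValueError("need at least one marker")
    if np.isnan(d.y).any():
        raise ValueError("training phenotypes contain missing values")
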