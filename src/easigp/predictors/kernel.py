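"""Gaussian-kernel RKHS regression solved as a kernel mixed model."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..data_io import Dataset
from .base import check_train
from .linear import _fixed_design, _reml_delta


def gaussian_kernel(G1: np.ndarray, G2: np.ndarray, h: float) -> np.ndarray:
    """K[i, i'] = exp(-h * mean_k (x_ik - x_i'k)^2); values in (0, 1]."""
    G1 = np.atleast_2d(np.asarray(G1, dtype=float))
    G2 = np.atleast_2d(np.asarray(G2, dtype=float))
    if G1.shape[1] != G2.shape[1]:
        raise ValueError("marker counts differ between genotype matrices")
    p = G1.shape[1]
    if p == 0:
        raise ValueError("kernel undefined for zero markers")
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    sq = (np.sum(G1 ** 2, axis=1)[:, None] + np.sum(G2 ** 2, axis=1)[None, :]
          - 2.0 * G1 @ G2.T)
    return np.exp(-h * np.clip(sq, 0.0, None) / p)


@dataclass
class KernelModelFit:
    """RKHS fit: y = Fb + u + eps with u ~ N(0, K sigma2_u)."""

    tag: str
    h: float
    p: int
    mu: float
    fixed: np.ndarray
    alpha: np.ndarray           # dual coefficients: u_hat = K alpha
    train_G: np.ndarray
    K: np.ndarray
    sigma2_u: float
    sigma2_eps: float
    marker_names: list
    use_replicate: bool = True

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Kx = gaussian_kernel(X[:, :self.p], self.train_G, self.h)
        out = self.mu + Kx @ self.alpha
        nfix = len(self.fixed)
        if self.use_replicate and nfix and X.shape[1] >= self.p + nfix:
            out = out + X[:, self.p:self.p + nfix] @ self.fixed
        return out

    def predict(self, d: Dataset) -> np.ndarray:
        return self.predict_matrix(d.features(use_replicate=self.use_replicate))


def fit_rkhs(train: Dataset, h: float = 1.0, lam: float | None = None,
             use_replicate: bool = True) -> KernelModelFit:
    """Kernel mixed model solved via (K + lambda I) alpha = y - Fb with
    lambda = sigma2_eps / sigma2_u from REML unless pinned by ``lam``."""
    check_train(train)
    y = train.y.astype(float)
    F = _fixed_design(train, use_replicate)
    G = train.G.astype(float)
    p = train.n_markers
    K = gaussian_kernel(G, G, h)
    K = (K + K.T) / 2

    ev = np.linalg.eigvalsh(K)
    if ev.min() < -1e-6:
        raise ValueError(f"kernel matrix not PSD (min eigenvalue {ev.min():.3g})")

    if np.var(y) == 0:
        return KernelModelFit("RKHS", h, p, float(y[0]), np.zeros(F.shape[1] - 1),
                              np.zeros(train.n_records), G, K, 0.0, 0.0,
                              list(train.marker_names), use_replicate)

    if lam is None:
        delta, s2u, s2e = _reml_delta(K, F, y)
    else:
        delta, s2u, s2e = float(lam), np.nan, np.nan
    n = train.n_records
    Vinv = np.linalg.inv(K + delta * np.eye(n) + 1e-10 * np.eye(n))
    b = np.linalg.solve(F.T @ Vinv @ F, F.T @ Vinv @ y)
    alpha = Vinv @ (y - F @ b)
    if lam is not None:
        resid = y - F @ b - K @ alpha
        s2e = float(resid @ resid / max(n - F.shape[1], 1))
        s2u = s2e / delta
    return KernelModelFit("RKHS", h, p, float(b[0]), np.asarray(b[1:]), alpha, G, K,
                          float(s2u), float(s2e), list(train.marker_names), use_replicate)
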