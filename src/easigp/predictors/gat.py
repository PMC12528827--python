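"""Bipartite graph attention network for phenotype regression.

Each feature (marker, plus optionally the replicate factor) is a node whose
dosage feeds a directed edge into a single phenotype node; there are no
marker-marker edges. One attention layer with ``channels`` hidden channels
and ELU activation pools the per-node embeddings into the phenotype node,
whose embedding is read out linearly. Attention coefficients over the
incoming edges are a softmax, so they are non-negative and sum to one.

Implemented directly in numpy (forward, analytic backprop, AdamW) so the
model trains on one CPU with no deep-learning framework, and so exact input
gradients are available for integrated-gradients attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..data_io import Dataset
from .base import check_train

_LEAKY = 0.2


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.clip(x, None, 30.0)))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.clip(x, None, 30.0)))


def _lrelu(x):
    return np.where(x > 0, x, _LEAKY * x)


def _lrelu_grad(x):
    return np.where(x > 0, 1.0, _LEAKY)


@dataclass
class GATFit:
    tag: str
    W: np.ndarray               # (n_features, channels) per-node projection
    a: np.ndarray               # (channels,) attention vector
    c: float                    # attention logit bias (target-node term)
    w2: np.ndarray              # (channels,) readout weights
    b2: float
    y_mean: float
    y_std: float
    marker_names: list
    config: dict = field(default_factory=dict)
    losses: np.ndarray | None = None
    use_replicate: bool = True

    # -- forward pieces ----------------------------------------------------
    def _forward(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = X[:, :, None] * self.W[None, :, :]            # (B, p, C)
        u = z @ self.a + self.c                           # (B, p)
        e = _lrelu(u)
        e = e - e.max(axis=1, keepdims=True)
        alpha = np.exp(e)
        alpha /= alpha.sum(axis=1, keepdims=True)
        s = np.einsum("bp,bpc->bc", alpha, z)
        h = _elu(s)
        pred = h @ self.w2 + self.b2
        return X, z, u, alpha, s, h, pred

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        if np.ndim(X) == 2 and np.shape(X)[1] != self.W.shape[0]:
            raise ValueError(f"expected {self.W.shape[0]} features, got {np.shape(X)[1]}")
        *_, pred = self._forward(X)
        return pred * self.y_std + self.y_mean

    def predict(self, d: Dataset) -> np.ndarray:
        return self.predict_matrix(d.features(use_replicate=self.use_replicate))

    def attention(self, X: np.ndarray) -> np.ndarray:
        """Attention coefficients over the phenotype node's incoming edges,
        one row per record (each row sums to 1)."""
        _, _, _, alpha, *_ = self._forward(X)
        return alpha

    def input_gradients(self, X: np.ndarray) -> np.ndarray:
        """d prediction / d feature, analytically, on the original y scale."""
        X, z, u, alpha, s, h, _ = self._forward(X)
        aw = self.W @ self.a                                        # (p,)
        gate = _lrelu_grad(u) * aw[None, :] * alpha                 # (B, p)
        ds = alpha[:, :, None] * self.W[None, :, :] \
            + gate[:, :, None] * (z - s[:, None, :])                # (B, p, C)
        head = self.w2[None, :] * _elu_grad(s)                      # (B, C)
        return np.einsum("bc,bpc->bp", head, ds) * self.y_std


def fit_gat(train: Dataset, channels: int = 20, epochs: int = 50, batch: int = 8,
            lr: float = 0.005, weight_decay: float = 0.0, seed: int = 0,
            use_replicate: bool = True) -> GATFit:
    """Train the bipartite attention network with AdamW on mean squared error.

    The phenotype is standardized internally; raising a ``FloatingPointError``
    on a non-finite loss rather than returning garbage.
    """
    check_train(train)
    rng = np.random.default_rng(seed)
    X = train.features(use_replicate=use_replicate)
    n, p = X.shape
    y_mean, y_std = float(train.y.mean()), float(train.y.std())
    if y_std == 0:
        y_std = 1.0
    yt = (train.y - y_mean) / y_std

    C = channels
    params = {
        "W": rng.normal(0.0, np.sqrt(2.0 / (1 + C)), size=(p, C)),
        "a": rng.normal(0.0, np.sqrt(1.0 / C), size=C),
        "c": np.zeros(()),
        "w2": rng.normal(0.0, np.sqrt(1.0 / C), size=C),
        "b2": np.zeros(()),
    }
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    losses = []

    def forward_backward(Xb, yb):
        W, a, c, w2, b2 = params["W"], params["a"], params["c"], params["w2"], params["b2"]
        B = Xb.shape[0]
        z = Xb[:, :, None] * W[None, :, :]
        u = z @ a + c
        e = _lrelu(u)
        e_sh = e - e.max(axis=1, keepdims=True)
        alpha = np.exp(e_sh)
        alpha /= alpha.sum(axis=1, keepdims=True)
        s = np.einsum("bp,bpc->bc", alpha, z)
        h = _elu(s)
        pred = h @ w2 + b2
        err = pred - yb
        loss = float(np.mean(err ** 2))

        g = 2.0 * err / B                                           # (B,)
        grads = {}
        grads["w2"] = h.T @ g
        grads["b2"] = np.sum(g)
        vv = g[:, None] * w2[None, :] * _elu_grad(s)                # (B, C)
        vz = np.einsum("bc,bpc->bp", vv, z)
        vs = np.einsum("bc,bc->b", vv, s)
        de = alpha * (vz - vs[:, None])                             # softmax jacobian applied
        lg = _lrelu_grad(u)
        grads["c"] = np.sum(de * lg)
        grads["a"] = np.einsum("bp,bpc->c", de * lg, z)
        dz = alpha[:, :, None] * vv[:, None, :] \
            + (de * lg)[:, :, None] * a[None, None, :]
        grads["W"] = np.einsum("bpc,bp->pc", dz, Xb)
        return loss, grads

    for _epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            loss, grads = forward_backward(X[idx], yt[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("GAT training loss diverged (non-finite)")
            losses.append(loss)
            t += 1
            for k in params:
                gk = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * gk
                v[k] = beta2 * v[k] + (1 - beta2) * gk ** 2
                mhat = m[k] / (1 - beta1 ** t)
                vhat = v[k] / (1 - beta2 ** t)
                params[k] = params[k] - lr * (mhat / (np.sqrt(vhat) + eps)
                                              + weight_decay * params[k])

    return GATFit(
        "GAT", params["W"], params["a"], float(params["c"]), params["w2"],
        float(params["b2"]), y_mean, y_std, list(train.marker_names),
        config=dict(channels=channels, epochs=epochs, batch=batch, lr=lr,
                    weight_decay=weight_decay, seed=seed),
        losses=np.asarray(losses), use_replicate=use_replicate,
    )
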