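"""Linear marker-effect models: rrBLUP (ridge/BLUP with REML shrinkage)
and BayesB (spike-and-slab Gibbs sampler)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from ..data_io import Dataset
from .base import check_train


@dataclass
class LinearModelFit:
    """Fitted additive model y = mu + [replicate] + X beta + eps."""

    tag: str
    mu: float
    beta: np.ndarray            # per-marker allele-substitution effects
    fixed: np.ndarray           # coefficients of extra fixed columns (replicate)
    centers: np.ndarray         # marker means used for centering
    sigma2_beta: float
    sigma2_eps: float
    marker_names: list
    use_replicate: bool = True
    inclusion_prob: np.ndarray | None = None   # BayesB only
    pi: float | None = None                    # BayesB slab proportion
    beta_sd: np.ndarray | None = None          # posterior SDs (BayesB)

    def __post_init__(self):
        if len(self.beta) != len(self.marker_names):
            raise ValueError("beta length does not match marker count")
        if self.sigma2_beta < 0 or self.sigma2_eps < 0:
            raise ValueError("variance components must be non-negative")
        if self.inclusion_prob is not None:
            ip = np.asarray(self.inclusion_prob)
            if ip.min() < -1e-12 or ip.max() > 1 + 1e-12:
                raise ValueError("inclusion probabilities outside [0,1]")

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p = len(self.beta)
        out = self.mu + (X[:, :p] - self.centers) @ self.beta
        nfix = len(self.fixed)
        if self.use_replicate and nfix and X.shape[1] >= p + nfix:
            out = out + X[:, p:p + nfix] @ self.fixed
        return out

    def predict(self, d: Dataset) -> np.ndarray:
        return self.predict_matrix(d.features(use_replicate=self.use_replicate))


def _fixed_design(d: Dataset, use_replicate: bool) -> np.ndarray:
    cols = [np.ones(d.n_records)]
    if use_replicate and len(np.unique(d.replicate)) > 1:
        cols.append(d.replicate.astype(float))
    return np.column_stack(cols)


def _reml_delta(K: np.ndarray, F: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """REML estimate of delta = sigma2_e / sigma2_u for y ~ N(Fb, sigma2_u K + sigma2_e I).

    Spectral (EMMA-style) formulation: eigendecompose the genetic covariance
    projected off the fixed effects and maximise the restricted likelihood
    over delta on a log grid refined by Brent search.
    """
    n, q = F.shape
    S = np.eye(n) - F @ np.linalg.pinv(F.T @ F) @ F.T
    M = S @ K @ S
    xi, U = np.linalg.eigh((M + M.T) / 2)
    xi, U = xi[q:], U[:, q:]            # drop the q eigenvalues tied to fixed effects
    xi = np.clip(xi, 0.0, None)
    eta2 = (U.T @ y) ** 2
    nq = n - q

    def neg_rll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        denom = xi + delta
        rss = np.sum(eta2 / denom)
        return 0.5 * (nq * np.log(rss) + np.sum(np.log(denom)))

    grid = np.linspace(-10, 10, 41)
    best = grid[np.argmin([neg_rll(g) for g in grid])]
    res = minimize_scalar(neg_rll, bounds=(best - 1.0, best + 1.0), method="bounded")
    delta = float(np.exp(res.x))
    sigma2_u = float(np.sum(eta2 / (xi + delta)) / nq)
    return delta, sigma2_u, delta * sigma2_u


def fit_rrblup(train: Dataset, lam: float | None = None,
               use_replicate: bool = True) -> LinearModelFit:
    """Ridge-regression BLUP: beta solves (X'X + lambda I) beta = X'(y - Fb),
    with lambda = sigma2_eps / sigma2_beta from REML unless fixed via ``lam``.

    Solved in the n x n dual (GBLUP) form and mapped back to marker effects,
    which is exactly equivalent and cheap when p >> n.
    """
    check_train(train)
    y = train.y.astype(float)
    F = _fixed_design(train, use_replicate)
    Xr = train.G.astype(float)
    centers = Xr.mean(axis=0)
    Xc = Xr - centers

    if np.var(y) == 0:
        return LinearModelFit("rrBLUP", float(y[0]), np.zeros(train.n_markers),
                              np.zeros(F.shape[1] - 1), centers, 0.0, 0.0,
                              list(train.marker_names), use_replicate)

    K = Xc @ Xc.T
    if lam is None:
        delta, s2u, s2e = _reml_delta(K, F, y)
    else:
        delta = float(lam)
        s2u, s2e = np.nan, np.nan
    n = train.n_records
    Vinv = np.linalg.inv(K + delta * np.eye(n))
    b = np.linalg.solve(F.T @ Vinv @ F, F.T @ Vinv @ y)
    alpha = Vinv @ (y - F @ b)
    beta = Xc.T @ alpha
    if lam is not None:
        resid = y - F @ b - Xc @ beta
        s2e = float(resid @ resid / max(n - F.shape[1], 1))
        s2u = s2e / delta
    return LinearModelFit("rrBLUP", float(b[0]), beta, np.asarray(b[1:]), centers,
                          float(s2u), float(s2e), list(train.marker_names), use_replicate)


def _scaled_inv_chi2(rng: np.random.Generator, df: float, scale: float) -> float:
    return df * scale / rng.chisquare(df)


def fit_bayesb(train: Dataset, n_iter: int = 12000, burn_in: int = 2000,
               seed: int = 0, use_replicate: bool = True,
               nu: float = 5.0, h2_prior: float = 0.5,
               fixed_pi: float | None = None,
               fixed_slab_var: float | None = None,
               fixed_sigma2_eps: float | None = None,
               thin: int = 1) -> LinearModelFit:
    """BayesB via single-site Gibbs sampling.

    Prior: beta_j = 0 with probability 1 - pi, otherwise N(0, sigma2_j) with
    sigma2_j ~ scaled-inv-chi2(nu, S); pi ~ Beta(1, 1) (prior mean 0.5). The
    slab scale S is solved from an assumed prior heritability ``h2_prior``.
    Reported effects are posterior means over post-burn-in samples.

    ``fixed_pi`` / ``fixed_slab_var`` / ``fixed_sigma2_eps`` pin the
    corresponding parameters (used to check convergence to the ridge
    solution when the spike is switched off).
    """
    check_train(train)
    if n_iter <= burn_in:
        raise ValueError(f"n_iter ({n_iter}) must exceed burn_in ({burn_in})")
    rng = np.random.default_rng(seed)
    y = train.y.astype(float)
    F = _fixed_design(train, use_replicate)
    centers = train.G.astype(float).mean(axis=0)
    X = train.G.astype(float) - centers
    n, p = X.shape
    xx = np.einsum("ij,ij->j", X, X)
    vary = float(np.var(y))

    if vary == 0:
        return LinearModelFit("BayesB", float(y[0]), np.zeros(p), np.zeros(F.shape[1] - 1),
                              centers, 0.0, 0.0, list(train.marker_names), use_replicate,
                              inclusion_prob=np.zeros(p), pi=0.0, beta_sd=np.zeros(p))

    msx = float(np.sum(np.var(X, axis=0))) or 1.0
    pi0 = 0.5 if fixed_pi is None else float(fixed_pi)
    # prior slab scale: expected genetic variance = h2_prior * var(y)
    S_slab = max(h2_prior * vary / (pi0 * msx), 1e-12) * (nu - 2) / nu
    nu_e, S_e = 5.0, max((1 - h2_prior) * vary, 1e-12) * 3.0 / 5.0

    beta = np.zeros(p)
    delta_ind = np.zeros(p, dtype=bool)
    sigma2_j = np.full(p, nu * S_slab / (nu - 2))
    sigma2_e = (1 - h2_prior) * vary if fixed_sigma2_eps is None else float(fixed_sigma2_eps)
    pi = pi0
    b = np.linalg.lstsq(F, y, rcond=None)[0]
    resid = y - F @ b

    kept = 0
    beta_sum = np.zeros(p)
    beta_sq = np.zeros(p)
    incl_sum = np.zeros(p)
    b_sum = np.zeros(F.shape[1])
    pi_sum = 0.0
    s2e_sum = 0.0
    FtF_inv = np.linalg.inv(F.T @ F)

    for it in range(n_iter):
        # fixed effects
        resid += F @ b
        b_hat = FtF_inv @ (F.T @ resid)
        b = b_hat + np.linalg.cholesky(FtF_inv * sigma2_e) @ rng.standard_normal(F.shape[1])
        resid -= F @ b

        order = rng.permutation(p)
        for j in order:
            if beta[j] != 0.0:
                resid += X[:, j] * beta[j]
            rhs = X[:, j] @ resid
            s2 = sigma2_j[j] if fixed_slab_var is None else fixed_slab_var
            if xx[j] == 0:
                beta[j] = 0.0
                delta_ind[j] = False
                continue
            # marginal log-likelihood ratio of slab vs spike
            d1 = xx[j] * s2 + sigma2_e
            log_bf = -0.5 * np.log(d1 / sigma2_e) + 0.5 * rhs ** 2 * s2 / (sigma2_e * d1)
            log_odds = np.log(pi / (1 - pi)) + log_bf if 0 < pi < 1 else (np.inf if pi >= 1 else -np.inf)
            p_in = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
            if rng.random() < p_in:
                c_var = 1.0 / (xx[j] / sigma2_e + 1.0 / s2)
                beta[j] = rng.normal(c_var * rhs / sigma2_e, np.sqrt(c_var))
                delta_ind[j] = True
                resid -= X[:, j] * beta[j]
            else:
                beta[j] = 0.0
                delta_ind[j] = False
            if fixed_slab_var is None:
                if delta_ind[j]:
                    sigma2_j[j] = _scaled_inv_chi2(rng, nu + 1, (nu * S_slab + beta[j] ** 2) / (nu + 1))
                else:
                    sigma2_j[j] = _scaled_inv_chi2(rng, nu, S_slab)

        if fixed_pi is None:
            k = int(delta_ind.sum())
            pi = rng.beta(1 + k, 1 + p - k)
            pi = min(max(pi, 1e-6), 1 - 1e-6)
        if fixed_sigma2_eps is None:
            sigma2_e = _scaled_inv_chi2(rng, nu_e + n, (nu_e * S_e + resid @ resid) / (nu_e + n))

        if it >= burn_in and (it - burn_in) % thin == 0:
            kept += 1
            beta_sum += beta
            beta_sq += beta ** 2
            incl_sum += delta_ind
            b_sum += b
            pi_sum += pi
            s2e_sum += sigma2_e

    beta_mean = beta_sum / kept
    beta_var = np.maximum(beta_sq / kept - beta_mean ** 2, 0.0)
    b_mean = b_sum / kept
    return LinearModelFit(
        "BayesB", float(b_mean[0]), beta_mean, np.asarray(b_mean[1:]), centers,
        float(np.mean(sigma2_j)), float(s2e_sum / kept), list(train.marker_names),
        use_replicate, inclusion_prob=incl_sum / kept, pi=float(pi_sum / kept),
        beta_sd=np.sqrt(beta_var),
    )
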