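"""Diagonal-covariance Gaussian mixtures fitted by EM.

The surrogate-extraction step needs a generative stand-in P for the joint
feature distribution of the training data, so that unlimited synthetic
feature vectors x~ ~ P can be drawn and labeled by the black box.  A mixture
of axis-aligned Gaussians,

    p(x) = sum_i  phi_i  N(x; mu_i, diag(sigma_i^2)),

is deliberately simple: it smooths over the empirical distribution (binary
and one-hot columns are treated as continuous coordinates) while remaining
cheap to fit and to sample.  Fitting is classical EM with a variance floor;
the number of components can be chosen by BIC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class DiagonalGMM:
    weights: np.ndarray          # (K,)
    means: np.ndarray            # (K, d)
    variances: np.ndarray        # (K, d), all >= var floor used at fit time
    feature_names: tuple[str, ...] = ()
    log_likelihood: float = np.nan
    n_iter: int = 0
    seed: int | None = None
    loglik_path: tuple[float, ...] = ()

    @property
    def K(self) -> int:
        return self.weights.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def validate(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-12):
            raise ValueError("mixture weights must sum to 1")
        if (self.weights < 0).any() or (self.weights > 1).any():
            raise ValueError("mixture weights must lie in [0, 1]")
        if (self.variances <= 0).any():
            raise ValueError("variances must be strictly positive")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "feature_names": list(self.feature_names),
            "log_likelihood": None if np.isnan(self.log_likelihood) else self.log_likelihood,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DiagonalGMM":
        from .tree import _read_text_maybe_path

        text = _read_text_maybe_path(source)
        payload = json.loads(text)
        return cls(
            weights=np.asarray(payload["weights"], dtype=float),
            means=np.asarray(payload["means"], dtype=float),
            variances=np.asarray(payload["variances"], dtype=float),
            feature_names=tuple(payload.get("feature_names", ())),
            log_likelihood=payload.get("log_likelihood") or np.nan,
            n_iter=payload.get("n_iter", 0),
            seed=payload.get("seed"),
        )


def _component_log_density(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(n, K) matrix of per-component log N(x; mu_i, diag var_i)."""
    # broadcast: (n, 1, d) - (K, d)
    z2 = (X[:, None, :] - means[None, :, :]) ** 2 / variances[None, :, :]
    return -0.5 * (z2.sum(axis=2) + np.log(variances).sum(axis=1)[None, :] + X.shape[1] * _LOG2PI)


def log_density(gmm: DiagonalGMM, x) -> float | np.ndarray:
    """log p(x) under the mixture, computed with log-sum-exp stability.

    Accepts a single vector (returns a scalar) or an (n, d) matrix.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != gmm.d:
        raise ValueError(f"expected {gmm.d} features, got {X.shape[1]}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in input")
    logp = logsumexp(_component_log_density(X, gmm.means, gmm.variances)
                     + np.log(gmm.weights)[None, :], axis=1)
    return float(logp[0]) if single else logp


def _kmeans_init(X: np.ndarray, K: int, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=K, n_init=1, random_state=seed)
    km.fit(X)
    return km.cluster_centers_


def fit_em(
    X,
    K: int,
    init: str = "kmeans",
    tol: float = 1e-6,
    max_iter: int = 500,
    var_floor_frac: float = 1e-6,
    seed: int = 0,
    feature_names: Sequence[str] = (),
) -> DiagonalGMM:
    """Maximum-likelihood fit of a K-component diagonal GMM by EM.

    E-step: responsibilities proportional to phi_i * N(x; mu_i, var_i).
    M-step: responsibility-weighted means, variances and weights.  Variances
    are floored at ``var_floor_frac`` times the column variance (one-hot
    columns would otherwise collapse to zero-width spikes).  Iteration stops
    when the absolute log-likelihood gain drops below ``tol`` or after
    ``max_iter`` sweeps; the recorded log-likelihood path is non-decreasing
    up to floating-point slack.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    n, d = X.shape
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in X")
    if K >= n:
        raise ValueError(f"K={K} must be smaller than n={n}")
    if tol <= 0:
        raise ValueError("tol must be positive")

    col_var = X.var(axis=0)
    var_floor = np.maximum(var_floor_frac * col_var, 1e-12)

    rng = np.random.default_rng(seed)
    if K == 1:
        means = X.mean(axis=0, keepdims=True)
    elif init == "kmeans":
        means = _kmeans_init(X, K, seed)
    elif init == "random":
        means = X[rng.choice(n, size=K, replace=False)]
    else:
        raise ValueError(f"unknown init {init!r}")
    variances = np.tile(np.maximum(col_var, var_floor), (K, 1))
    weights = np.full(K, 1.0 / K)

    path: list[float] = []
    prev = -np.inf
    for it in range(1, max_iter + 1):
        log_comp = _component_log_density(X, means, variances) + np.log(weights)[None, :]
        log_norm = logsumexp(log_comp, axis=1)
        loglik = float(log_norm.sum())
        path.append(loglik)
        resp = np.exp(log_comp - log_norm[:, None])  # (n, K)

        nk = resp.sum(axis=0)  # effective counts
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        sq = resp.T @ (X**2) / nk[:, None] - means**2
        variances = np.maximum(sq, var_floor[None, :])

        if loglik - prev < tol and it > 1:
            break
        prev = loglik

    return DiagonalGMM(
        weights=weights,
        means=means,
        variances=variances,
        feature_names=tuple(feature_names),
        log_likelihood=path[-1],
        n_iter=len(path),
        seed=seed,
        loglik_path=tuple(path),
    )


def sample(gmm: DiagonalGMM, m: int, seed: int = 0) -> np.ndarray:
    """Draw m rows: component by the mixture weights, then independent
    normals per coordinate.  m = 0 yields an empty (0, d) matrix."""
    if m < 0:
        raise ValueError("m must be non-negative")
    rng = np.random.default_rng(seed)
    comp = rng.choice(gmm.K, size=m, p=gmm.weights)
    return rng.normal(loc=gmm.means[comp], scale=np.sqrt(gmm.variances[comp]))


def bic(gmm: DiagonalGMM, X) -> float:
    """Bayesian information criterion: -2 loglik + n_params log n, with
    n_params = (K-1) + 2 K d for a diagonal mixture."""
    X = np.asarray(X, dtype=float)
    loglik = float(np.sum(log_density(gmm, X)))
    n_params = (gmm.K - 1) + 2 * gmm.K * gmm.d
    return -2.0 * loglik + n_params * np.log(X.shape[0])


def select_K(X, K_grid: Sequence[int], criterion: str = "BIC", seed: int = 0, **fit_kwargs) -> int:
    """Fit each K in the grid and return the BIC-minimizing one (ties ->
    smallest K).  Raises if every fit fails, listing per-K errors."""
    if criterion != "BIC":
        raise ValueError(f"unsupported criterion {criterion!r}")
    grid = sorted(set(int(k) for k in K_grid))
    if not grid:
        raise ValueError("empty K grid")
    best_K, best_bic = None, np.inf
    failures = {}
    for K in grid:
        try:
            gmm = fit_em(X, K, seed=seed, **fit_kwargs)
            score = bic(gmm, X)
        except Exception as exc:  # noqa: BLE001 - report per-K status
            failures[K] = repr(exc)
            continue
        if score < best_bic:
            best_bic, best_K = score, K
    if best_K is None:
        raise RuntimeError(f"all GMM fits failed: {failures}")
    return best_K
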