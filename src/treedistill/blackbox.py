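"""Black-box risk scorers and the imbalance-aware tuning harness.

The distillation pipeline is agnostic to what produced the risk score: any
object satisfying the :class:`RiskScorer` contract — a map from feature
vectors to probabilities in [0, 1] — can be distilled.  This module ships two
conforming reference scorers (a logistic baseline and a small feed-forward
network, both thin wrappers over scikit-learn) plus the training protocol
used throughout: stratified k-fold cross-validation with per-fold up- or
down-sampling of the training portion to counter class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier


@runtime_checkable
class RiskScorer(Protocol):
    """Feature matrix -> per-row probability of the positive outcome."""

    feature_names: tuple[str, ...]

    def score(self, X: np.ndarray) -> np.ndarray: ...


@dataclass
class SklearnScorer:
    """RiskScorer wrapping any fitted sklearn classifier with predict_proba."""

    model: Any
    feature_names: tuple[str, ...] = ()

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p = self.model.predict_proba(X)[:, 1]
        return np.clip(p, 0.0, 1.0)


@dataclass
class FunctionScorer:
    """RiskScorer from a plain vectorized function (useful for known truths)."""

    fn: Callable[[np.ndarray], np.ndarray]
    feature_names: tuple[str, ...] = ()

    def score(self, X: np.ndarray) -> np.ndarray:
        p = np.asarray(self.fn(np.asarray(X, dtype=float)), dtype=float)
        if p.size and (p.min() < 0.0 or p.max() > 1.0):
            raise ValueError("scorer produced values outside [0, 1]")
        return p


def rebalance(X, y, mode: str = "up", seed: int = 0):
    """Equalize class counts: 'up' resamples the minority with replacement,
    'down' subsamples the majority without replacement.  Deterministic under
    ``seed``; raises if y has a single class."""
    X = np.asarray(X)
    y = np.asarray(y)
    if mode not in ("up", "down"):
        raise ValueError(f"unknown rebalance mode {mode!r}")
    classes, counts = np.unique(y), None
    if classes.size != 2:
        raise ValueError("rebalance requires exactly two classes present")
    idx0 = np.flatnonzero(y == classes[0])
    idx1 = np.flatnonzero(y == classes[1])
    minority, majority = (idx0, idx1) if idx0.size < idx1.size else (idx1, idx0)
    if minority.size == majority.size:
        return X, y
    rng = np.random.default_rng(seed)
    if mode == "up":
        extra = rng.choice(minority, size=majority.size - minority.size, replace=True)
        keep = np.concatenate([majority, minority, extra])
    else:
        keep = np.concatenate([rng.choice(majority, size=minority.size, replace=False), minority])
    keep = np.sort(keep)
    return X[keep], y[keep]


def fit_logistic(X, y, feature_names: Sequence[str] = (), seed: int = 0, **kwargs) -> SklearnScorer:
    """Reference interpretable baseline: L2 logistic regression."""
    model = LogisticRegression(max_iter=2000, random_state=seed, **kwargs)
    model.fit(np.asarray(X, dtype=float), np.asarray(y))
    return SklearnScorer(model, tuple(feature_names))


def fit_mlp(
    X,
    y,
    feature_names: Sequence[str] = (),
    seed: int = 0,
    hidden_layer_sizes: tuple[int, ...] = (16,),
    alpha: float = 1e-3,
    max_iter: int = 200,
    **kwargs,
) -> SklearnScorer:
    """Reference black box: a small feed-forward network.

    The exact architecture is not the point — the distillation contract only
    sees the score function — so the defaults are deliberately modest.
    """
    model = MLPClassifier(
        hidden_layer_sizes=hidden_layer_sizes,
        alpha=alpha,
        max_iter=max_iter,
        random_state=seed,
        **kwargs,
    )
    model.fit(np.asarray(X, dtype=float), np.asarray(y))
    return SklearnScorer(model, tuple(feature_names))


ScorerBuilder = Callable[[np.ndarray, np.ndarray, int], RiskScorer]


def stratified_kfold_tune(
    X,
    y,
    scorer_factory: Callable[[dict], ScorerBuilder],
    param_grid: Sequence[dict],
    k: int = 5,
    metric: str = "auc",
    rebalance_mode: str | None = "up",
    seed: int = 0,
) -> tuple[dict, dict[int, list[float]]]:
    """Grid search by stratified k-fold CV with training-fold rebalancing.

    Folds preserve class proportions; rebalancing touches only the k-1
    training folds, never the held-out fold.  Returns the grid entry with the
    best mean fold score (ties broken in favour of the first-listed entry)
    and the per-entry fold scores.
    """
    from . import evaluation  # local import: evaluation depends on this module

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not param_grid:
        raise ValueError("empty parameter grid")
    if k < 2:
        raise ValueError("k must be >= 2")
    metric_fn = {"auc": evaluation.auc_roc, "auprc": evaluation.auprc}.get(metric)
    if metric_fn is None:
        raise ValueError(f"unsupported tuning metric {metric!r}")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for _, te in folds:
        if len(np.unique(y[te])) < 2:
            raise ValueError("a fold lacks one of the classes; reduce k")

    fold_scores: dict[int, list[float]] = {}
    best_params, best_mean = None, -np.inf
    for gi, params in enumerate(param_grid):
        builder = scorer_factory(params)
        scores = []
        for fi, (tr, te) in enumerate(folds):
            X_tr, y_tr = X[tr], y[tr]
            if rebalance_mode is not None:
                X_tr, y_tr = rebalance(X_tr, y_tr, mode=rebalance_mode, seed=seed + fi)
            scorer = builder(X_tr, y_tr, seed + fi)
            scores.append(float(metric_fn(y[te], scorer.score(X[te]))))
        fold_scores[gi] = scores
        mean = float(np.mean(scores))
        if mean > best_mean:
            best_mean, best_params = mean, params
    return best_params, fold_scores
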