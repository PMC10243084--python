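"""Surrogate-tree extraction: distilling a black-box scorer into a tree.

The two-step procedure: (1) train any black-box risk scorer f; (2) fit a
diagonal GMM P to the training features, draw synthetic feature vectors
x~ ~ P, label them with the scorer, and fit a tree to the pairs.  The
proposed variant keeps the scorer's *continuous* score y~ = f(x~) in [0, 1]
and fits a regression tree; the baseline variant first binarizes the score
at a threshold (0.5 by default, scores at the threshold mapping to 1) and
fits a classification tree — discarding the score's gradation, which is
precisely the information loss the regression variant avoids.

Samples from P may fall outside the physical feature support (a Gaussian
tail emits, e.g., negative lengths of stay).  They are passed to the scorer
unclipped by default — the scorer is a function on R^d and the surrogate
should approximate it where P puts mass — with optional per-feature
clipping for scorers that insist on valid ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import mixture
from .blackbox import RiskScorer
from .tree import Tree, TreeParams, fit_classification_tree, fit_regression_tree

MAX_DEFAULT_M = 100_000


def default_m(n_train: int) -> int:
    """Synthetic sample budget: 10x the training size, capped at 100,000."""
    return min(10 * n_train, MAX_DEFAULT_M)


@dataclass(frozen=True)
class ExtractionConfig:
    m: int = 20_000
    label_mode: str = "continuous"            # "continuous" | "binary"
    binary_threshold: float = 0.5
    tree_params: TreeParams = field(default_factory=TreeParams)
    seed: int = 0
    clip_ranges: Mapping[str, tuple[float, float]] | None = None

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 < self.binary_threshold < 1.0:
            raise ValueError("binary_threshold must lie in (0, 1)")
        if self.label_mode not in ("continuous", "binary"):
            raise ValueError(f"unknown label_mode {self.label_mode!r}")


@dataclass(frozen=True)
class FidelityReport:
    """How faithfully the surrogate mimics the scorer on fresh samples."""

    r_squared: float
    auc_agreement: float            # NaN when the scorer's binarized labels are single-class
    abs_diff_quantiles: dict[str, float]
    m_eval: int
    zero_variance: bool = False


@dataclass(frozen=True)
class ExtractionResult:
    tree: Tree
    fidelity: FidelityReport
    config: ExtractionConfig


def _check_alignment(scorer: RiskScorer, gmm: mixture.DiagonalGMM) -> None:
    if scorer.feature_names and gmm.feature_names and (
        tuple(scorer.feature_names) != tuple(gmm.feature_names)
    ):
        raise ValueError(
            "scorer and GMM disagree on feature names/order: "
            f"{scorer.feature_names} vs {gmm.feature_names}"
        )


def _draw_and_score(scorer, gmm, m, seed, clip_ranges):
    X = mixture.sample(gmm, m, seed=seed)
    if clip_ranges:
        names = gmm.feature_names or tuple(f"x{j}" for j in range(gmm.d))
        for name, (lo, hi) in clip_ranges.items():
            if name in names:
                j = names.index(name)
                X[:, j] = np.clip(X[:, j], lo, hi)
    scores = np.asarray(scorer.score(X), dtype=float)
    if scores.size and (scores.min() < 0.0 or scores.max() > 1.0):
        raise ValueError("scorer returned values outside [0, 1]")
    return X, scores


def extract_regression_tree(
    scorer: RiskScorer, gmm: mixture.DiagonalGMM, config: ExtractionConfig = ExtractionConfig()
) -> ExtractionResult:
    """Proposed variant: regression tree fitted on (x~, f(x~)) with the
    continuous score kept as the target."""
    config.validate()
    _check_alignment(scorer, gmm)
    X, scores = _draw_and_score(scorer, gmm, config.m, config.seed, config.clip_ranges)
    tree = fit_regression_tree(X, scores, config.tree_params, gmm.feature_names)
    report = fidelity_report(tree, scorer, gmm, m_eval=max(config.m // 2, 2),
                             seed=config.seed + 1, clip_ranges=config.clip_ranges,
                             threshold=config.binary_threshold)
    return ExtractionResult(tree=tree, fidelity=report, config=config)


def extract_decision_tree(
    scorer: RiskScorer, gmm: mixture.DiagonalGMM, config: ExtractionConfig = ExtractionConfig()
) -> ExtractionResult:
    """Baseline variant: scores binarized before fitting — strictly below the
    threshold maps to 0, at or above maps to 1 — then a Gini classification
    tree on the binary labels."""
    config.validate()
    _check_alignment(scorer, gmm)
    X, scores = _draw_and_score(scorer, gmm, config.m, config.seed, config.clip_ranges)
    labels = (scores >= config.binary_threshold).astype(float)
    tree = fit_classification_tree(X, labels, config.tree_params, gmm.feature_names)
    report = fidelity_report(tree, scorer, gmm, m_eval=max(config.m // 2, 2),
                             seed=config.seed + 1, clip_ranges=config.clip_ranges,
                             threshold=config.binary_threshold)
    return ExtractionResult(tree=tree, fidelity=report, config=config)


def fidelity_report(
    tree: Tree,
    scorer: RiskScorer,
    gmm: mixture.DiagonalGMM,
    m_eval: int = 10_000,
    seed: int = 1,
    clip_ranges=None,
    threshold: float = 0.5,
) -> FidelityReport:
    """Evaluate tree-vs-scorer agreement on a fresh synthetic batch:
    squared Pearson correlation of the two prediction vectors, AUC of the
    tree's scores against the scorer's binarized labels, and quantiles of
    the absolute prediction gap.  A zero-variance pair (e.g. constant scorer
    matched by a single leaf) reports R^2 = 1 with a flag."""
    from .evaluation import auc_roc

    if m_eval < 2:
        raise ValueError("m_eval must be >= 2")
    _check_alignment(scorer, gmm)
    X, scores = _draw_and_score(scorer, gmm, m_eval, seed, clip_ranges)
    preds = tree.predict(X)

    zero_var = float(np.var(scores)) == 0.0 or float(np.var(preds)) == 0.0
    if zero_var:
        r2 = 1.0 if np.allclose(preds, scores) else 0.0
    else:
        r2 = float(np.corrcoef(preds, scores)[0, 1] ** 2)

    labels = (scores >= threshold).astype(float)
    if 0 < labels.sum() < labels.size:
        auc = float(auc_roc(labels, preds))
    else:
        auc = float("nan")

    gaps = np.abs(preds - scores)
    quantiles = {f"q{int(q * 100):02d}": float(np.quantile(gaps, q))
                 for q in (0.5, 0.9, 0.99, 1.0)}
    return FidelityReport(
        r_squared=r2,
        auc_agreement=auc,
        abs_diff_quantiles=quantiles,
        m_eval=m_eval,
        zero_variance=zero_var,
    )
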