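"""Classification metrics and replication-based model comparison.

Readmission cohorts are heavily imbalanced (roughly one positive in seven for
30-day outcomes), so the module reports the metrics that remain informative
under imbalance — AUC of the ROC curve, area under the precision–recall curve
(average precision), and Matthews correlation — alongside accuracy, precision,
recall and F1.

Model comparison follows a bootstrap-style protocol: R independent stratified
70–30 train/test splits, a full metric set per replication, and a
deliberately conservative standard error obtained by inflating the sample SD
of the replicated scores with the one-sided upper confidence limit of a
normal population SD (a chi-square quantile ratio; 1.2017 for R = 50 at the
95% level).  A candidate model is flagged significantly better than the
baseline when its mean exceeds the baseline mean by more than two (95%) or
three (99%) of these adjusted SEs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2, rankdata

from .blackbox import RiskScorer, rebalance

METRIC_NAMES = ("acc", "auc", "auprc", "precision", "recall", "f_value", "mcc")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a thresholded binary classification."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    acc: float
    auc: float
    auprc: float
    precision: float
    recall: float
    f_value: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def _validate_pair(y, scores):
    y = np.asarray(y, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape or y.ndim != 1:
        raise ValueError(
            f"labels and scores must be 1-d and equal length, got {y.shape} vs {scores.shape}"
        )
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    return y, scores


def confusion(y, scores, threshold: float = 0.5) -> ConfusionMatrix:
    """Tally the confusion matrix; predicted positive iff score >= threshold."""
    y, scores = _validate_pair(y, scores)
    pred = scores >= threshold
    pos = y == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


def auc_roc(y, scores) -> float:
    """ROC AUC via the midrank (Mann–Whitney) estimator; ties get average rank.

    Equals the probability that a random positive outscores a random negative,
    counting score ties as one half.  Raises on single-class labels, where the
    quantity is undefined.
    """
    y, scores = _validate_pair(y, scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined when only one class is present")
    ranks = rankdata(scores)  # average-rank ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auprc(y, scores) -> float:
    """Average precision: mean of precision at each positive, in descending-score
    order, with tied scores processed as one block (block-end precision).

    The no-skill baseline of this estimator equals the positive prevalence.
    """
    y, scores = _validate_pair(y, scores)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("average precision is undefined with no positives")
    order = np.argsort(-scores, kind="mergesort")
    y_sorted = y[order]
    s_sorted = scores[order]
    cum_tp = np.cumsum(y_sorted)
    k = np.arange(1, y.size + 1)
    # last index of each tie block
    block_end = np.ones(y.size, dtype=bool)
    block_end[:-1] = s_sorted[:-1] != s_sorted[1:]
    ends = np.flatnonzero(block_end)
    tp_at_end = cum_tp[ends]
    prec_at_end = tp_at_end / k[ends]
    tp_in_block = np.diff(np.concatenate(([0.0], tp_at_end)))
    return float(np.sum(tp_in_block * prec_at_end) / n_pos)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 by convention when any margin is empty."""
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom2))


def metric_set(y, scores, threshold: float = 0.5) -> MetricSet:
    """Full metric panel at a score threshold (default 0.5)."""
    cm = confusion(y, scores, threshold)
    n = cm.n
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else 0.0
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    f_value = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MetricSet(
        acc=(cm.tp + cm.tn) / n,
        auc=auc_roc(y, scores),
        auprc=auprc(y, scores),
        precision=precision,
        recall=recall,
        f_value=f_value,
        mcc=mcc(cm),
    )


def sd_adjustment_factor(R: int, alpha: float = 0.05) -> float:
    """One-sided upper (1-alpha) confidence-limit multiplier for a normal
    population SD estimated from R replications: sqrt((R-1)/chi2_{alpha,R-1}).

    1.2017 for R = 50, alpha = 0.05; decreases to 1 as R grows.
    """
    if R < 2:
        raise ValueError("need at least 2 replications")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(np.sqrt((R - 1) / chi2.ppf(alpha, R - 1)))


@dataclass(frozen=True)
class ReplicationSummary:
    """Per-metric mean, sample SD and chi-square-adjusted SE over R splits."""

    means: Mapping[str, float]
    sds: Mapping[str, float]
    adjusted_se: Mapping[str, float]
    R: int
    split: float
    seeds: tuple[int, ...]
    per_replication: tuple[MetricSet, ...] = ()
    warnings: tuple[str, ...] = ()


ModelBuilder = Callable[[np.ndarray, np.ndarray, int], RiskScorer]


def _stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    """Indices of a stratified train/test split preserving class proportions
    within one row per class."""
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def replicate(
    X,
    y,
    model_builder: ModelBuilder,
    R: int = 50,
    split: float = 0.70,
    rebalance_mode: str | None = "up",
    base_seed: int = 0,
    threshold: float = 0.5,
    alpha: float = 0.05,
) -> ReplicationSummary:
    """Run R stratified train/test replications of a model-building recipe.

    Per replication r: split the rows 70–30 (stratified by label, seeded by
    ``base_seed + r``), rebalance the training portion only, build the model,
    and score the untouched test portion.  The summary holds per-metric means,
    sample SDs (denominator R-1) and adjusted SEs
    ``sd_adjustment_factor(R, alpha) * SD``.

    A builder failure aborts that replication; the summary then covers the
    completed ones and carries a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if R < 2:
        raise ValueError("R must be >= 2")
    if not 0.0 < split < 1.0:
        raise ValueError("split must lie in (0, 1)")
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")

    seeds = tuple(base_seed + r for r in range(R))
    results: list[MetricSet] = []
    warnings: list[str] = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        tr, te = _stratified_split(y, split, rng)
        X_tr, y_tr = X[tr], y[tr]
        if rebalance_mode is not None:
            X_tr, y_tr = rebalance(X_tr, y_tr, mode=rebalance_mode, seed=seed)
        try:
            scorer = model_builder(X_tr, y_tr, seed)
            scores = scorer.score(X[te])
            results.append(metric_set(y[te], scores, threshold))
        except Exception as exc:  # noqa: BLE001 - replication-level isolation
            warnings.append(f"replication seed={seed} failed: {exc!r}")
    if len(results) < 2:
        raise RuntimeError(f"fewer than 2 replications completed: {warnings}")
    if len(results) < R:
        warnings.append(f"summary covers {len(results)}/{R} replications")

    factor = sd_adjustment_factor(R, alpha)
    table = {m: np.array([getattr(res, m) for res in results]) for m in METRIC_NAMES}
    means = {m: float(v.mean()) for m, v in table.items()}
    sds = {m: float(v.std(ddof=1)) for m, v in table.items()}
    return ReplicationSummary(
        means=means,
        sds=sds,
        adjusted_se={m: factor * sds[m] for m in METRIC_NAMES},
        R=R,
        split=split,
        seeds=seeds,
        per_replication=tuple(results),
        warnings=tuple(warnings),
    )


def significance_flags(
    candidate: ReplicationSummary,
    baseline: ReplicationSummary,
    paired: bool = False,
) -> dict[str, str]:
    """One-sided improvement flags per metric: '*' when the candidate mean
    exceeds the baseline mean by strictly more than 2 baseline adjusted SEs,
    '**' beyond 3, 'ns' otherwise (including any deficit).

    ``paired=True`` instead tests the per-replication differences (both
    summaries must carry per-replication results from the same seeds): the
    yardstick becomes the adjusted SE of the difference series, which is
    more powerful when the two models share split-to-split luck.  Off by
    default; the headline comparison uses the baseline-SE rule.
    """
    if candidate.R != baseline.R:
        raise ValueError("summaries must use the same number of replications")
    flags = {}
    if paired:
        if (
            len(candidate.per_replication) != len(baseline.per_replication)
            or candidate.seeds != baseline.seeds
        ):
            raise ValueError("paired comparison needs per-replication results on shared seeds")
        factor = sd_adjustment_factor(baseline.R, 0.05)
        for m in METRIC_NAMES:
            diffs = np.array(
                [getattr(c, m) - getattr(b, m)
                 for c, b in zip(candidate.per_replication, baseline.per_replication)]
            )
            se = factor * diffs.std(ddof=1)
            flags[m] = "**" if diffs.mean() > 3 * se else "*" if diffs.mean() > 2 * se else "ns"
        return flags
    for m in METRIC_NAMES:
        diff = candidate.means[m] - baseline.means[m]
        se = baseline.adjusted_se[m]
        if diff > 3 * se:
            flags[m] = "**"
        elif diff > 2 * se:
            flags[m] = "*"
        else:
            flags[m] = "ns"
    return flags
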