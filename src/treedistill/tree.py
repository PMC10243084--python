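"""Axis-aligned binary regression and classification trees.

The interpretable model class of the pipeline: greedy CART-style induction
with variance-reduction splits (regression, mean-valued leaves) or Gini
splits (classification, positive-fraction leaves — so every leaf scores in
[0, 1] either way).  Candidate thresholds are midpoints between consecutive
distinct sorted feature values, which on 0/1 columns yields exactly the 0.5
cutoff convention.  Ties among equal-cost splits resolve to the lowest
feature index, then the smallest threshold, so a fit is fully deterministic.

Kept intentionally free of scikit-learn so that split search, tie-breaking
and rendering semantics are pinned down by this file alone; sklearn trees
serve as an independent cross-check in the test-suite, not as the engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence, Union

import numpy as np


def _read_text_maybe_path(source) -> str:
    """Accept a filesystem path or the serialized text itself."""
    s = str(source)
    if "\n" in s or s.lstrip().startswith("{"):
        return s
    return Path(s).read_text()


@dataclass
class Leaf:
    value: float          # mean target (regression) / positive fraction (classification)
    n_train: int


@dataclass
class Split:
    feature: int
    threshold: float
    left: "Node"
    right: "Node"
    gain: float           # parent cost minus summed child cost
    n_train: int
    value: float          # mean target at this node (used for rendering)


Node = Union[Leaf, Split]


@dataclass(frozen=True)
class TreeParams:
    """Induction hyperparameters.

    max_depth 4 keeps the tree readable at a glance; min_leaf 50 is sized for
    the tens of thousands of synthetic rows a distillation run fits on;
    min_gain is a numerical guard against splitting on noise-level cost
    differences.
    """

    max_depth: int = 4
    min_leaf: int = 50
    min_gain: float = 1e-7


@dataclass
class Tree:
    root: Node
    kind: str                                 # "regression" | "classification"
    feature_names: tuple[str, ...] = ()
    params: TreeParams = field(default_factory=TreeParams)

    # -- prediction ------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Route rows by 'feature <= threshold goes left'; returns leaf values."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if self.feature_names and X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        max_used = max(
            (n.feature for n in self.walk() if isinstance(n, Split)), default=-1
        )
        if X.shape[1] <= max_used:
            raise ValueError(f"expected at least {max_used + 1} features, got {X.shape[1]}")
        out = np.empty(X.shape[0], dtype=float)
        self._route(self.root, X, np.arange(X.shape[0]), out)
        return float(out[0]) if single else out

    def _route(self, node: Node, X, idx, out) -> None:
        if isinstance(node, Leaf):
            out[idx] = node.value
            return
        go_left = X[idx, node.feature] <= node.threshold
        self._route(node.left, X, idx[go_left], out)
        self._route(node.right, X, idx[~go_left], out)

    # -- inspection ------------------------------------------------------
    def walk(self) -> Iterator[Node]:
        """Pre-order traversal."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if isinstance(node, Split):
                stack.extend([node.right, node.left])

    def n_nodes(self) -> int:
        return sum(1 for _ in self.walk())

    def depth(self) -> int:
        def _d(node: Node) -> int:
            if isinstance(node, Leaf):
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def split_features(self) -> list[tuple[str, int, float]]:
        """(feature name, times used, total gain), ordered by total gain
        descending, ties by first pre-order appearance."""
        order: list[int] = []
        counts: dict[int, int] = {}
        gains: dict[int, float] = {}
        for node in self.walk():
            if isinstance(node, Split):
                if node.feature not in counts:
                    order.append(node.feature)
                    counts[node.feature] = 0
                    gains[node.feature] = 0.0
                counts[node.feature] += 1
                gains[node.feature] += node.gain
        ranked = sorted(order, key=lambda f: (-gains[f], order.index(f)))
        return [(self._name(f), counts[f], gains[f]) for f in ranked]

    def _name(self, feature: int) -> str:
        return self.feature_names[feature] if self.feature_names else f"x{feature}"

    # -- rendering -------------------------------------------------------
    def render(self, format: str = "text") -> str:
        if format == "text":
            lines: list[str] = []
            self._render_text(self.root, 0, lines)
            return "\n".join(lines)
        if format == "dot":
            return self._render_dot()
        raise ValueError(f"unknown render format {format!r}")

    def _render_text(self, node: Node, depth: int, lines: list[str]) -> None:
        pad = "  " * depth
        if isinstance(node, Leaf):
            lines.append(f"{pad}-> {node.value:.4f}  (n={node.n_train})")
            return
        lines.append(f"{pad}{self._name(node.feature)} <= {node.threshold:g}")
        self._render_text(node.left, depth + 1, lines)
        lines.append(f"{pad}{self._name(node.feature)} > {node.threshold:g}")
        self._render_text(node.right, depth + 1, lines)

    def _render_dot(self) -> str:
        lines = ["digraph tree {", '  node [shape=box, style="filled"];']
        counter = [0]

        def fill(value: float) -> str:
            # HSV red whose saturation tracks the node's mean risk
            return f'"0.000 {min(max(value, 0.0), 1.0):.3f} 1.000"'

        def emit(node: Node) -> int:
            nid = counter[0]
            counter[0] += 1
            if isinstance(node, Leaf):
                lines.append(
                    f'  n{nid} [label="{node.value:.3f}\\nn={node.n_train}", fillcolor={fill(node.value)}];'
                )
                return nid
            lines.append(
                f'  n{nid} [label="{self._name(node.feature)} <= {node.threshold:g}", '
                f"fillcolor={fill(node.value)}];"
            )
            lid = emit(node.left)
            rid = emit(node.right)
            lines.append(f'  n{nid} -> n{lid} [label="yes"];')
            lines.append(f'  n{nid} -> n{rid} [label="no"];')
            return nid

        emit(self.root)
        lines.append("}")
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        def encode(node: Node) -> dict:
            if isinstance(node, Leaf):
                return {"value": node.value, "n_train": node.n_train}
            return {
                "feature": node.feature,
                "threshold": node.threshold,
                "gain": node.gain,
                "n_train": node.n_train,
                "value": node.value,
                "left": encode(node.left),
                "right": encode(node.right),
            }

        payload = {
            "kind": self.kind,
            "feature_names": list(self.feature_names),
            "params": {"max_depth": self.params.max_depth, "min_leaf": self.params.min_leaf,
                       "min_gain": self.params.min_gain},
            "conventions": {"routing": "feature <= threshold goes left"},
            "root": encode(self.root),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Tree":
        text = _read_text_maybe_path(source)
        payload = json.loads(text)

        def decode(obj: dict) -> Node:
            if "feature" in obj:
                return Split(
                    feature=obj["feature"],
                    threshold=obj["threshold"],
                    left=decode(obj["left"]),
                    right=decode(obj["right"]),
                    gain=obj["gain"],
                    n_train=obj["n_train"],
                    value=obj["value"],
                )
            return Leaf(value=obj["value"], n_train=obj["n_train"])

        return cls(
            root=decode(payload["root"]),
            kind=payload["kind"],
            feature_names=tuple(payload["feature_names"]),
            params=TreeParams(**payload["params"]),
        )


# ---------------------------------------------------------------------------
# induction


def _node_cost(y: np.ndarray, kind: str) -> float:
    """Regression: sum of squared deviations from the mean.  Classification:
    n * Gini impurity (for binary y this is 2x the squared-deviation sum, so
    both criteria rank splits identically on 0/1 targets; Gini is kept
    explicit for clarity)."""
    n = y.size
    s = y.sum()
    sse = float((y**2).sum() - s * s / n)
    return sse if kind == "regression" else 2.0 * (float(s) - s * s / n)


def _best_split(X: np.ndarray, y: np.ndarray, kind: str, min_leaf: int):
    """Exhaustive scan over features x midpoint thresholds; returns
    (cost, feature, threshold) of the strictly best admissible split or None.

    Candidates tied in cost (within an arithmetic-noise tolerance, far below
    any real cost difference) resolve to the lowest feature index, then the
    smallest threshold, so fits are deterministic regardless of summation
    order.
    """
    n, d = X.shape
    if n < 2 * min_leaf:
        return None
    tol = 1e-9 * (float((y**2).sum()) + 1.0)
    best = None
    for j in range(d):
        order = np.argsort(X[:, j], kind="mergesort")
        xs = X[order, j]
        ys = y[order]
        # admissible split after position i: distinct neighbours + leaf sizes
        boundary = xs[:-1] < xs[1:]
        n_left = np.arange(1, n)
        ok = boundary & (n_left >= min_leaf) & (n - n_left >= min_leaf)
        if not ok.any():
            continue
        cum = np.cumsum(ys)[:-1]
        cum2 = np.cumsum(ys**2)[:-1]
        tot, tot2 = ys.sum(), (ys**2).sum()
        n_right = n - n_left
        if kind == "regression":
            cost = (cum2 - cum**2 / n_left) + ((tot2 - cum2) - (tot - cum) ** 2 / n_right)
        else:
            cost = 2.0 * (cum - cum**2 / n_left) + 2.0 * ((tot - cum) - (tot - cum) ** 2 / n_right)
        cost = np.where(ok, cost, np.inf)
        lowest = float(cost.min())
        i = int(np.argmax(cost <= lowest + tol))  # first near-minimum -> smallest threshold
        if best is None or cost[i] < best[0] - tol:
            best = (float(cost[i]), j, float((xs[i] + xs[i + 1]) / 2.0))
    return best


def _grow(X: np.ndarray, y: np.ndarray, kind: str, params: TreeParams, depth: int) -> Node:
    n = y.size
    mean = float(y.mean())
    if depth >= params.max_depth or n < 2 * params.min_leaf or np.ptp(y) == 0.0:
        return Leaf(value=mean, n_train=n)
    found = _best_split(X, y, kind, params.min_leaf)
    if found is None:
        return Leaf(value=mean, n_train=n)
    cost, j, thr = found
    gain = _node_cost(y, kind) - cost
    if gain <= params.min_gain:
        return Leaf(value=mean, n_train=n)
    go_left = X[:, j] <= thr
    return Split(
        feature=j,
        threshold=thr,
        left=_grow(X[go_left], y[go_left], kind, params, depth + 1),
        right=_grow(X[~go_left], y[~go_left], kind, params, depth + 1),
        gain=gain,
        n_train=n,
        value=mean,
    )


def _validate_xy(X, y, kind: str):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (n, d) and y length n")
    if y.size == 0:
        raise ValueError("empty target")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if kind == "classification" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("classification targets must be binary 0/1")
    return X, y


def fit_regression_tree(
    X, y, params: TreeParams = TreeParams(), feature_names: Sequence[str] = ()
) -> Tree:
    """Greedy variance-reduction tree on continuous targets in [0, 1];
    each leaf predicts the mean of its training targets."""
    X, y = _validate_xy(X, y, "regression")
    if y.size < 2 * params.min_leaf and y.size < 2:
        raise ValueError("need at least 2 rows")
    return Tree(_grow(X, y, "regression", params, 0), "regression",
                tuple(feature_names), params)


def fit_classification_tree(
    X, y, params: TreeParams = TreeParams(), feature_names: Sequence[str] = ()
) -> Tree:
    """Greedy Gini-impurity tree on binary targets; each leaf predicts its
    positive fraction (so it still scores in [0, 1])."""
    X, y = _validate_xy(X, y, "classification")
    return Tree(_grow(X, y, "classification", params, 0), "classification",
                tuple(feature_names), params)
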