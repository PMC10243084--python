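"""Cross-model feature comparison for extracted trees.

A tree's clinical usefulness lies in which features it splits on.  Comparing
the split features of several extracted trees (30- vs 90-day, all- vs
main-specialty, regression vs decision variant) surfaces the consensus risk
factors: features used by every model are the reliably influential ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .tree import Tree


@dataclass
class FeatureOverlapTable:
    """0/1 influence indicators (rows: features, columns: model labels) with
    the per-model total split gain as annotation."""

    indicators: pd.DataFrame
    gains: pd.DataFrame

    def consensus_features(self) -> list[str]:
        """Features used by every compared model."""
        return [f for f, row in self.indicators.iterrows() if row.all()]

    def to_csv(self, path: str | Path) -> None:
        merged = self.indicators.copy()
        merged.index.name = "feature"
        merged.to_csv(path)

    def to_markdown(self) -> str:
        pretty = self.indicators.replace({1: "x", 0: ""})
        pretty.index.name = "feature"
        return pretty.to_markdown()


def feature_overlap(
    trees: Sequence[tuple[str, Tree]], min_gain: float = 0.0
) -> FeatureOverlapTable:
    """Tabulate which features each tree splits on.

    A feature is influential for a model when it appears as any split with
    total gain above ``min_gain``.  Rows are ordered by the number of models
    using the feature (descending), then alphabetically.
    """
    if not trees:
        raise ValueError("need at least one tree")
    per_model: dict[str, dict[str, float]] = {}
    for label, tree in trees:
        if tree.root is None:
            raise ValueError(f"tree {label!r} is not fitted")
        per_model[label] = {
            name: gain for name, _, gain in tree.split_features() if gain > min_gain
        }

    features = sorted({f for gains in per_model.values() for f in gains})
    labels = [label for label, _ in trees]
    indicators = pd.DataFrame(
        [[int(f in per_model[m]) for m in labels] for f in features],
        index=features, columns=labels, dtype=int,
    )
    gains = pd.DataFrame(
        [[per_model[m].get(f, 0.0) for m in labels] for f in features],
        index=features, columns=labels, dtype=float,
    )
    order = indicators.sum(axis=1).sort_values(ascending=False, kind="mergesort")
    ordered = sorted(features, key=lambda f: (-order[f], f))
    return FeatureOverlapTable(indicators.loc[ordered], gains.loc[ordered])
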