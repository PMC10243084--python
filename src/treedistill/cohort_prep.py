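"""From raw admission tables to labeled design matrices.

Notation: patient i's k-th visit has admission date t0_{i,k} and discharge
date t_{i,k}.  The 30-day readmission label of visit k is the indicator
1{t0_{i,k+1} - t_{i,k} <= 30} (90-day analogously); a patient's last
recorded visit is labeled 0.  The prior-visit feature counts strictly
earlier visits whose discharge lies within the last 180 days of the current
admission, boundary inclusive.  All date comparisons are whole-day
differences with inclusive <=.

Features enter the design matrix unscaled; categoricals are one-hot encoded
with the full level set retained (trees are indifferent to collinearity);
rows missing a roster feature are dropped and counted, never imputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("treedistill")

EXCLUDED_SPECIALTIES = ("pediatrics", "obstetrics_gynecology")
MAIN_SPECIALTIES = ("medicine", "surgery", "orthopedics", "cardiology")


def _as_days(values) -> np.ndarray:
    """Dates (ISO strings / datetimes) -> integer day numbers.  Integer input
    is taken to be day numbers already."""
    arr = np.asarray(values)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.int64)
    return pd.to_datetime(arr).to_numpy(dtype="datetime64[D]").astype(np.int64)


def _check_single_sorted(admits: np.ndarray, discharges: np.ndarray) -> None:
    if np.any(np.diff(admits) < 0):
        raise ValueError("visits must be sorted ascending by admission date")
    if np.any(discharges < admits):
        raise ValueError("discharge before admission")
    if np.any(admits[1:] < discharges[:-1]):
        raise ValueError("overlapping stays within one patient")


def count_prior_visits(
    admit_dates, discharge_dates, window_days: int = 180, include_self: bool = False
) -> np.ndarray:
    """Per-visit count of earlier visits discharged within the window.

    Entry k counts visits j < k with 0 <= t0_k - t_j <= window_days (both
    bounds inclusive).  ``include_self`` adds the always-true j = k term of
    the literal running-sum formulation; the default counts strict priors,
    i.e. the number of previous hospitalizations.
    """
    admits = _as_days(admit_dates)
    discharges = _as_days(discharge_dates)
    _check_single_sorted(admits, discharges)
    # discharges are non-decreasing, so eligible priors form a contiguous
    # run locatable by binary search: t_j in [t0_k - window, t0_k]
    lo = np.searchsorted(discharges, admits - window_days, side="left")
    hi = np.searchsorted(discharges, admits, side="right")
    k = np.arange(admits.size)
    counts = np.minimum(hi, k) - np.minimum(lo, k)
    if include_self:
        counts = counts + 1
    return counts.astype(np.int64)


def build_labels(admit_dates, discharge_dates, window_days: int) -> np.ndarray:
    """Binary readmission indicators: entry k is 1 iff visit k+1 exists and
    t0_{k+1} - t_k <= window_days; the last visit gets 0."""
    admits = _as_days(admit_dates)
    discharges = _as_days(discharge_dates)
    _check_single_sorted(admits, discharges)
    labels = np.zeros(admits.size, dtype=np.int64)
    if admits.size > 1:
        gaps = admits[1:] - discharges[:-1]
        if np.any(gaps < 0):
            raise ValueError("negative readmission gap (overlapping stays)")
        labels[:-1] = gaps <= window_days
    return labels


def filter_specialties(table: pd.DataFrame, mode: str) -> pd.DataFrame:
    """'all': drop pediatrics and obstetrics/gynecology rows.
    'main': keep only medicine, surgery, orthopedics, cardiology."""
    if "specialty" not in table.columns:
        raise ValueError("table has no specialty column")
    if mode == "all":
        keep = ~table["specialty"].isin(EXCLUDED_SPECIALTIES)
    elif mode == "main":
        keep = table["specialty"].isin(MAIN_SPECIALTIES)
    else:
        raise ValueError(f"unknown specialty mode {mode!r}")
    kept = table[keep]
    logger.info(
        "filter_specialties mode=%s kept=%d dropped=%d", mode, len(kept), len(table) - len(kept)
    )
    return kept.reset_index(drop=True)


def add_history_columns(
    table: pd.DataFrame,
    prior_window_days: int = 180,
    label_windows: Sequence[int] = (30, 90),
    include_self: bool = False,
) -> pd.DataFrame:
    """Append per-patient history features and outcome labels to an admission
    table: ``n_prior_visits``, one ``y<w>`` column per window, and a
    ``censored`` flag for visits admitted within max(window) days of the
    table's last admission date (their labels may be truncated zeros)."""
    out = table.sort_values(["patient_id", "admit_date"], kind="mergesort").reset_index(drop=True)
    prior = np.empty(len(out), dtype=np.int64)
    labels = {w: np.empty(len(out), dtype=np.int64) for w in label_windows}
    for _, idx in out.groupby("patient_id", sort=False).indices.items():
        admits = out["admit_date"].to_numpy()[idx]
        discharges = out["discharge_date"].to_numpy()[idx]
        prior[idx] = count_prior_visits(admits, discharges, prior_window_days, include_self)
        for w in label_windows:
            labels[w][idx] = build_labels(admits, discharges, w)
    out["n_prior_visits"] = prior
    for w in label_windows:
        out[f"y{w}"] = labels[w]
    admit_days = _as_days(out["admit_date"])
    out["censored"] = admit_days > admit_days.max() - max(label_windows)
    return out


@dataclass
class LabeledDataset:
    """Design matrix plus outcomes, ready for model fitting."""

    X: np.ndarray
    y30: np.ndarray
    y90: np.ndarray
    feature_names: tuple[str, ...]
    row_keys: tuple[tuple[str, str], ...]
    level_orders: dict[str, tuple[str, ...]] = field(default_factory=dict)
    n_dropped_missing: int = 0

    def __post_init__(self) -> None:
        if np.any(self.y30 > self.y90):
            raise ValueError("y30 must be <= y90 element-wise")
        if np.isnan(self.X).any():
            raise ValueError("design matrix contains missing values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def y(self, window: int) -> np.ndarray:
        if window == 30:
            return self.y30
        if window == 90:
            return self.y90
        raise ValueError("window must be 30 or 90")

    def save(self, stem: str | Path) -> None:
        """CSV matrix + JSON sidecar (feature names, level orders, row keys)."""
        stem = Path(stem)
        frame = pd.DataFrame(self.X, columns=list(self.feature_names))
        frame["y30"] = self.y30
        frame["y90"] = self.y90
        frame.to_csv(stem.with_suffix(".csv"), index=False)
        sidecar = {
            "feature_names": list(self.feature_names),
            "level_orders": {k: list(v) for k, v in self.level_orders.items()},
            "row_keys": [list(rk) for rk in self.row_keys],
            "n_dropped_missing": self.n_dropped_missing,
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, stem: str | Path) -> "LabeledDataset":
        stem = Path(stem)
        frame = pd.read_csv(stem.with_suffix(".csv"))
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        names = sidecar["feature_names"]
        return cls(
            X=frame[names].to_numpy(dtype=float),
            y30=frame["y30"].to_numpy(dtype=np.int64),
            y90=frame["y90"].to_numpy(dtype=np.int64),
            feature_names=tuple(names),
            row_keys=tuple(tuple(rk) for rk in sidecar["row_keys"]),
            level_orders={k: tuple(v) for k, v in sidecar["level_orders"].items()},
            n_dropped_missing=sidecar["n_dropped_missing"],
        )


def assemble_design_matrix(
    table: pd.DataFrame,
    feature_roster: Sequence[str],
    label_windows: Sequence[int] = (30, 90),
    drop_censored: bool = False,
) -> LabeledDataset:
    """Encode an admission table (with history columns already attached or
    attachable) into a :class:`LabeledDataset`.

    Continuous and 0/1 columns pass through bit-identically (no scaling or
    centering); object-dtype columns are one-hot encoded over their sorted
    observed levels, all levels kept.  Rows with a missing roster value are
    dropped and counted.
    """
    needs_history = "y30" not in table.columns or (
        "n_prior_visits" in feature_roster and "n_prior_visits" not in table.columns
    )
    if needs_history:
        table = add_history_columns(table, label_windows=tuple(set(label_windows) | {30, 90}))
    missing_cols = [c for c in feature_roster if c not in table.columns]
    if missing_cols:
        raise ValueError(f"roster columns absent from table: {missing_cols}")

    work = table.reset_index(drop=True)
    if drop_censored and "censored" in work.columns:
        work = work[~work["censored"]].reset_index(drop=True)
    complete = work[list(feature_roster)].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("assemble_design_matrix dropped %d rows with missing features", n_dropped)
    work = work[complete].reset_index(drop=True)

    blocks: list[np.ndarray] = []
    names: list[str] = []
    level_orders: dict[str, tuple[str, ...]] = {}
    for col in feature_roster:
        series = work[col]
        if series.dtype == object:
            levels = tuple(sorted(series.unique()))
            level_orders[col] = levels
            for level in levels:
                blocks.append((series == level).to_numpy(dtype=float)[:, None])
                names.append(f"{col}={level}")
        else:
            values = series.to_numpy(dtype=float)
            if not np.isfinite(values).all():
                raise ValueError(f"non-numeric value in continuous column {col!r}")
            blocks.append(values[:, None])
            names.append(col)

    return LabeledDataset(
        X=np.hstack(blocks) if blocks else np.empty((len(work), 0)),
        y30=work["y30"].to_numpy(dtype=np.int64),
        y90=work["y90"].to_numpy(dtype=np.int64),
        feature_names=tuple(names),
        row_keys=tuple(zip(work["patient_id"].astype(str), work["visit_id"].astype(str))),
        level_orders=level_orders,
        n_dropped_missing=n_dropped,
    )


DEFAULT_ROSTER = (
    "age", "charlson_score", "van_walraven_score", "length_of_stay",
    "second_diag_count", "n_prior_visits", "admit_ed", "nursing_home_discharge",
    "insurance_public", "surgery", "icu_flag", "transfer_count",
    "admit_month", "admit_dow", "specialty",
)


def prepare_dataset(
    table: pd.DataFrame,
    mode: str = "all",
    feature_roster: Sequence[str] = DEFAULT_ROSTER,
    drop_censored: bool = False,
) -> LabeledDataset:
    """Full preparation path: history features and labels are computed on the
    complete visit history first (so specialty filtering cannot sever
    label-defining visit pairs), then rows are filtered by specialty mode and
    encoded."""
    enriched = add_history_columns(table)
    filtered = filter_specialties(enriched, mode)
    return assemble_design_matrix(filtered, feature_roster, drop_censored=drop_censored)
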