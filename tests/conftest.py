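import dataclasses

import numpy as np
import pandas as pd
import pytest

import treedistill as td


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 400-patient default-mechanism cohort, shared across read-only tests."""
    config = td.SyntheticCohortConfig(n_patients=400, seed=11)
    return td.generate_cohort(config, td.default_mechanism())


@pytest.fixture(scope="session")
def small_dataset(small_cohort) -> td.LabeledDataset:
    return td.prepare_dataset(small_cohort, mode="all")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_visit_table(visits: dict[str, list[tuple[int, int]]]) -> pd.DataFrame:
    """Admission table from {patient_id: [(admit_day, discharge_day), ...]},
    with day numbers mapped onto real dates and filler features."""
    base = np.datetime64("2009-01-01")
    rows = []
    for pid, stays in visits.items():
        for k, (a, d) in enumerate(stays):
            rows.append(
                {
                    "patient_id": pid,
                    "visit_id": f"{pid}v{k}",
                    "admit_date": str(base + a),
                    "discharge_date": str(base + d),
                    "specialty": "medicine",
                    "age": 60.0,
                }
            )
    return pd.DataFrame(rows)


def brute_force_prior_visits(admits, discharges, window=180):
    """O(K^2) double loop straight from the definition."""
    out = []
    for k in range(len(admits)):
        count = 0
        for j in range(k):
            gap = admits[k] - discharges[j]
            if 0 <= gap <= window:
                count += 1
        out.append(count)
    return out


def brute_force_labels(admits, discharges, window):
    out = []
    for k in range(len(admits)):
        if k + 1 < len(admits) and admits[k + 1] - discharges[k] <= window:
            out.append(1)
        else:
            out.append(0)
    return out


def random_history(rng: np.random.Generator, max_visits: int = 8):
    """Random non-overlapping visit history in integer days."""
    n = int(rng.integers(1, max_visits + 1))
    admits, discharges = [], []
    t = int(rng.integers(0, 50))
    for _ in range(n):
        los = int(rng.integers(0, 15))
        admits.append(t)
        discharges.append(t + los)
        t = t + los + int(rng.integers(1, 250))
    return admits, discharges
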