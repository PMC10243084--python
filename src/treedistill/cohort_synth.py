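"""Synthetic hospital-admission cohorts with a known ground-truth risk model.

Real readmission data are administrative, proprietary and visit-structured:
one row per hospital visit, linked by patient id, with admission/discharge
dates and a roster of administrative features (length of stay, comorbidity
scores, admission source, insurance class, specialty, ...).  This module
fabricates tables of that shape under a *known* logistic risk mechanism so
that every downstream stage — label construction, black-box training, GMM
fitting, tree extraction, feature recovery — can be tested against ground
truth the proprietary data cannot provide.

The generative story per patient: an initial admission date, then a chain of
visits.  Each visit draws its features from configurable marginals, computes
a true 30-day readmission probability p = logistic(intercept + sum coef*x),
and draws the gap to the next admission so that

  * with probability p               the gap is uniform on [1, 30] days,
  * else with ``late_readmit_prob``  uniform on [31, 90] days,
  * else                             91 days plus an exponential tail whose
                                     scale is ``interarrival_scale``.

The chain stops at ``max_visits_per_patient`` or when the next admission
would fall outside the observation window.  Because a patient's last
recorded visit necessarily gets label 0, the realized per-visit prevalence
sits below the mechanism's mean risk; :func:`calibrate_mechanism` therefore
tunes the intercept (and the late-readmission probability) against realized
pilot-cohort label means rather than against the risk marginal.

Randomness is a single root seed split per patient by a counter-based
sub-seed, so enlarging the cohort never perturbs earlier patients' draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

# feature columns written to the admission table, in schema order
ID_COLUMNS = ("patient_id", "visit_id", "admit_date", "discharge_date")

SPECIALTY_LEVELS = (
    "medicine", "surgery", "orthopedics", "cardiology",
    "pediatrics", "obstetrics_gynecology", "other",
)


@dataclass(frozen=True)
class FeatureSpec:
    """Marginal description of one generated feature.

    kind 'normal'     : params mean, sd, optional clip (lo, hi), round flag
    kind 'lognormal'  : params mu, sigma of log, round flag
    kind 'binary'     : params p (success probability)
    kind 'categorical': params levels (tuple), probs (tuple summing to 1)
    """

    kind: str
    params: dict = field(default_factory=dict)

    def validate(self, name: str) -> None:
        if self.kind == "binary":
            p = self.params["p"]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}: binary p={p} outside [0, 1]")
        elif self.kind == "categorical":
            probs = np.asarray(self.params["probs"], dtype=float)
            if (probs < 0).any() or (probs > 1).any():
                raise ValueError(f"{name}: categorical probabilities outside [0, 1]")
            if not np.isclose(probs.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{name}: categorical probabilities sum to {probs.sum()}")
            if len(probs) != len(self.params["levels"]):
                raise ValueError(f"{name}: levels/probs length mismatch")
        elif self.kind not in ("normal", "lognormal"):
            raise ValueError(f"{name}: unknown marginal kind {self.kind!r}")


@dataclass
class GroundTruthMechanism:
    """The data-generating risk model: logistic in the generated features.

    ``coefficients`` are on the log-odds scale and may reference any
    generated feature, the emergent ``n_prior_visits``, or a categorical
    indicator written ``"specialty=medicine"``.
    """

    intercept: float
    coefficients: dict[str, float]
    feature_specs: dict[str, FeatureSpec]
    interarrival_scale: float = 150.0     # days; exponential tail beyond 90
    late_readmit_prob: float = 0.15       # P(gap in [31, 90] | no 30-day readmission)

    def validate(self) -> None:
        for name, spec in self.feature_specs.items():
            spec.validate(name)
        for key in self.coefficients:
            base = key.split("=", 1)[0]
            if base not in self.feature_specs and base != "n_prior_visits":
                raise ValueError(f"coefficient references unknown feature {key!r}")
        if not 0.0 <= self.late_readmit_prob <= 1.0:
            raise ValueError("late_readmit_prob must lie in [0, 1]")

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = {
            "intercept": float(self.intercept),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "interarrival_scale": float(self.interarrival_scale),
            "late_readmit_prob": float(self.late_readmit_prob),
            "feature_specs": {
                name: {"kind": s.kind, "params": _plain(s.params)}
                for name, s in self.feature_specs.items()
            },
        }
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "GroundTruthMechanism":
        from .tree import _read_text_maybe_path

        text = _read_text_maybe_path(source)
        payload = yaml.safe_load(text)
        specs = {
            name: FeatureSpec(kind=d["kind"], params=dict(d["params"]))
            for name, d in payload["feature_specs"].items()
        }
        return cls(
            intercept=payload["intercept"],
            coefficients=dict(payload["coefficients"]),
            feature_specs=specs,
            interarrival_scale=payload["interarrival_scale"],
            late_readmit_prob=payload["late_readmit_prob"],
        )


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class SyntheticCohortConfig:
    n_patients: int = 5000
    max_visits_per_patient: int = 8
    date_range: tuple[str, str] = ("2009-01-01", "2010-12-31")
    seed: int = 0
    target_prevalence_30: float = 0.143
    target_prevalence_90: float = 0.244

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.max_visits_per_patient <= 0:
            raise ValueError("max_visits_per_patient must be positive")
        start, end = (date.fromisoformat(d) for d in self.date_range)
        if (end - start).days < 365:
            raise ValueError("date_range must span at least 365 days")
        if not 0.0 < self.target_prevalence_30 <= self.target_prevalence_90 < 1.0:
            raise ValueError("need 0 < target_prevalence_30 <= target_prevalence_90 < 1")

    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = _plain(dataclasses.asdict(self))
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SyntheticCohortConfig":
        from .tree import _read_text_maybe_path

        text = _read_text_maybe_path(source)
        payload = yaml.safe_load(text)
        if "date_range" in payload:
            payload["date_range"] = tuple(payload["date_range"])
        return cls(**payload)


def default_feature_specs() -> dict[str, FeatureSpec]:
    """Marginals sized to resemble an administrative teaching-hospital table:
    age in years, comorbidity indices, length of stay in days, admission
    source/insurance/surgery/ICU flags, specialty shares close to the
    medicine/surgery/orthopedics/cardiology-dominated mix of such hospitals."""
    return {
        "age": FeatureSpec("normal", {"mean": 58.0, "sd": 18.0, "clip": (18.0, 95.0), "round": True}),
        "charlson_score": FeatureSpec("lognormal", {"mu": 0.3, "sigma": 0.8, "round": True}),
        "van_walraven_score": FeatureSpec("normal", {"mean": 4.0, "sd": 6.0, "clip": (-5.0, 30.0), "round": True}),
        "length_of_stay": FeatureSpec("lognormal", {"mu": 1.2, "sigma": 0.8, "round": True}),
        "second_diag_count": FeatureSpec("lognormal", {"mu": 0.9, "sigma": 0.7, "round": True}),
        "admit_ed": FeatureSpec("binary", {"p": 0.55}),
        "nursing_home_discharge": FeatureSpec("binary", {"p": 0.06}),
        "insurance_public": FeatureSpec("binary", {"p": 0.62}),
        "surgery": FeatureSpec("binary", {"p": 0.30}),
        "icu_flag": FeatureSpec("binary", {"p": 0.08}),
        "transfer_count": FeatureSpec("normal", {"mean": 0.15, "sd": 0.5, "clip": (0.0, 5.0), "round": True}),
        "specialty": FeatureSpec("categorical", {
            "levels": list(SPECIALTY_LEVELS),
            "probs": [0.248, 0.197, 0.095, 0.094, 0.06, 0.06, 0.246],
        }),
    }


def default_mechanism() -> GroundTruthMechanism:
    """Stated-world default: a handful of strong administrative risk factors
    (prior visits, comorbidity burden, emergency admission, age, length of
    stay) on the log-odds scale.  The intercept and late-readmission
    probability are the output of :func:`calibrate_mechanism` against the
    14.3% / 24.4% per-visit prevalence targets under the default config."""
    return GroundTruthMechanism(
        intercept=-3.688158563065786,
        coefficients={
            "n_prior_visits": 0.35,
            "charlson_score": 0.18,
            "van_walraven_score": 0.04,
            "age": 0.012,
            "length_of_stay": 0.03,
            "admit_ed": 0.40,
            "nursing_home_discharge": 0.30,
        },
        feature_specs=default_feature_specs(),
        interarrival_scale=150.0,
        late_readmit_prob=0.1315991071652639,
    )


def true_risk(mechanism: GroundTruthMechanism, feature_vector: Mapping[str, object]) -> float:
    """Ground-truth 30-day readmission probability:
    inverse-logit(intercept + sum coefficient * feature).  Categorical terms
    written ``"name=level"`` contribute their coefficient when the level
    matches.  Raises naming any feature a coefficient needs but the vector
    lacks."""
    z = mechanism.intercept
    for key, coef in mechanism.coefficients.items():
        if "=" in key:
            base, level = key.split("=", 1)
            if base not in feature_vector:
                raise KeyError(f"feature vector missing {base!r}")
            z += coef * float(feature_vector[base] == level)
        else:
            if key not in feature_vector:
                raise KeyError(f"feature vector missing {key!r}")
            z += coef * float(feature_vector[key])
    return float(expit(z))


def _draw_feature(spec: FeatureSpec, rng: np.random.Generator, size: int):
    if spec.kind == "normal":
        v = rng.normal(spec.params["mean"], spec.params["sd"], size)
        if "clip" in spec.params:
            v = np.clip(v, *spec.params["clip"])
        return np.round(v) if spec.params.get("round") else v
    if spec.kind == "lognormal":
        v = rng.lognormal(spec.params["mu"], spec.params["sigma"], size)
        return np.round(v) if spec.params.get("round") else v
    if spec.kind == "binary":
        return (rng.random(size) < spec.params["p"]).astype(float)
    if spec.kind == "categorical":
        return rng.choice(spec.params["levels"], size=size, p=spec.params["probs"])
    raise ValueError(f"unknown marginal kind {spec.kind!r}")


def generate_cohort(
    config: SyntheticCohortConfig, mechanism: GroundTruthMechanism
) -> pd.DataFrame:
    """Simulate the admission table: one row per visit, sorted by
    (patient_id, admit_date), ISO dates, features in schema order.

    Byte-for-byte reproducible for identical (config, mechanism): patient i
    uses the dedicated generator ``default_rng([seed, i])``.
    """
    config.validate()
    mechanism.validate()
    start, end = (date.fromisoformat(d) for d in config.date_range)
    span = (end - start).days
    max_v = config.max_visits_per_patient
    spec_items = list(mechanism.feature_specs.items())

    rows: list[dict] = []
    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        draws = {name: _draw_feature(spec, rng, max_v) for name, spec in spec_items}
        # per-patient constants: age and insurance do not change between visits
        for const in ("age", "insurance_public"):
            if const in draws:
                draws[const][:] = draws[const][0]
        u_readmit = rng.random(max_v)
        u_late = rng.random(max_v)
        gaps_30 = rng.integers(1, 31, size=max_v)
        gaps_90 = rng.integers(31, 91, size=max_v)
        gaps_far = 91.0 + rng.exponential(mechanism.interarrival_scale, size=max_v)

        # first admission lands early enough that a follow-up window exists
        admit = start + timedelta(days=int(rng.integers(0, max(span - 180, 1))))
        history_admits: list[date] = []
        history_discharges: list[date] = []
        for k in range(max_v):
            feats = {name: draws[name][k] for name in draws}
            n_prior = sum(
                1
                for a, dch in zip(history_admits, history_discharges)
                if 0 <= (admit - dch).days <= 180
            )
            feats["n_prior_visits"] = n_prior
            los = max(int(feats.get("length_of_stay", 1)), 0)
            discharge = admit + timedelta(days=los)
            rows.append(
                {
                    "patient_id": f"p{i:06d}",
                    "visit_id": f"p{i:06d}v{k:02d}",
                    "admit_date": admit.isoformat(),
                    "discharge_date": discharge.isoformat(),
                    "admit_month": admit.month,
                    "admit_year": admit.year,
                    "admit_dow": admit.weekday(),
                    **{name: feats[name] for name in draws},
                }
            )
            p30 = true_risk(mechanism, feats)
            if u_readmit[k] < p30:
                gap = int(gaps_30[k])
            elif u_late[k] < mechanism.late_readmit_prob:
                gap = int(gaps_90[k])
            else:
                gap = int(gaps_far[k])
            next_admit = discharge + timedelta(days=max(gap, 1))
            if next_admit > end:
                break
            history_admits.append(admit)
            history_discharges.append(discharge)
            admit = next_admit

    table = pd.DataFrame(rows)
    feature_cols = ["admit_month", "admit_year", "admit_dow"] + [n for n, _ in spec_items]
    table = table[list(ID_COLUMNS) + feature_cols]
    return table.sort_values(["patient_id", "admit_date"], kind="mergesort").reset_index(drop=True)


def _realized_prevalences(config: SyntheticCohortConfig, mechanism: GroundTruthMechanism):
    """Per-visit 30- and 90-day label means of a generated cohort."""
    from . import cohort_prep

    table = generate_cohort(config, mechanism)
    labeled = cohort_prep.add_history_columns(table)
    return float(labeled["y30"].mean()), float(labeled["y90"].mean())


def calibrate_mechanism(
    config: SyntheticCohortConfig,
    mechanism: GroundTruthMechanism,
    pilot_patients: int = 2000,
    pilot_seeds: int = 2,
    tol: float = 2e-3,
    max_iter: int = 18,
) -> GroundTruthMechanism:
    """Tune intercept and late_readmit_prob by bisection so the *realized*
    per-visit label means of seeded pilot cohorts hit the config targets.

    Realized prevalence is diluted below the mechanism's mean risk by
    terminal visits (no recorded follow-up), which is why calibration runs
    against full pilot simulations rather than the risk marginal alone.
    Each bisection evaluation averages ``pilot_seeds`` pilot cohorts so that
    the baked-in constants are not fitted to one pilot's Monte-Carlo noise.
    """

    def realized(mech: GroundTruthMechanism) -> tuple[float, float]:
        pairs = [
            _realized_prevalences(
                dataclasses.replace(config, n_patients=pilot_patients, seed=config.seed + s),
                mech,
            )
            for s in range(pilot_seeds)
        ]
        return (float(np.mean([p for p, _ in pairs])), float(np.mean([q for _, q in pairs])))

    mech = dataclasses.replace(mechanism)

    lo, hi = -8.0, 3.0
    for _ in range(max_iter):
        mech.intercept = (lo + hi) / 2.0
        p30, _ = realized(mech)
        if abs(p30 - config.target_prevalence_30) < tol:
            break
        if p30 < config.target_prevalence_30:
            lo = mech.intercept
        else:
            hi = mech.intercept

    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        mech.late_readmit_prob = (lo + hi) / 2.0
        _, p90 = realized(mech)
        if abs(p90 - config.target_prevalence_90) < tol:
            break
        if p90 < config.target_prevalence_90:
            lo = mech.late_readmit_prob
        else:
            hi = mech.late_readmit_prob

    # Bisection stops as soon as a noisy pilot average dips inside tol, which
    # biases the constants by up to the pilot SE.  One corrective step on
    # fresh pilot seeds fixes that: at low prevalence the realized 30-day
    # rate scales ~ e^intercept, and the realized 31-90-day excess scales
    # linearly in late_readmit_prob.
    fresh = dataclasses.replace(config, seed=config.seed + 1000)

    def realized_fresh(mech: GroundTruthMechanism) -> tuple[float, float]:
        pairs = [
            _realized_prevalences(
                dataclasses.replace(fresh, n_patients=pilot_patients, seed=fresh.seed + s), mech
            )
            for s in range(pilot_seeds)
        ]
        return (float(np.mean([p for p, _ in pairs])), float(np.mean([q for _, q in pairs])))

    p30, _ = realized_fresh(mech)
    mech.intercept += float(np.log(config.target_prevalence_30 / p30))
    p30, p90 = realized_fresh(mech)
    excess = max(p90 - p30, 1e-6)
    target_excess = config.target_prevalence_90 - config.target_prevalence_30
    mech.late_readmit_prob = float(
        np.clip(mech.late_readmit_prob * target_excess / excess, 0.0, 1.0)
    )
    return mech


def write_cohort_csv(table: pd.DataFrame, path: str | Path, provenance: str | None = None) -> None:
    """UTF-8 CSV with mandatory header; optional '#'-prefixed provenance line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        table.to_csv(fh, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
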