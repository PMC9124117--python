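"""Synthetic transplant cohort generator with known ground truth.

Real registries of kidney-transplant recipients are rarely shareable, so the
test bed for the whole pipeline is a simulator that emulates their shape: a
few dozen mixed numeric/categorical donor-recipient covariates of which only
a planted minority drive the outcome, identifier and post-operative columns
that the cleaning stage must strip, a small completely-at-random missingness
rate, and transplant / dialysis-initiation / last-follow-up dates from which
a five-year graft-survival label can be derived.

The five-year binary outcome is drawn from a logistic model on the planted
informative pre-operative covariates; the three date columns are then drawn
consistently with it (failed grafts receive a dialysis-initiation date within
the horizon, functioning grafts do not), so re-deriving the label from the
dates reproduces the stored outcome. The returned :class:`GroundTruth`
records which columns were informative and with what coefficients, enabling
feature-recovery tests downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import DIALYSIS_DATE, FOLLOWUP_DATE, TRANSPLANT_DATE, CohortTable
from .errors import ConfigurationError

__all__ = ["CohortSpec", "GroundTruth", "generate_cohort", "outcome_probability"]


@dataclass
class CohortSpec:
    """Parameters of a simulated transplant cohort.

    ``n_features`` counts all identifier + pre-operative + post-operative
    columns (dates and the outcome come on top), so the default 67 yields
    61 pre-operative covariates. ``coefficients`` are log-odds effect
    sizes of the ``n_informative`` planted covariates; the default is an
    alternating ±1 pattern, a strong-but-plausible clinical effect on
    standardized covariates.
    """

    n_patients: int
    n_features: int = 67
    n_informative: int = 10
    n_postop: int = 4
    n_identifier: int = 2
    coefficients: np.ndarray | None = None
    intercept: float = 0.0
    missing_rate: float = 0.01
    categorical_fraction: float = 0.3
    horizon_days: int = 1826
    start_date: str = "1995-01-01"
    window_days: int = 3650
    censored_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        if self.n_postop < 0 or self.n_identifier < 0:
            raise ConfigurationError("column counts must be non-negative")
        if self.n_preop < 1:
            raise ConfigurationError(
                "n_features must exceed n_identifier + n_postop"
            )
        if not 1 <= self.n_informative <= self.n_preop:
            raise ConfigurationError(
                f"n_informative must be in [1, {self.n_preop}]"
            )
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1]")
        if not 0.0 <= self.categorical_fraction <= 1.0:
            raise ConfigurationError("categorical_fraction must lie in [0, 1]")
        if self.horizon_days < 1:
            raise ConfigurationError("horizon_days must be positive")
        if self.coefficients is None:
            signs = np.where(np.arange(self.n_informative) % 2 == 0, 1.0, -1.0)
            self.coefficients = signs
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.n_informative,):
            raise ConfigurationError(
                f"coefficients must have length {self.n_informative}, "
                f"got {self.coefficients.shape}"
            )

    @property
    def n_preop(self) -> int:
        return self.n_features - self.n_identifier - self.n_postop


@dataclass
class GroundTruth:
    """What the generator planted: which columns matter and how much."""

    informative_columns: list[str]
    coefficients: np.ndarray
    intercept: float
    latent_probabilities: np.ndarray = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "informative_columns": self.informative_columns,
            "coefficients": list(map(float, self.coefficients)),
            "intercept": float(self.intercept),
            "latent_probabilities": list(map(float, self.latent_probabilities)),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def outcome_probability(
    covariates: np.ndarray, coefficients: np.ndarray, intercept: float
) -> float:
    """Logistic link: P(survive) = 1 / (1 + exp(-(intercept + x·beta)))."""
    covariates = np.asarray(covariates, dtype=float)
    coefficients = np.asarray(coefficients, dtype=float)
    if covariates.shape != coefficients.shape:
        raise ConfigurationError(
            f"covariates {covariates.shape} and coefficients "
            f"{coefficients.shape} must have equal length"
        )
    return float(expit(intercept + covariates @ coefficients))


def _draw_feature_matrix(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-op covariate matrix and a boolean categorical marker per column.

    Categorical columns hold symmetric integer codes (level - (k-1)//2 for k
    levels) so a zero intercept keeps outcome prevalence near one half.
    """
    p = spec.n_preop
    n_cat = int(round(spec.categorical_fraction * p))
    is_cat = np.zeros(p, dtype=bool)
    if n_cat:
        is_cat[rng.choice(p, size=n_cat, replace=False)] = True
    X = np.empty((spec.n_patients, p))
    for j in range(p):
        if is_cat[j]:
            k = int(rng.integers(2, 6))  # 2..5 levels
            probs = rng.dirichlet(np.full(k, 5.0))
            levels = rng.choice(k, size=spec.n_patients, p=probs)
            X[:, j] = levels - (k - 1) // 2
        else:
            X[:, j] = rng.normal(size=spec.n_patients)
    return X, is_cat


def generate_cohort(spec: CohortSpec) -> tuple[CohortTable, GroundTruth]:
    """Simulate a cohort table and its generating ground truth.

    The table's rows are sorted by transplant date (the temporal order used
    by neighbour-mean imputation). Missing cells are injected completely at
    random into pre-op and post-op columns only, never in two temporally
    adjacent cells of the same column.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    # transplant dates first: row order is ascending transplant date
    start = np.datetime64(spec.start_date)
    tx_offsets = np.sort(rng.integers(0, spec.window_days, size=n))
    tx_dates = start + tx_offsets.astype("timedelta64[D]")

    X, is_cat = _draw_feature_matrix(spec, rng)
    informative_idx = np.sort(
        rng.choice(spec.n_preop, size=spec.n_informative, replace=False)
    )
    eta = spec.intercept + X[:, informative_idx] @ spec.coefficients
    prob = expit(eta)
    y = (rng.uniform(size=n) < prob).astype(int)  # 1 = graft functioning at 5y

    # dates consistent with the outcome
    horizon = spec.horizon_days
    dialysis = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    followup = np.empty(n, dtype="datetime64[D]")
    fail_delay = rng.integers(30, horizon, size=n)
    post_fail = rng.integers(0, 366, size=n)
    surv_extra = rng.integers(horizon, horizon + 1096, size=n)
    cens_delay = rng.integers(180, horizon, size=n)
    censored = (y == 1) & (rng.uniform(size=n) < spec.censored_fraction)
    for i in range(n):
        if y[i] == 0:
            dialysis[i] = tx_dates[i] + np.timedelta64(int(fail_delay[i]), "D")
            followup[i] = dialysis[i] + np.timedelta64(int(post_fail[i]), "D")
        elif censored[i]:
            followup[i] = tx_dates[i] + np.timedelta64(int(cens_delay[i]), "D")
        else:
            followup[i] = tx_dates[i] + np.timedelta64(int(surv_extra[i]), "D")

    # assemble columns
    frame = pd.DataFrame()
    schema: dict[str, str] = {}
    for j in range(spec.n_identifier):
        name = f"id_{j}"
        if j == 0:
            frame[name] = [f"P{i:06d}" for i in range(n)]
        else:
            frame[name] = rng.integers(10_000, 99_999, size=n)
        schema[name] = "identifier"
    preop_names = []
    for j in range(spec.n_preop):
        kind = "cat" if is_cat[j] else "num"
        name = f"preop_{j:02d}_{kind}"
        preop_names.append(name)
        frame[name] = X[:, j]
        schema[name] = "preop"
    for j in range(spec.n_postop):
        name = f"postop_{j}"
        # independent of outcome by construction
        frame[name] = rng.normal(size=n)
        schema[name] = "postop"
    frame[TRANSPLANT_DATE] = pd.to_datetime(tx_dates)
    frame[DIALYSIS_DATE] = pd.to_datetime(dialysis)
    frame[FOLLOWUP_DATE] = pd.to_datetime(followup)
    schema[TRANSPLANT_DATE] = schema[DIALYSIS_DATE] = schema[FOLLOWUP_DATE] = "date"
    frame["graft_survival_5y"] = y
    schema["graft_survival_5y"] = "outcome"

    _inject_missing(frame, schema, spec, rng)

    truth = GroundTruth(
        informative_columns=[preop_names[j] for j in informative_idx],
        coefficients=spec.coefficients.copy(),
        intercept=spec.intercept,
        latent_probabilities=prob,
    )
    return CohortTable(frame, schema), truth


def _inject_missing(
    frame: pd.DataFrame,
    schema: dict[str, str],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> None:
    """Blank cells MCAR in feature columns, never two adjacent in a column.

    Adjacency exclusion guarantees the temporal-neighbour mean imputation
    always has at least one observed neighbour on each side (or the single
    nearest one at the boundary).
    """
    if spec.missing_rate == 0:
        return
    n = len(frame)
    eligible = [c for c in frame.columns if schema[c] in ("preop", "postop")]
    for col in eligible:
        target = rng.binomial(n, spec.missing_rate)
        if target == 0:
            continue
        chosen: set[int] = set()
        for idx in rng.permutation(n):
            if len(chosen) >= target:
                break
            if idx - 1 in chosen or idx + 1 in chosen:
                continue
            chosen.add(int(idx))
        values = frame[col].astype(float).to_numpy()
        values[sorted(chosen)] = np.nan
        frame[col] = values
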