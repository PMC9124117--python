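"""Data processing: cleaning, temporal-neighbour imputation, censoring labels.

The pipeline predicts the transplant outcome *before* the operation, so
cleaning removes every identifier and post-operative column and keeps only
pre-operative covariates, the date columns needed for labelling, and the
outcome. Missing covariate values are imputed with the mean of the nearest
preceding and next observed values in temporal order (rows are ordered by
transplant date); a missing value at a temporal boundary falls back to its
single nearest observed neighbour. Rows that are mostly missing are dropped
before imputation.

Graft time is the number of days from transplantation to dialysis
re-initiation (failed graft) or to the last follow-up visit (functioning
graft); a functioning graft observed for less than the five-year horizon is
censored. For binary modelling, functioning grafts -- survived or censored
-- form class 1 ("survive") and failed grafts class 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .cohort import DIALYSIS_DATE, FOLLOWUP_DATE, TRANSPLANT_DATE, CohortTable
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "CensoredOutcome",
    "clean_table",
    "drop_sparse_rows",
    "impute_temporal_mean",
    "impute_table",
    "derive_graft_outcome",
    "attach_labels",
    "split_train_test",
]

#: five years in days (5 x 365.25, rounded)
DEFAULT_HORIZON_DAYS = 1826


@dataclass(frozen=True)
class CensoredOutcome:
    """Graft time in days plus its censoring status."""

    graft_time_days: int
    status: str  # "failed" | "survived" | "censored"

    @property
    def label(self) -> int:
        """Binary modelling label: 1 = survive (incl. censored-functioning)."""
        return 0 if self.status == "failed" else 1


def clean_table(table: CohortTable, run_log: list[str] | None = None) -> CohortTable:
    """Drop identifier and post-operative columns.

    Keeps pre-op covariates, date columns (needed for labelling) and the
    outcome. Idempotent. Raises :class:`DataError` if no pre-op column
    would remain.
    """
    keep = table.columns_by_tag("preop", "date", "outcome")
    dropped = [c for c in table.frame.columns if c not in keep]
    if not table.columns_by_tag("preop"):
        raise DataError("cleaning would leave no pre-operative columns")
    for col in dropped:
        msg = f"drop_column {col} reason={table.schema[col]}"
        logger.info(msg)
        if run_log is not None:
            run_log.append(msg)
    return table.select_columns(keep)


def drop_sparse_rows(
    table: CohortTable,
    max_missing_fraction: float = 0.3,
    run_log: list[str] | None = None,
) -> CohortTable:
    """Delete rows whose missing fraction over feature columns is excessive."""
    feature_cols = table.columns_by_tag("preop", "postop")
    if not feature_cols:
        return table
    frac = table.frame[feature_cols].isna().mean(axis=1)
    bad = frac > max_missing_fraction
    if bad.any():
        for idx in table.frame.index[bad]:
            msg = f"drop_row {idx} reason=missing_fraction>{max_missing_fraction}"
            logger.info(msg)
            if run_log is not None:
                run_log.append(msg)
    return CohortTable(table.frame.loc[~bad].reset_index(drop=True), dict(table.schema))


def impute_temporal_mean(values, temporal_order=None) -> np.ndarray:
    """Impute missing entries from temporal neighbours.

    Each missing entry becomes the arithmetic mean of the nearest preceding
    and nearest following observed values in temporal order; at the
    boundaries (no preceding or no following observation) the single nearest
    observed neighbour is used. Observed entries are returned unchanged.

    Parameters
    ----------
    values : 1-d array-like with NaN for missing entries
    temporal_order : optional permutation of indices giving temporal order;
        by default the array is assumed already temporally ordered.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if temporal_order is None:
        order = np.arange(n)
    else:
        order = np.asarray(temporal_order)
        if sorted(order.tolist()) != list(range(n)):
            raise ConfigurationError("temporal_order is not a permutation")
    ordered = values[order]
    observed = np.flatnonzero(~np.isnan(ordered))
    if observed.size == 0:
        raise DataError("cannot impute a column with no observed values")
    result = ordered.copy()
    for i in np.flatnonzero(np.isnan(ordered)):
        pos = np.searchsorted(observed, i)
        prev_idx = observed[pos - 1] if pos > 0 else None
        next_idx = observed[pos] if pos < observed.size else None
        if prev_idx is not None and next_idx is not None:
            result[i] = 0.5 * (ordered[prev_idx] + ordered[next_idx])
        elif prev_idx is not None:
            result[i] = ordered[prev_idx]
        else:
            result[i] = ordered[next_idx]
    out = np.empty_like(result)
    out[order] = result
    return out


def impute_table(table: CohortTable, run_log: list[str] | None = None) -> CohortTable:
    """Apply temporal-neighbour mean imputation to every feature column."""
    frame = table.frame.copy()
    for col in table.columns_by_tag("preop", "postop"):
        n_missing = int(frame[col].isna().sum())
        if n_missing == 0:
            continue
        frame[col] = impute_temporal_mean(frame[col].to_numpy(dtype=float))
        msg = f"impute_column {col} n_missing={n_missing}"
        logger.debug(msg)
        if run_log is not None:
            run_log.append(msg)
    return CohortTable(frame, dict(table.schema))


def derive_graft_outcome(
    record: Mapping, horizon_days: int = DEFAULT_HORIZON_DAYS
) -> CensoredOutcome:
    """Derive graft time and censoring status from a patient's dates.

    A present dialysis-initiation date means the graft failed: graft time is
    dialysis start minus transplant date. Otherwise the graft functioned
    through follow-up: graft time is last follow-up minus transplant date,
    and the record is censored when that time is shorter than the horizon.
    """
    tx = pd.Timestamp(record[TRANSPLANT_DATE])
    if pd.isna(tx):
        raise DataError("transplant date is missing")
    dial = record.get(DIALYSIS_DATE)
    if dial is not None and not pd.isna(dial):
        days = (pd.Timestamp(dial) - tx).days
        if days < 0:
            raise DataError("dialysis initiation precedes transplantation")
        return CensoredOutcome(graft_time_days=days, status="failed")
    fup = record.get(FOLLOWUP_DATE)
    if fup is None or pd.isna(fup):
        raise DataError("neither dialysis-start nor follow-up date present")
    days = (pd.Timestamp(fup) - tx).days
    if days < 0:
        raise DataError("last follow-up precedes transplantation")
    status = "survived" if days >= horizon_days else "censored"
    return CensoredOutcome(graft_time_days=days, status=status)


def attach_labels(
    table: CohortTable, horizon_days: int = DEFAULT_HORIZON_DAYS
) -> CohortTable:
    """Re-derive the binary outcome from the date columns.

    Adds/overwrites the outcome column with the censoring-derived label and
    drops the date columns (their information is consumed). The existing
    outcome column name is preserved if present, else ``graft_survival_5y``.
    """
    outcomes = table.columns_by_tag("outcome")
    out_col = outcomes[0] if outcomes else "graft_survival_5y"
    labels = np.empty(table.n_patients, dtype=int)
    for i, (_, row) in enumerate(table.frame.iterrows()):
        labels[i] = derive_graft_outcome(row, horizon_days).label
    frame = table.frame.drop(columns=table.columns_by_tag("date")).copy()
    frame[out_col] = labels
    schema = {c: table.schema[c] for c in frame.columns if c != out_col}
    schema[out_col] = "outcome"
    return CohortTable(frame, schema)


def split_train_test(
    table: CohortTable,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[CohortTable, CohortTable]:
    """Disjoint train/test row partition, reproducible by seed.

    The training partition holds round(train_fraction * n) rows and is
    stratified by outcome by default.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must lie strictly in (0, 1)")
    n = table.n_patients
    if n < 2:
        raise DataError("need at least 2 rows to split")
    train_n = int(round(train_fraction * n))
    train_n = min(max(train_n, 1), n - 1)
    strat = table.frame[table.outcome_column].to_numpy() if stratify else None
    idx_train, idx_test = train_test_split(
        np.arange(n), train_size=train_n, random_state=seed, stratify=strat
    )
    idx_train.sort()
    idx_test.sort()
    schema = dict(table.schema)
    return (
        CohortTable(table.frame.iloc[idx_train].reset_index(drop=True), schema),
        CohortTable(table.frame.iloc[idx_test].reset_index(drop=True), dict(schema)),
    )
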