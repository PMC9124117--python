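"""Cohort container: a patient-by-feature table with a column schema.

Every column of a :class:`CohortTable` carries one of five schema tags --
``identifier``, ``preop``, ``postop``, ``date`` or ``outcome`` -- which the
cleaning and labelling stages use to decide what to keep, what to drop and
where the survival label comes from. On disk a cohort is a plain CSV plus a
sidecar ``<name>.schema`` file of ``column=tag`` lines, so a cohort round
trips through text only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DataError

VALID_TAGS = frozenset({"identifier", "preop", "postop", "date", "outcome"})

#: canonical date column names used throughout the pipeline
TRANSPLANT_DATE = "transplant_date"
DIALYSIS_DATE = "dialysis_start_date"
FOLLOWUP_DATE = "last_followup_date"


@dataclass
class CohortTable:
    """A rectangular patient table plus per-column schema tags.

    Rows are kept in temporal order (ascending transplant date); the
    generator emits them sorted and the preprocessing stages preserve
    that order, so "temporal neighbours" are simply adjacent rows.
    """

    frame: pd.DataFrame
    schema: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(self.frame.columns) - set(self.schema)
        if missing:
            raise DataError(f"columns without schema tag: {sorted(missing)}")
        extra = set(self.schema) - set(self.frame.columns)
        if extra:
            raise DataError(f"schema tags for absent columns: {sorted(extra)}")
        bad = {c: t for c, t in self.schema.items() if t not in VALID_TAGS}
        if bad:
            raise DataError(f"invalid schema tags: {bad}")
        outcomes = self.columns_by_tag("outcome")
        if len(outcomes) > 1:
            raise DataError(f"expected at most one outcome column, got {outcomes}")

    # -- accessors ---------------------------------------------------------

    def columns_by_tag(self, *tags: str) -> list[str]:
        """Column names carrying any of the given tags, in table order."""
        want = set(tags)
        return [c for c in self.frame.columns if self.schema[c] in want]

    @property
    def outcome_column(self) -> str:
        cols = self.columns_by_tag("outcome")
        if not cols:
            raise DataError("cohort has no outcome column")
        return cols[0]

    @property
    def n_patients(self) -> int:
        return len(self.frame)

    def copy(self) -> "CohortTable":
        return CohortTable(self.frame.copy(), dict(self.schema))

    def select_columns(self, columns: list[str]) -> "CohortTable":
        return CohortTable(
            self.frame[columns].copy(), {c: self.schema[c] for c in columns}
        )

    # -- text round trip ---------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV and its schema as a ``.schema`` sidecar."""
        path = Path(path)
        frame = self.frame.copy()
        for col in self.columns_by_tag("date"):
            # ISO dates; empty string for missing
            frame[col] = frame[col].dt.strftime("%Y-%m-%d")
        frame.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".schema")
        lines = [f"{c}={self.schema[c]}" for c in self.frame.columns]
        sidecar.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, schema_path: str | Path | None = None) -> "CohortTable":
        path = Path(path)
        if schema_path is None:
            schema_path = path.with_suffix(path.suffix + ".schema")
        schema_path = Path(schema_path)
        if not schema_path.exists():
            raise DataError(f"schema sidecar not found: {schema_path}")
        schema: dict[str, str] = {}
        for line in schema_path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            col, _, tag = line.partition("=")
            schema[col] = tag
        frame = pd.read_csv(path)
        for col, tag in schema.items():
            if tag == "date" and col in frame.columns:
                frame[col] = pd.to_datetime(frame[col], format="%Y-%m-%d")
        return cls(frame, schema)
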