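"""Experiment-level data schema and CSV I/O.

One row of the dataset describes one published whole-cell patch-clamp
experiment on heterologously expressed Nav1.5: the reported mean midpoint of
activation (``mu_a``, mV) and/or inactivation (``mu_i``, mV), the spread
across cells (sample SD ``sd_a``/``sd_i`` or SEM ``sem_a``/``sem_i``), the
cell counts ``n_a``/``n_i``, and experimental metadata (expression system,
alpha-subunit isoform, beta1 co-expression, liquid-junction-potential status,
holding potentials, activation slope factor, voltage of peak current,
temperature, and solution concentrations).

The in-memory container is a :class:`pandas.DataFrame` with exactly the
columns in :data:`COLUMNS`; empty cells mean "not reported". Voltages are in
mV (negative = hyperpolarized), temperature in degrees C, concentrations in
mM except intracellular calcium in uM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import (
    ConsistencyError,
    DatasetError,
    FormatError,
    RecordError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Columns of the experiment table, in canonical order.
COLUMNS = [
    "study_id",
    "experiment_id",
    "mu_a",
    "sd_a",
    "sem_a",
    "n_a",
    "mu_i",
    "sd_i",
    "sem_i",
    "n_i",
    "cell_type",
    "alpha_subunit",
    "beta1",
    "ljp_status",
    "ljp_mV",
    "v_hold_a",
    "v_hold_i",
    "k_a",
    "v_peak",
    "temperature_C",
    "na_out_mM",
    "na_in_mM",
    "ca_in_uM",
    "cl_out_mM",
    "cl_in_mM",
]

NUMERIC_COLUMNS = [
    "mu_a", "sd_a", "sem_a", "n_a",
    "mu_i", "sd_i", "sem_i", "n_i",
    "ljp_mV", "v_hold_a", "v_hold_i", "k_a", "v_peak", "temperature_C",
    "na_out_mM", "na_in_mM", "ca_in_uM", "cl_out_mM", "cl_in_mM",
]

COUNT_COLUMNS = ["n_a", "n_i"]

CATEGORICAL_LEVELS = {
    "cell_type": {"HEK", "CHO"},
    "alpha_subunit": {"a", "b", "a*", "b*", "unknown"},
    "beta1": {"yes", "no"},
    "ljp_status": {"corrected", "uncorrected", "unreported"},
}

#: Value used when a categorical field is left empty.
CATEGORICAL_DEFAULTS = {
    "alpha_subunit": "unknown",   # missing isoform info is recorded as unknown
    "beta1": "no",                # no statement of beta1 means not co-expressed
    "ljp_status": "unreported",
}

#: Minimum cells per reported midpoint in the surveyed literature.
MIN_CELL_COUNT = 3

#: Relative tolerance when both SD and SEM are reported for the same side.
SD_SEM_RTOL = 0.01


@dataclass
class ExperimentRecord:
    """A single experiment, as a typed convenience view of one table row."""

    study_id: str
    experiment_id: str
    mu_a: float | None = None
    sd_a: float | None = None
    sem_a: float | None = None
    n_a: int | None = None
    mu_i: float | None = None
    sd_i: float | None = None
    sem_i: float | None = None
    n_i: int | None = None
    cell_type: str = "HEK"
    alpha_subunit: str = "unknown"
    beta1: str = "no"
    ljp_status: str = "unreported"
    ljp_mV: float | None = None
    v_hold_a: float | None = None
    v_hold_i: float | None = None
    k_a: float | None = None
    v_peak: float | None = None
    temperature_C: float | None = None
    na_out_mM: float | None = None
    na_in_mM: float | None = None
    ca_in_uM: float | None = None
    cl_out_mM: float | None = None
    cl_in_mM: float | None = None

    def to_series(self) -> pd.Series:
        return pd.Series({c: getattr(self, c) for c in COLUMNS})


def records_to_frame(records: Iterable[ExperimentRecord]) -> pd.DataFrame:
    """Stack :class:`ExperimentRecord` objects into a schema DataFrame."""
    df = pd.DataFrame([r.to_series() for r in records])
    return _coerce_numeric(df.reindex(columns=COLUMNS))


def _coerce_numeric(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in [c for c in COLUMNS if c not in NUMERIC_COLUMNS]:
        df[col] = df[col].astype("object")
    return df


def _row_errors(row: pd.Series) -> list[str]:
    """Invariant violations for one (numerically coerced) row."""
    errs: list[str] = []
    has_a = pd.notna(row["mu_a"])
    has_i = pd.notna(row["mu_i"])
    if not (has_a or has_i):
        errs.append("neither mu_a nor mu_i present")
    for side, has in (("a", has_a), ("i", has_i)):
        if not has:
            continue
        n = row[f"n_{side}"]
        sd = row[f"sd_{side}"]
        sem = row[f"sem_{side}"]
        if pd.isna(n):
            errs.append(f"n_{side}")
        elif n != int(n) or n < MIN_CELL_COUNT:
            errs.append(f"n_{side} must be an integer >= {MIN_CELL_COUNT}")
        if pd.isna(sd) and pd.isna(sem):
            errs.append(f"one of sd_{side}/sem_{side} required")
        if pd.notna(sd) and sd <= 0:
            errs.append(f"sd_{side} must be > 0")
        if pd.notna(sem) and sem <= 0:
            errs.append(f"sem_{side} must be > 0")
    if pd.notna(row["k_a"]) and row["k_a"] <= 0:
        errs.append("k_a must be > 0")
    if pd.notna(row["ljp_mV"]) and row["ljp_status"] != "corrected":
        errs.append("ljp_mV given but ljp_status is not 'corrected'")
    for col, levels in CATEGORICAL_LEVELS.items():
        val = row[col]
        if pd.notna(val) and val not in levels:
            errs.append(f"{col}={val!r} not in {sorted(levels)}")
    return errs


def validate(df: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate a schema DataFrame against the record invariants.

    In strict mode any violation raises :class:`RecordError` listing the
    offending rows; in lenient mode offending rows are dropped and reported
    through the module logger. Raises :class:`DatasetError` if no valid rows
    remain.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    df = _coerce_numeric(df[COLUMNS])
    for col, default in CATEGORICAL_DEFAULTS.items():
        df[col] = df[col].where(df[col].notna() & (df[col] != ""), default)
    bad_rows, messages = [], []
    for idx, row in df.iterrows():
        errs = _row_errors(row)
        if errs:
            bad_rows.append(idx)
            messages.append(f"row {idx}: {'; '.join(errs)}")
    if bad_rows:
        if strict:
            raise RecordError("\n".join(messages))
        for msg in messages:
            logger.warning("dropping invalid record (%s)", msg)
        df = df.drop(index=bad_rows)
    if len(df) == 0:
        raise DatasetError("no valid records")
    return df.reset_index(drop=True)


def load_dataset(path, strict: bool = True) -> pd.DataFrame:
    """Read an experiment table from CSV and validate it.

    Empty cells denote absent values; the header must contain every schema
    column. Non-numeric text in a numeric column is a row error, handled
    according to ``strict`` as in :func:`validate`.
    """
    try:
        raw = pd.read_csv(path, dtype="object", keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file or missing header") from exc
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: header is missing columns {missing}")
    raw = raw[COLUMNS]
    raw = raw.where(raw != "", np.nan)
    # a non-empty cell that fails numeric coercion is a row error
    coerced = _coerce_numeric(raw)
    bad_numeric = pd.Series(False, index=raw.index)
    for col in NUMERIC_COLUMNS:
        bad_numeric |= raw[col].notna() & coerced[col].isna()
    if bad_numeric.any():
        rows = list(raw.index[bad_numeric])
        if strict:
            raise RecordError(f"non-numeric values in numeric columns, rows {rows}")
        logger.warning("dropping rows with non-numeric values: %s", rows)
        coerced = coerced.drop(index=rows)
    return validate(coerced, strict=strict)


def save_dataset(df: pd.DataFrame, path) -> None:
    """Write a schema DataFrame as CSV (empty string for absent values)."""
    out = df.reindex(columns=COLUMNS).copy()
    for col in COUNT_COLUMNS:
        # counts are integers; avoid "10.0" in the file
        out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False, na_rep="")


def resolve_sd(df: pd.DataFrame) -> pd.DataFrame:
    """Populate both SD and SEM on every reported side.

    Uses sigma = SEM * sqrt(n) where only the SEM was published and
    SEM = sigma / sqrt(n) where only the SD was. Idempotent. If both were
    reported and disagree by more than 1% relative, raises
    :class:`ConsistencyError`.
    """
    df = df.copy()
    for side in ("a", "i"):
        mu, sd, sem, n = f"mu_{side}", f"sd_{side}", f"sem_{side}", f"n_{side}"
        present = df[mu].notna()
        both = present & df[sd].notna() & df[sem].notna()
        if both.any():
            implied = df.loc[both, sem] * np.sqrt(df.loc[both, n])
            rel = np.abs(implied - df.loc[both, sd]) / df.loc[both, sd]
            bad = rel > SD_SEM_RTOL
            if bad.any():
                rows = list(df.index[both][bad])
                raise ConsistencyError(
                    f"sd_{side} and sem_{side} disagree by >1% in rows {rows}"
                )
        only_sem = present & df[sd].isna() & df[sem].notna()
        df.loc[only_sem, sd] = df.loc[only_sem, sem] * np.sqrt(df.loc[only_sem, n])
        only_sd = present & df[sem].isna() & df[sd].notna()
        df.loc[only_sd, sem] = df.loc[only_sd, sd] / np.sqrt(df.loc[only_sd, n])
    return df


def subset(df: pd.DataFrame, **criteria) -> pd.DataFrame:
    """Select records whose metadata match every ``field=value`` criterion.

    A value may also be a callable predicate applied elementwise. Order is
    preserved. Unknown field names raise :class:`SchemaError`.
    """
    mask = pd.Series(True, index=df.index)
    for field, value in criteria.items():
        if field not in COLUMNS:
            raise SchemaError(f"unknown field {field!r}")
        col = df[field]
        if callable(value):
            mask &= col.map(lambda v: bool(value(v)))
        else:
            mask &= col == value
    return df[mask]


def partition(df: pd.DataFrame, key: str) -> dict[str, pd.DataFrame]:
    """Split records into disjoint groups by a metadata field.

    Absent values form their own ``"unknown"`` group, so the groups cover all
    records. Group order follows first appearance; row order is stable.
    """
    if key not in COLUMNS:
        raise SchemaError(f"unknown field {key!r}")
    labels = df[key].where(df[key].notna(), "unknown").astype(str)
    groups: dict[str, pd.DataFrame] = {}
    for label in labels:
        if label not in groups:
            groups[label] = df[labels == label]
    return groups


def midpoint_counts(df: pd.DataFrame) -> dict[str, int]:
    """Counts of experiments with both, only-activation, only-inactivation."""
    has_a, has_i = df["mu_a"].notna(), df["mu_i"].notna()
    return {
        "total": int(len(df)),
        "both": int((has_a & has_i).sum()),
        "activation_only": int((has_a & ~has_i).sum()),
        "inactivation_only": int((~has_a & has_i).sum()),
    }
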