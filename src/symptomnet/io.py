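"""Reading, validation, filtering and summarising of binary symptom-occurrence data.

The central container is :class:`OccurrenceMatrix`: one row per patient, one
column per symptom short code, entries 0/1 with explicit missingness (NaN).
A whole-assessment miss is an all-NaN row, never a row of zeros, so that the
complete-case filter can see it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceMatrix",
    "SymptomCodebook",
    "RateTable",
    "CsvDialect",
    "ValidationError",
    "SchemaError",
    "load_occurrence_matrix",
    "save_occurrence_matrix",
    "complete_case_filter",
    "occurrence_rates",
    "select_top_k_by_occurrence",
    "round_half_up",
]


class ValidationError(ValueError):
    """A cell value violates the binary-data contract."""


class SchemaError(ValueError):
    """Structural problem: duplicate ids/codes, mismatched columns, etc."""


def round_half_up(x: float | Decimal, ndigits: int = 1) -> float:
    """Round with ties away from zero at `ndigits` decimals (half-up).

    Printed occurrence percentages use this convention; plain float rounding
    (banker's) would disagree on exact .x5 ties.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def _rate_percent(count: int, n: int, ndigits: int = 1) -> float:
    # exact rational before rounding, so 112/987 -> 11.3 not 11.299999...
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(100 * count) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CsvDialect:
    """Separator and missing-value markers for occurrence CSV/TSV files."""

    sep: str = ","
    missing_markers: tuple[str, ...] = ("", "NA")


@dataclass
class OccurrenceMatrix:
    """n x p binary symptom data for one time point.

    values : float ndarray, entries in {0.0, 1.0, NaN}; NaN marks missing.
    patient_ids : unique row identifiers.
    symptom_codes : unique column short codes.
    time_point : optional label, e.g. "T1".
    """

    values: np.ndarray
    patient_ids: list[str]
    symptom_codes: list[str]
    time_point: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("values must be a 2-D array")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise SchemaError("matrix must have at least one row and one column")
        if len(self.patient_ids) != n:
            raise SchemaError(f"{len(self.patient_ids)} patient ids for {n} rows")
        if len(self.symptom_codes) != p:
            raise SchemaError(f"{len(self.symptom_codes)} symptom codes for {p} columns")
        if len(set(self.patient_ids)) != n:
            raise SchemaError("duplicate patient ids")
        if len(set(self.symptom_codes)) != p:
            raise SchemaError("duplicate symptom codes")
        obs = self.values[~np.isnan(self.values)]
        bad = obs[(obs != 0.0) & (obs != 1.0)]
        if bad.size:
            i, j = np.argwhere(~np.isnan(self.values) & (self.values != 0) & (self.values != 1))[0]
            raise ValidationError(
                f"non-binary value {self.values[i, j]!r} at row {self.patient_ids[i]!r}, "
                f"column {self.symptom_codes[j]!r}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def complete_rows(self) -> np.ndarray:
        """Boolean mask of rows with no missing entry."""
        return ~np.isnan(self.values).any(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.patient_ids, name="id"),
                            columns=self.symptom_codes)

    def subset_patients(self, ids: Sequence[str]) -> "OccurrenceMatrix":
        pos = {pid: i for i, pid in enumerate(self.patient_ids)}
        idx = [pos[i] for i in ids]
        return OccurrenceMatrix(self.values[idx], list(ids), list(self.symptom_codes),
                                self.time_point)

    def subset_symptoms(self, codes: Sequence[str]) -> "OccurrenceMatrix":
        pos = {c: j for j, c in enumerate(self.symptom_codes)}
        idx = [pos[c] for c in codes]
        return OccurrenceMatrix(self.values[:, idx], list(self.patient_ids), list(codes),
                                self.time_point)


@dataclass(frozen=True)
class SymptomCodebook:
    """Short code -> full symptom name, in a fixed display order."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for code, name in self.entries.items():
            if not name:
                raise SchemaError(f"empty name for code {code!r}")

    @property
    def codes(self) -> list[str]:
        return list(self.entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SymptomCodebook":
        df = pd.read_csv(path, dtype=str)
        codes = df.iloc[:, 0].tolist()
        if len(set(codes)) != len(codes):
            raise SchemaError("duplicate codes in codebook")
        return cls(dict(zip(codes, df.iloc[:, 1].tolist())))


@dataclass
class RateTable:
    """Per-symptom occurrence counts and percentages, sorted descending by rate."""

    table: pd.DataFrame  # index: code; columns: count (int), rate_percent (float)
    n: int

    def rate(self, code: str) -> float:
        return float(self.table.loc[code, "rate_percent"])

    def count(self, code: str) -> int:
        return int(self.table.loc[code, "count"])

    def to_csv(self, path: str | Path, codebook: SymptomCodebook | None = None) -> None:
        out = self.table.copy()
        if codebook is not None:
            out.insert(0, "symptom", [codebook.entries.get(c, "") for c in out.index])
        out.to_csv(path, index_label="code")


def load_occurrence_matrix(path: str | Path, dialect: CsvDialect = CsvDialect(),
                           time_point: str | None = None) -> OccurrenceMatrix:
    """Read a patient x symptom occurrence table.

    The first column is the patient id; the header row holds symptom short
    codes. Missing markers become NaN. Any other non-binary cell raises
    :class:`ValidationError` naming the offending row and column.
    """
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, index_col=0,
                     keep_default_na=False)
    if df.index.has_duplicates:
        raise SchemaError(f"duplicate patient ids in {path}")
    if df.columns.has_duplicates:
        raise SchemaError(f"duplicate symptom codes in {path}")
    vals = np.full(df.shape, np.nan)
    raw = df.to_numpy()
    for (i, j), cell in np.ndenumerate(raw):
        s = cell.strip() if isinstance(cell, str) else cell
        if s in dialect.missing_markers:
            continue
        if s == "0":
            vals[i, j] = 0.0
        elif s == "1":
            vals[i, j] = 1.0
        else:
            raise ValidationError(
                f"non-binary value {cell!r} at row {df.index[i]!r}, column {df.columns[j]!r}"
            )
    m = OccurrenceMatrix(vals, [str(i) for i in df.index], [str(c) for c in df.columns],
                         time_point)
    logger.info("loaded %s: n=%d, p=%d, missing=%d", path, m.n, m.p,
                int(m.missing_mask.sum()))
    return m


def save_occurrence_matrix(m: OccurrenceMatrix, path: str | Path,
                           dialect: CsvDialect = CsvDialect()) -> None:
    """Write a matrix in the dialect `load_occurrence_matrix` reads back."""
    df = m.to_dataframe()
    out = df.map(lambda v: "" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep=dialect.sep)


@dataclass
class CompleteCaseReport:
    retained: int
    dropped: int
    dropped_per_time_point: dict[str, int] = field(default_factory=dict)


def complete_case_filter(
    matrices: Sequence[OccurrenceMatrix],
) -> tuple[list[OccurrenceMatrix], CompleteCaseReport]:
    """Restrict every time point to patients fully observed at all time points.

    Returns matrices over the intersection of complete patients (original
    order preserved) plus a report of dropped counts. An empty retained set
    is a warning, not an error.
    """
    codes = matrices[0].symptom_codes
    for m in matrices:
        if m.symptom_codes != codes:
            raise SchemaError("matrices disagree on symptom codes")
    complete_sets = []
    per_tp: dict[str, int] = {}
    for t, m in enumerate(matrices):
        ok = m.complete_rows()
        complete = {pid for pid, c in zip(m.patient_ids, ok) if c}
        per_tp[m.time_point or f"T{t + 1}"] = m.n - len(complete)
        complete_sets.append(complete)
    common = set.intersection(*complete_sets) if complete_sets else set()
    # intersect with patients present at every time point
    for m in matrices:
        common &= set(m.patient_ids)
    keep = [pid for pid in matrices[0].patient_ids if pid in common]
    n_total = len(set().union(*(set(m.patient_ids) for m in matrices)))
    report = CompleteCaseReport(retained=len(keep), dropped=n_total - len(keep),
                                dropped_per_time_point=per_tp)
    if not keep:
        warnings.warn("complete-case filter retained no patients", stacklevel=2)
        return [], report
    return [m.subset_patients(keep) for m in matrices], report


def occurrence_rates(m: OccurrenceMatrix) -> RateTable:
    """Column occurrence counts and percentages (half-up, one decimal).

    Requires complete data: run after :func:`complete_case_filter`. Sorted
    descending by rate so the most common symptom heads the table.
    """
    if m.has_missing:
        raise ValidationError("occurrence_rates requires complete data (missing entries found)")
    counts = m.values.sum(axis=0).astype(int)
    rates = [_rate_percent(int(c), m.n) for c in counts]
    df = pd.DataFrame({"count": counts, "rate_percent": rates},
                      index=pd.Index(m.symptom_codes, name="code"))
    df = df.sort_values("rate_percent", ascending=False, kind="stable")
    return RateTable(table=df, n=m.n)


def select_top_k_by_occurrence(m: OccurrenceMatrix, k: int,
                               reference: RateTable | None = None,
                               codebook_order: Sequence[str] | None = None) -> OccurrenceMatrix:
    """Keep the `k` symptoms with the highest occurrence rate.

    Ties are broken by codebook order (defaults to the matrix's own column
    order); the returned columns are ordered by descending rate.
    """
    if not 1 <= k <= m.p:
        raise ValueError(f"k={k} out of range 1..{m.p}")
    if reference is None:
        reference = occurrence_rates(m)
    order = list(codebook_order) if codebook_order is not None else list(m.symptom_codes)
    rank = {c: i for i, c in enumerate(order)}
    ordered = sorted(m.symptom_codes,
                     key=lambda c: (-reference.rate(c), rank.get(c, len(rank))))
    return m.subset_symptoms(ordered[:k])
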