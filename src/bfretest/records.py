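"""Extraction-sheet schema and CSV round-trip for reported t tests.

One :class:`ReportedTest` corresponds to one t test extracted from a published
article: the test kind, the group summary statistics (mean, SD, n — or the
difference summaries for dependent tests), the P value as printed together with
its qualifier ("=", "<" or "≤"), and optionally the printed t statistic.

The canonical CSV layout is fixed: UTF-8, comma-separated, RFC-4180 quoting,
header ``test_id, source, test_kind, n1, mean1, sd1, n2, mean2, sd2,
reported_t, reported_p, reported_p_qualifier``. Missing numeric cells are empty
strings, never sentinel numbers. Unknown extra columns (provenance notes and
the like) are carried through a round-trip untouched but ignored by every
computation.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import RowValidationError, SchemaError

__all__ = [
    "TestKind",
    "PQualifier",
    "ReportedTest",
    "CANONICAL_COLUMNS",
    "read_tests",
    "write_tests",
]


class TestKind(str, enum.Enum):
    """Which t-test family the article reported."""

    ONE_SAMPLE = "one_sample"
    INDEPENDENT = "independent"
    DEPENDENT = "dependent"


class PQualifier(str, enum.Enum):
    """How the article printed its P value: "=", "<" or "≤"."""

    EQ = "eq"
    LT = "lt"
    LE = "le"


CANONICAL_COLUMNS: tuple[str, ...] = (
    "test_id",
    "source",
    "test_kind",
    "n1",
    "mean1",
    "sd1",
    "n2",
    "mean2",
    "sd2",
    "reported_t",
    "reported_p",
    "reported_p_qualifier",
)

#: Columns that must appear in the header. The qualifier column may be omitted,
#: in which case every P is taken as printed exactly ("=").
_MANDATORY_COLUMNS = tuple(c for c in CANONICAL_COLUMNS if c != "reported_p_qualifier")

_FLOAT_FIELDS = ("mean1", "sd1", "mean2", "sd2", "reported_t", "reported_p")
_INT_FIELDS = ("n1", "n2")


@dataclass
class ReportedTest:
    """One extracted t test, as printed in the source article.

    For ``one_sample`` records ``mean1`` is the sample mean minus the reference
    value; for ``dependent`` records ``mean1``/``sd1`` are the mean and SD of
    the within-pair differences and ``n1`` is the pair count.
    """

    test_id: str
    source: str
    test_kind: TestKind
    n1: int
    mean1: float | None = None
    sd1: float | None = None
    n2: int | None = None
    mean2: float | None = None
    sd2: float | None = None
    reported_t: float | None = None
    reported_p: float | None = None
    reported_p_qualifier: PQualifier = PQualifier.EQ
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.test_kind = TestKind(self.test_kind)
        self.reported_p_qualifier = PQualifier(self.reported_p_qualifier)

    # -- validation ---------------------------------------------------------

    def problems(self) -> list[str]:
        """All schema violations for this record (empty list == valid)."""
        out: list[str] = []
        if self.n1 is None or self.n1 < 2:
            out.append(f"n1 must be an integer >= 2, got {self.n1!r}")
        if self.sd1 is not None and not self.sd1 > 0:
            out.append(f"sd1 must be strictly positive, got {self.sd1!r}")
        if self.sd2 is not None and not self.sd2 > 0:
            out.append(f"sd2 must be strictly positive, got {self.sd2!r}")
        if self.test_kind is TestKind.INDEPENDENT:
            if self.n2 is None or self.n2 < 2:
                out.append(f"independent test requires n2 >= 2, got {self.n2!r}")
            if self.has_summaries() and (self.mean2 is None or self.sd2 is None):
                # group-1 summaries without group-2 counterparts are unusable
                out.append("independent test with mean1/sd1 requires mean2 and sd2")
        else:
            for name in ("n2", "mean2", "sd2"):
                if getattr(self, name) is not None:
                    out.append(f"{name} must be absent for {self.test_kind.value} tests")
        if self.reported_p is not None and not (0.0 < self.reported_p <= 1.0):
            out.append(f"reported_p must lie in (0, 1], got {self.reported_p!r}")
        if not self.has_summaries() and self.reported_t is None:
            out.append(
                "record carries neither complete mean/sd summaries nor a reported t; "
                "the t statistic cannot be reconstructed"
            )
        return out

    def validate(self) -> "ReportedTest":
        """Raise :class:`RowValidationError` if the record is malformed."""
        probs = self.problems()
        if probs:
            raise RowValidationError(f"test_id={self.test_id!r}: " + "; ".join(probs))
        return self

    def has_summaries(self) -> bool:
        """True when mean/SD summaries sufficient for the test kind are present."""
        if self.mean1 is None or self.sd1 is None:
            return False
        if self.test_kind is TestKind.INDEPENDENT:
            return self.mean2 is not None and self.sd2 is not None and self.n2 is not None
        return True


def _parse_cell(row_no: int, name: str, raw: str, caster, problems: list[str]):
    raw = raw.strip()
    if raw == "":
        return None
    try:
        value = caster(raw)
    except ValueError:
        problems.append(f"row {row_no}: column {name!r}: not numeric: {raw!r}")
        return None
    if isinstance(value, float) and not math.isfinite(value):
        problems.append(f"row {row_no}: column {name!r}: non-finite value {raw!r}")
        return None
    return value


def _parse_int(raw: str) -> int:
    f = float(raw)
    i = int(round(f))
    if f != i:
        raise ValueError(raw)
    return i


def _record_from_row(row_no: int, row: dict[str, str]) -> ReportedTest:
    """Build and validate one record; raises RowValidationError with row number."""
    problems: list[str] = []
    kind_raw = (row.get("test_kind") or "").strip()
    try:
        kind = TestKind(kind_raw)
    except ValueError:
        raise RowValidationError(
            f"row {row_no}: column 'test_kind': unknown kind {kind_raw!r} "
            f"(expected one of {[k.value for k in TestKind]})"
        )
    qual_raw = (row.get("reported_p_qualifier") or "").strip()
    try:
        qualifier = PQualifier(qual_raw) if qual_raw else PQualifier.EQ
    except ValueError:
        raise RowValidationError(
            f"row {row_no}: column 'reported_p_qualifier': unknown qualifier {qual_raw!r}"
        )

    numeric: dict[str, float | int | None] = {}
    for name in _INT_FIELDS:
        numeric[name] = _parse_cell(row_no, name, row.get(name, ""), _parse_int, problems)
    for name in _FLOAT_FIELDS:
        numeric[name] = _parse_cell(row_no, name, row.get(name, ""), float, problems)
    if problems:
        raise RowValidationError("; ".join(problems))

    extra = {k: v for k, v in row.items() if k not in CANONICAL_COLUMNS and k is not None}
    rec = ReportedTest(
        test_id=(row.get("test_id") or "").strip(),
        source=(row.get("source") or "").strip(),
        test_kind=kind,
        n1=numeric["n1"] if numeric["n1"] is not None else 0,
        mean1=numeric["mean1"],
        sd1=numeric["sd1"],
        n2=numeric["n2"],
        mean2=numeric["mean2"],
        sd2=numeric["sd2"],
        reported_t=numeric["reported_t"],
        reported_p=numeric["reported_p"],
        reported_p_qualifier=qualifier,
        extra=extra,
    )
    probs = rec.problems()
    if probs:
        raise RowValidationError(f"row {row_no}: " + "; ".join(probs))
    return rec


def read_tests(
    path: str | Path,
    dialect: str | csv.Dialect = "excel",
    *,
    errors: str = "raise",
) -> list[ReportedTest] | tuple[list[ReportedTest], list[str]]:
    """Read an extraction sheet.

    Parameters
    ----------
    path
        CSV file with the canonical header.
    dialect
        A :mod:`csv` dialect name or object. The canonical sheets use the
        default ``"excel"`` (comma, RFC-4180 quoting).
    errors
        ``"raise"`` (default): any malformed row aborts with a diagnostic
        naming every offending row. ``"collect"``: return
        ``(records, diagnostics)`` with malformed rows reported, never
        silently dropped.

    An empty file with a valid header yields an empty collection.
    """
    if errors not in ("raise", "collect"):
        raise ValueError(f"errors must be 'raise' or 'collect', got {errors!r}")
    path = Path(path)
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, dialect=dialect)
        header = reader.fieldnames
        if header is None:
            raise SchemaError(f"{path}: file is empty (no header row)")
        missing = [c for c in _MANDATORY_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        records: list[ReportedTest] = []
        diagnostics: list[str] = []
        for row_no, row in enumerate(reader, start=2):  # header is line 1
            try:
                records.append(_record_from_row(row_no, row))
            except RowValidationError as exc:
                diagnostics.append(str(exc))
    if errors == "collect":
        return records, diagnostics
    if diagnostics:
        raise RowValidationError(f"{path}: " + " | ".join(diagnostics))
    return records


def _format_number(value: float | int | None) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):  # guard: bool is an int subclass
        raise TypeError("boolean is not a valid numeric cell")
    if isinstance(value, int):
        return str(value)
    return repr(float(value))  # shortest exact round-trip decimal


def write_tests(tests: Iterable[ReportedTest], path: str | Path) -> None:
    """Write records as the canonical CSV; inverse of :func:`read_tests`.

    Extra (non-canonical) columns present on any record are appended after the
    canonical ones, in first-seen order, so that round-trips preserve them.
    Output is byte-stable for a fixed collection.
    """
    tests = list(tests)
    for t in tests:
        t.validate()
    extra_cols: list[str] = []
    for t in tests:
        for k in t.extra:
            if k not in extra_cols:
                extra_cols.append(k)
    header = list(CANONICAL_COLUMNS) + extra_cols
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for t in tests:
            row = [
                t.test_id,
                t.source,
                t.test_kind.value,
                _format_number(t.n1),
                _format_number(t.mean1),
                _format_number(t.sd1),
                _format_number(t.n2),
                _format_number(t.mean2),
                _format_number(t.sd2),
                _format_number(t.reported_t),
                _format_number(t.reported_p),
                t.reported_p_qualifier.value,
            ]
            row.extend(t.extra.get(k, "") for k in extra_cols)
            writer.writerow(row)


def tests_to_frame(tests: Sequence[ReportedTest]):
    """Represent a collection as a pandas DataFrame (one row per record)."""
    import pandas as pd

    rows = []
    for t in tests:
        rows.append(
            {
                "test_id": t.test_id,
                "source": t.source,
                "test_kind": t.test_kind.value,
                "n1": t.n1,
                "mean1": t.mean1,
                "sd1": t.sd1,
                "n2": t.n2,
                "mean2": t.mean2,
                "sd2": t.sd2,
                "reported_t": t.reported_t,
                "reported_p": t.reported_p,
                "reported_p_qualifier": t.reported_p_qualifier.value,
            }
        )
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
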