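"""Canonical schemas and CSV I/O for the five linked record tables.

A linked-record bundle holds person-level linked unscheduled-care data in five
tables joined by ``person_id``:

* ``persons``      — demographics (date of birth, sex, residency flag)
* ``calls``        — emergency ambulance contacts (service class S), carrying
  the final dispatch triage (AMPDS) code and optional clinical flags
* ``ed``           — emergency-department attendances (class E) with a
  disposition (completed / self-discharge / admitted)
* ``admissions``   — inpatient episodes; ``ward_type`` acute maps to service
  class A, psychiatric to M
* ``deaths``       — at most one death record per person with a coarse cause
  category (suicide / mental & behavioural / other)

Timestamps are ISO-8601 at minute resolution; dates are ISO calendar dates.
Boolean flags absent from a file are read as false, which lets under-reported
optional fields (e.g. alcohol intoxication) be represented directly.
Writing is deterministic: rows are sorted by (person_id, start_datetime,
contact_id) so write→read→write round trips are byte-identical.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

SEX_VALUES = ("male", "female", "unknown")
DISPOSITION_VALUES = ("completed", "self_discharge", "admitted")
WARD_VALUES = ("acute", "psychiatric")
CAUSE_VALUES = ("suicide", "mental_behavioural", "other")
SERVICE_CLASSES = ("S", "E", "A", "M")

TIMESTAMP_FMT = "%Y-%m-%dT%H:%M"
DATE_FMT = "%Y-%m-%d"

_TRUE = "true"
_FALSE = "false"


class BundleFormatError(ValueError):
    """Fatal structural problem in a bundle directory or table."""


@dataclasses.dataclass
class _ColumnSpec:
    kind: str  # "str" | "timestamp" | "date" | "bool" | "enum" | "int"
    required: bool = True
    enum: tuple[str, ...] | None = None


@dataclasses.dataclass
class _TableSpec:
    name: str
    filename: str
    columns: dict[str, _ColumnSpec]
    sort_cols: list[str]


TABLE_SPECS: dict[str, _TableSpec] = {
    "persons": _TableSpec(
        "persons",
        "persons.csv",
        {
            "person_id": _ColumnSpec("str"),
            "date_of_birth": _ColumnSpec("date"),
            "sex": _ColumnSpec("enum", enum=SEX_VALUES),
            "resident_in_scope": _ColumnSpec("bool"),
        },
        ["person_id"],
    ),
    "calls": _TableSpec(
        "calls",
        "calls.csv",
        {
            "contact_id": _ColumnSpec("str"),
            "person_id": _ColumnSpec("str"),
            "start_datetime": _ColumnSpec("timestamp"),
            "end_datetime": _ColumnSpec("timestamp", required=False),
            "final_ampds_code": _ColumnSpec("str"),
            "alcohol_flag": _ColumnSpec("bool"),
            "drug_flag": _ColumnSpec("bool"),
            "lowest_priority_flag": _ColumnSpec("bool"),
            "transported": _ColumnSpec("bool"),
        },
        ["person_id", "start_datetime", "contact_id"],
    ),
    "ed": _TableSpec(
        "ed",
        "ed.csv",
        {
            "contact_id": _ColumnSpec("str"),
            "person_id": _ColumnSpec("str"),
            "start_datetime": _ColumnSpec("timestamp"),
            "end_datetime": _ColumnSpec("timestamp", required=False),
            "disposition": _ColumnSpec("enum", enum=DISPOSITION_VALUES),
            "triage_category": _ColumnSpec("int", required=False),
        },
        ["person_id", "start_datetime", "contact_id"],
    ),
    "admissions": _TableSpec(
        "admissions",
        "admissions.csv",
        {
            "contact_id": _ColumnSpec("str"),
            "person_id": _ColumnSpec("str"),
            "start_datetime": _ColumnSpec("timestamp"),
            "end_datetime": _ColumnSpec("timestamp", required=False),
            "ward_type": _ColumnSpec("enum", enum=WARD_VALUES),
        },
        ["person_id", "start_datetime", "contact_id"],
    ),
    "deaths": _TableSpec(
        "deaths",
        "deaths.csv",
        {
            "person_id": _ColumnSpec("str"),
            "date_of_death": _ColumnSpec("date"),
            "cause_category": _ColumnSpec("enum", enum=CAUSE_VALUES),
        },
        ["person_id"],
    ),
}


@dataclasses.dataclass
class LinkedRecordBundle:
    """The five typed tables of one linked extract, keyed by person_id."""

    persons: pd.DataFrame
    calls: pd.DataFrame
    ed: pd.DataFrame
    admissions: pd.DataFrame
    deaths: pd.DataFrame

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def n_persons(self) -> int:
        return len(self.persons)


@dataclasses.dataclass
class ValidationReport:
    """Outcome of structural validation; errors make a bundle unusable,
    warnings (e.g. contacts recorded after a death date) do not."""

    errors: list[str] = dataclasses.field(default_factory=list)
    warnings: list[str] = dataclasses.field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.errors


def _empty_column(kind: str) -> pd.Series:
    if kind in ("timestamp",):
        return pd.Series(dtype="datetime64[ns]")
    if kind == "date":
        return pd.Series(dtype="datetime64[ns]")
    if kind == "bool":
        return pd.Series(dtype=bool)
    if kind == "int":
        return pd.Series(dtype="Int64")
    return pd.Series(dtype=object)


def empty_bundle() -> LinkedRecordBundle:
    """A bundle with five correctly typed zero-row tables."""
    tables = {}
    for name, spec in TABLE_SPECS.items():
        tables[name] = pd.DataFrame(
            {col: _empty_column(cs.kind) for col, cs in spec.columns.items()}
        )
    return LinkedRecordBundle(**tables)


def _parse_column(raw: pd.Series, col: str, cs: _ColumnSpec, table: str) -> pd.Series:
    raw = raw.astype(str).str.strip()
    blank = raw.eq("") | raw.eq("nan")
    if cs.kind == "str":
        if cs.required and blank.any():
            rows = list(raw.index[blank][:5])
            raise BundleFormatError(
                f"{table}.{col}: empty value in rows {rows}"
            )
        return raw.astype(object)
    if cs.kind in ("timestamp", "date"):
        parsed = pd.to_datetime(raw.where(~blank, None), errors="coerce")
        bad = ~blank & parsed.isna()
        if bad.any():
            rows = [(int(i), raw[i]) for i in raw.index[bad][:5]]
            raise BundleFormatError(
                f"{table}.{col}: unparseable timestamp(s) at (row, value) {rows}"
            )
        if cs.required and blank.any():
            rows = list(raw.index[blank][:5])
            raise BundleFormatError(f"{table}.{col}: missing timestamp in rows {rows}")
        return parsed
    if cs.kind == "bool":
        mapped = raw.where(~blank, _FALSE).str.lower()
        bad = ~mapped.isin([_TRUE, _FALSE])
        if bad.any():
            val = raw[raw.index[bad][0]]
            raise BundleFormatError(
                f"{table}.{col}: invalid boolean value {val!r}"
            )
        return mapped.eq(_TRUE)
    if cs.kind == "enum":
        assert cs.enum is not None
        ok = raw.isin(cs.enum) | (blank & ~cs.required)
        if not ok.all():
            val = raw[raw.index[~ok][0]]
            raise BundleFormatError(
                f"{table}.{col}: invalid value {val!r}; allowed: {cs.enum}"
            )
        return raw.where(~blank, None).astype(object)
    if cs.kind == "int":
        out = pd.to_numeric(raw.where(~blank, None), errors="coerce")
        bad = ~blank & out.isna()
        if bad.any():
            val = raw[raw.index[bad][0]]
            raise BundleFormatError(f"{table}.{col}: invalid integer {val!r}")
        return out.astype("Int64")
    raise AssertionError(cs.kind)


def _read_table(path: Path, spec: _TableSpec) -> pd.DataFrame:
    if not path.exists():
        raise BundleFormatError(f"missing table: {path.name}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in spec.columns if c not in raw.columns]
    if missing:
        raise BundleFormatError(f"{spec.name}: missing columns {missing}")
    extra = [c for c in raw.columns if c not in spec.columns]
    if extra:
        raise BundleFormatError(f"{spec.name}: unexpected columns {extra}")
    if len(raw) == 0:
        return pd.DataFrame(
            {col: _empty_column(cs.kind) for col, cs in spec.columns.items()}
        )
    out = pd.DataFrame(
        {
            col: _parse_column(raw[col], col, cs, spec.name)
            for col, cs in spec.columns.items()
        }
    )
    return out


def read_bundle(directory_path: str | Path) -> LinkedRecordBundle:
    """Read the five tables from ``directory_path`` and type-check them.

    Raises :class:`BundleFormatError` for a missing table, an unparseable
    timestamp (reported with its row number) or an unknown enumeration value
    (reported with the offending value).
    """
    directory = Path(directory_path)
    tables = {
        name: _read_table(directory / spec.filename, spec)
        for name, spec in TABLE_SPECS.items()
    }
    return LinkedRecordBundle(**tables)


def _format_column(values: pd.Series, cs: _ColumnSpec) -> pd.Series:
    if cs.kind == "timestamp":
        return values.dt.strftime(TIMESTAMP_FMT).fillna("")
    if cs.kind == "date":
        return values.dt.strftime(DATE_FMT).fillna("")
    if cs.kind == "bool":
        return values.map({True: _TRUE, False: _FALSE})
    if cs.kind == "int":
        return values.map(lambda v: "" if pd.isna(v) else str(int(v)))
    return values.fillna("")


def write_bundle(bundle: LinkedRecordBundle, directory_path: str | Path) -> list[Path]:
    """Write the five tables as CSV with deterministic row order.

    Rows are sorted by (person_id, start_datetime, contact_id); timestamps are
    ISO-8601 at minute resolution. Returns the written paths.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, spec in TABLE_SPECS.items():
        df = bundle.table(name)
        if len(df):
            df = df.sort_values(spec.sort_cols, kind="mergesort").reset_index(drop=True)
        out = pd.DataFrame(
            {col: _format_column(df[col], cs) for col, cs in spec.columns.items()}
        )
        path = directory / spec.filename
        out.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    return written


def contact_tables(bundle: LinkedRecordBundle):
    """Yield (name, frame) for the three tables holding timestamped contacts."""
    yield "calls", bundle.calls
    yield "ed", bundle.ed
    yield "admissions", bundle.admissions


def validate_bundle(bundle: LinkedRecordBundle) -> ValidationReport:
    """Structural validation; never raises — returns a report.

    Errors: duplicate person_ids, duplicate contact_ids, orphan foreign keys,
    end < start intervals, multiple death records per person, dates of birth
    after a person's first contact. Warnings: contacts recorded after a
    person's date of death.
    """
    report = ValidationReport()
    persons = bundle.persons
    dup = persons["person_id"][persons["person_id"].duplicated()]
    for pid in dup:
        report.errors.append(f"persons: duplicate person_id {pid!r}")
    known = set(persons["person_id"])

    for name, df in contact_tables(bundle):
        dup = df["contact_id"][df["contact_id"].duplicated()]
        for cid in dup:
            report.errors.append(f"{name}: duplicate contact_id {cid!r}")
        orphan = df.loc[~df["person_id"].isin(known), "contact_id"]
        for cid in orphan:
            report.errors.append(f"{name}: orphan person_id on contact {cid!r}")
        if len(df):
            bad = df["end_datetime"].notna() & (df["end_datetime"] < df["start_datetime"])
            for cid in df.loc[bad, "contact_id"]:
                report.errors.append(f"{name}: end before start on contact {cid!r}")

    deaths = bundle.deaths
    for pid in deaths["person_id"][deaths["person_id"].duplicated()]:
        report.errors.append(f"deaths: multiple death records for {pid!r}")
    for pid in deaths.loc[~deaths["person_id"].isin(known), "person_id"]:
        report.errors.append(f"deaths: orphan person_id {pid!r}")

    # Chronology checks need per-person contact extremes.
    starts = pd.concat(
        [df[["person_id", "start_datetime"]] for _, df in contact_tables(bundle)],
        ignore_index=True,
    )
    if len(starts):
        first = starts.groupby("person_id")["start_datetime"].min()
        last = starts.groupby("person_id")["start_datetime"].max()
        merged = persons.merge(
            first.rename("first_contact"), left_on="person_id", right_index=True
        )
        bad = merged["date_of_birth"] > merged["first_contact"]
        for pid in merged.loc[bad, "person_id"]:
            report.errors.append(f"persons: date_of_birth after first contact for {pid!r}")
        dmerged = deaths.merge(
            last.rename("last_contact"), left_on="person_id", right_index=True
        )
        late = dmerged["date_of_death"] < dmerged["last_contact"].dt.normalize()
        for pid in dmerged.loc[late, "person_id"]:
            report.warnings.append(
                f"deaths: contact recorded after date_of_death for {pid!r}"
            )
    return report
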