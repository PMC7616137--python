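"""Synthetic EHR data model: logical schema, backend dialects, versioned databases.

The logical schema is fixed and minimal: one patient-level table (one row per
patient) and two event-level tables keyed by ``patient_id``. Physical storage
is plain CSV; a :class:`SchemaDialect` maps logical table/column names onto the
physical names a particular backend uses and fixes how dates are written on
disk. All comparisons and query semantics operate on the logical view, which is
dialect-free: internally dates are calendar dates, codes are verbatim strings,
and the empty string on disk denotes null.

Databases are immutable snapshots identified by a ``version_tag``; a rebuild
produces a new snapshot and leaves prior versions queryable, which is what
makes extraction results version-dependent.
"""

from __future__ import annotations

import copy
import csv
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import IntegrityError, SchemaError

COLUMN_TYPES = ("patient_id", "date", "code", "category", "numeric", "boolean")
DATE_FORMATS = ("ISO8601", "DMY-slash")


@dataclass(frozen=True)
class TableSchema:
    """Logical structure of one table: its kind and its typed, ordered columns."""

    name: str
    kind: str  # "patient" | "event"
    columns: tuple[tuple[str, str], ...]  # (column name, column type)

    def __post_init__(self) -> None:
        if self.kind not in ("patient", "event"):
            raise SchemaError(f"table {self.name!r}: unknown kind {self.kind!r}")
        names = [c for c, _ in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError(f"table {self.name!r}: duplicate column names")
        for cname, ctype in self.columns:
            if ctype not in COLUMN_TYPES:
                raise SchemaError(f"table {self.name!r}: column {cname!r} has unknown type {ctype!r}")
        if sum(1 for _, t in self.columns if t == "patient_id") != 1:
            raise SchemaError(f"table {self.name!r}: exactly one patient_id column required")

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.columns)

    def column_type(self, name: str) -> str:
        for cname, ctype in self.columns:
            if cname == name:
                return ctype
        raise SchemaError(f"table {self.name!r} has no column {name!r}")


#: The fixed logical schema. Sufficient to express every toolkit behaviour;
#: extensible by passing a different schema mapping to the loaders.
LOGICAL_SCHEMA: dict[str, TableSchema] = {
    "patients": TableSchema(
        "patients",
        "patient",
        (
            ("patient_id", "patient_id"),
            ("date_of_birth", "date"),
            ("sex", "category"),
            ("date_of_death", "date"),
            ("practice_id", "category"),
        ),
    ),
    "clinical_events": TableSchema(
        "clinical_events",
        "event",
        (
            ("patient_id", "patient_id"),
            ("date", "date"),
            ("code", "code"),
            ("numeric_value", "numeric"),
        ),
    ),
    "medications": TableSchema(
        "medications",
        "event",
        (
            ("patient_id", "patient_id"),
            ("date", "date"),
            ("code", "code"),
        ),
    ),
}


def patient_table_name(schema: Mapping[str, TableSchema]) -> str:
    names = [t.name for t in schema.values() if t.kind == "patient"]
    if len(names) != 1:
        raise SchemaError("logical schema must contain exactly one patient table")
    return names[0]


@dataclass(frozen=True)
class SchemaDialect:
    """Maps logical names onto one backend's physical names and date encoding.

    The mapping must be total over the logical schema and injective per table,
    so two logical columns never collapse onto one physical column.
    """

    dialect_id: str
    table_map: Mapping[str, str]
    column_map: Mapping[tuple[str, str], str]
    date_format: str = "ISO8601"

    def __post_init__(self) -> None:
        if self.date_format not in DATE_FORMATS:
            raise SchemaError(f"dialect {self.dialect_id!r}: unknown date format {self.date_format!r}")

    def validate_against(self, schema: Mapping[str, TableSchema]) -> None:
        problems = []
        for tname, tschema in schema.items():
            if tname not in self.table_map:
                problems.append(f"no physical table for logical table {tname!r}")
                continue
            physical = []
            for cname in tschema.column_names:
                if (tname, cname) not in self.column_map:
                    problems.append(f"no physical column for {tname}.{cname}")
                else:
                    physical.append(self.column_map[(tname, cname)])
            if len(set(physical)) != len(physical):
                problems.append(f"dialect not injective on table {tname!r}")
        if problems:
            raise SchemaError(f"dialect {self.dialect_id!r}: " + "; ".join(problems))

    def physical_table(self, logical: str) -> str:
        return self.table_map[logical]

    def physical_column(self, table: str, column: str) -> str:
        return self.column_map[(table, column)]

    def format_date(self, value: dt.date | None) -> str:
        if value is None:
            return ""
        if self.date_format == "ISO8601":
            return value.isoformat()
        return f"{value.day:02d}/{value.month:02d}/{value.year:04d}"

    def parse_date(self, text: str) -> dt.date | None:
        if text == "":
            return None
        try:
            if self.date_format == "ISO8601":
                return dt.date.fromisoformat(text)
            day, month, year = text.split("/")
            return dt.date(int(year), int(month), int(day))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unparseable {self.date_format} date: {text!r}") from exc

    def to_json(self) -> str:
        columns: dict[str, dict[str, str]] = {}
        for (t, c), phys in self.column_map.items():
            columns.setdefault(t, {})[c] = phys
        payload = {
            "dialect_id": self.dialect_id,
            "table_map": dict(self.table_map),
            "column_map": columns,
            "date_format": self.date_format,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "SchemaDialect":
        payload = json.loads(text)
        column_map = {
            (t, c): phys
            for t, cols in payload["column_map"].items()
            for c, phys in cols.items()
        }
        return cls(
            dialect_id=payload["dialect_id"],
            table_map=payload["table_map"],
            column_map=column_map,
            date_format=payload.get("date_format", "ISO8601"),
        )


def identity_dialect(dialect_id: str = "iso", date_format: str = "ISO8601",
                     schema: Mapping[str, TableSchema] | None = None) -> SchemaDialect:
    """Dialect whose physical names equal the logical names."""
    schema = schema or LOGICAL_SCHEMA
    return SchemaDialect(
        dialect_id=dialect_id,
        table_map={t: t for t in schema},
        column_map={(t, c): c for t, ts in schema.items() for c in ts.column_names},
        date_format=date_format,
    )


ISO_DIALECT = identity_dialect()


@dataclass
class EHRDatabase:
    """One versioned snapshot of the logical database.

    Tables are pandas DataFrames in logical form: object dtype throughout, with
    Python ``datetime.date`` for dates, ``str`` for codes/categories, ``float``
    for numerics, ``bool`` for booleans and ``None`` for null. Row order is
    load order; the positional index is the stable tie-break ordinal.
    """

    version_tag: str
    dialect: SchemaDialect
    tables: dict[str, pd.DataFrame]
    schema: Mapping[str, TableSchema] = field(default_factory=lambda: LOGICAL_SCHEMA)

    @property
    def patient_table(self) -> str:
        return patient_table_name(self.schema)

    def patient_ids(self) -> list[str]:
        return list(self.tables[self.patient_table]["patient_id"])


@dataclass(frozen=True)
class Finding:
    kind: str
    table: str
    row: int | None
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def __str__(self) -> str:
        if self.ok:
            return "no violations"
        return "\n".join(f"[{f.kind}] {f.table} row {f.row}: {f.message}" for f in self.findings)


def _convert_cell(text: str, ctype: str, dialect: SchemaDialect, table: str, column: str):
    if ctype in ("code", "category", "patient_id"):
        return text if text != "" else None
    if text == "":
        return None
    if ctype == "date":
        return dialect.parse_date(text)
    if ctype == "numeric":
        return float(text)
    if ctype == "boolean":
        low = text.lower()
        if low in ("true", "t", "1"):
            return True
        if low in ("false", "f", "0"):
            return False
        raise ValueError(f"unparseable boolean in {table}.{column}: {text!r}")
    raise SchemaError(f"unknown column type {ctype!r}")


def _format_cell(value, ctype: str, dialect: SchemaDialect) -> str:
    if value is None:
        return ""
    if ctype == "date":
        return dialect.format_date(value)
    if ctype == "numeric":
        # repr round-trips floats exactly; integral floats keep a single ".0"
        return repr(float(value))
    if ctype == "boolean":
        return "true" if value else "false"
    return str(value)


def load_database(path: str | Path, dialect: SchemaDialect, version_tag: str | None = None,
                  schema: Mapping[str, TableSchema] | None = None) -> EHRDatabase:
    """Load a directory of physical CSV tables into a logical database.

    Codes and identifiers are read verbatim as strings — never as numbers —
    so long digit codes survive round-trips without float corruption.
    """
    schema = schema or LOGICAL_SCHEMA
    dialect.validate_against(schema)
    path = Path(path)
    missing: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    for tname, tschema in schema.items():
        fname = path / (dialect.physical_table(tname) + ".csv")
        if not fname.exists():
            missing.append(f"missing file for table {tname!r}: {fname.name}")
            continue
        with open(fname, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            colmap = {c: dialect.physical_column(tname, c) for c in tschema.column_names}
            absent = [f"{tname}.{c} (physical {p!r})" for c, p in colmap.items() if p not in header]
            if absent:
                missing.append("missing columns: " + ", ".join(absent))
                continue
            rows = []
            for raw in reader:
                rows.append({
                    c: _convert_cell(raw[colmap[c]], tschema.column_type(c), dialect, tname, c)
                    for c in tschema.column_names
                })
        tables[tname] = pd.DataFrame(rows, columns=list(tschema.column_names), dtype=object)
    if missing:
        raise SchemaError("; ".join(missing))
    db = EHRDatabase(
        version_tag=version_tag or path.name,
        dialect=dialect,
        tables=tables,
        schema=schema,
    )
    report = validate_database(db)
    if not report.ok:
        raise IntegrityError(str(report))
    return db


def write_database(db: EHRDatabase, path: str | Path, dialect: SchemaDialect | None = None) -> None:
    """Write the logical database to a directory under a dialect's physical names."""
    dialect = dialect or db.dialect
    dialect.validate_against(db.schema)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for tname, tschema in db.schema.items():
        fname = path / (dialect.physical_table(tname) + ".csv")
        with open(fname, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow([dialect.physical_column(tname, c) for c in tschema.column_names])
            for _, row in db.tables[tname].iterrows():
                writer.writerow([
                    _format_cell(row[c], tschema.column_type(c), dialect)
                    for c in tschema.column_names
                ])


def validate_database(db: EHRDatabase) -> ValidationReport:
    """Check every database invariant; violations become report findings, not exceptions."""
    findings: list[Finding] = []
    ptable = db.patient_table
    patients = db.tables[ptable]
    seen: dict[str, int] = {}
    for i, pid in enumerate(patients["patient_id"]):
        if pid is None:
            findings.append(Finding("null-patient-id", ptable, i, "patient_id is null"))
        elif pid in seen:
            findings.append(Finding("duplicate-patient", ptable, i,
                                    f"patient {pid!r} already defined at row {seen[pid]}"))
        else:
            seen[pid] = i
    known = set(seen)
    for tname, tschema in db.schema.items():
        if tschema.kind != "event":
            continue
        for i, pid in enumerate(db.tables[tname]["patient_id"]):
            if pid is None:
                findings.append(Finding("null-patient-id", tname, i, "patient_id is null"))
            elif pid not in known:
                findings.append(Finding("orphan-row", tname, i,
                                        f"patient {pid!r} not in patient table"))
    return ValidationReport(findings)


@dataclass(frozen=True)
class Insert:
    table: str
    row: Mapping[str, object]


@dataclass(frozen=True)
class Delete:
    table: str
    where: Mapping[str, object]


@dataclass(frozen=True)
class Edit:
    table: str
    where: Mapping[str, object]
    values: Mapping[str, object]


Update = Insert | Delete | Edit


def _matches(row: pd.Series, where: Mapping[str, object]) -> bool:
    return all(row[c] == v for c, v in where.items())


def rebuild_database(db: EHRDatabase, updates: Iterable[Update], new_version_tag: str) -> EHRDatabase:
    """Produce a new database version with the updates applied.

    The input snapshot is untouched, so earlier versions stay queryable.
    Deleting a patient cascades to their event rows (patients leave the
    database when they change practice). An update set that would violate any
    database invariant raises without partial application.
    """
    tables = {t: df.copy(deep=True) for t, df in db.tables.items()}
    for upd in updates:
        if upd.table not in db.schema:
            raise SchemaError(f"update references unknown table {upd.table!r}")
        tschema = db.schema[upd.table]
        cols = set(tschema.column_names)
        if isinstance(upd, Insert):
            unknown = set(upd.row) - cols
            if unknown:
                raise SchemaError(f"insert into {upd.table!r} references unknown columns {sorted(unknown)}")
            new_row = {c: copy.copy(upd.row.get(c)) for c in tschema.column_names}
            tables[upd.table] = pd.concat(
                [tables[upd.table], pd.DataFrame([new_row], dtype=object)],
                ignore_index=True,
            )
        elif isinstance(upd, (Delete, Edit)):
            unknown = set(upd.where) - cols
            if isinstance(upd, Edit):
                unknown |= set(upd.values) - cols
            if unknown:
                raise SchemaError(f"update on {upd.table!r} references unknown columns {sorted(unknown)}")
            df = tables[upd.table]
            mask = df.apply(lambda r: _matches(r, upd.where), axis=1) if len(df) else pd.Series([], dtype=bool)
            if isinstance(upd, Delete):
                if upd.table == db.patient_table:
                    gone = set(df.loc[mask, "patient_id"])
                    tables[upd.table] = df[~mask].reset_index(drop=True)
                    for tname, ts in db.schema.items():
                        if ts.kind == "event":
                            ev = tables[tname]
                            keep = ~ev["patient_id"].isin(gone) if len(ev) else pd.Series([], dtype=bool)
                            tables[tname] = ev[keep].reset_index(drop=True)
                else:
                    tables[upd.table] = df[~mask].reset_index(drop=True)
            else:
                for c, v in upd.values.items():
                    df.loc[mask, c] = [v] * int(mask.sum()) if mask.any() else df.loc[mask, c]
        else:  # pragma: no cover - union is closed
            raise SchemaError(f"unknown update type {type(upd).__name__}")
    new_db = EHRDatabase(
        version_tag=new_version_tag,
        dialect=db.dialect,
        tables=tables,
        schema=db.schema,
    )
    report = validate_database(new_db)
    if not report.ok:
        raise IntegrityError(f"rebuild would violate invariants: {report}")
    return new_db
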