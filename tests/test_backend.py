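import csv
import datetime as dt

import pandas as pd
import pytest

from trekit.backend import (
    Delete,
    Edit,
    ISO_DIALECT,
    Insert,
    LOGICAL_SCHEMA,
    SchemaDialect,
    TableSchema,
    identity_dialect,
    load_database,
    rebuild_database,
    validate_database,
    write_database,
)
from trekit.errors import IntegrityError, SchemaError
from trekit.fixtures import dmy_dialect, three_patient_database
from trekit.oracle import oracle_execute
from trekit.query import execute


def test_logical_schema_invariants():
    for ts in LOGICAL_SCHEMA.values():
        assert sum(1 for _, t in ts.columns if t == "patient_id") == 1
    with pytest.raises(SchemaError):
        TableSchema("bad", "event", (("a", "date"),))  # no patient_id
    with pytest.raises(SchemaError):
        TableSchema("bad", "event", (("patient_id", "patient_id"), ("patient_id", "date")))


def test_dialect_must_be_total_and_injective():
    d = identity_dialect()
    d.validate_against(LOGICAL_SCHEMA)
    incomplete = SchemaDialect("x", {"patients": "P"}, {("patients", "patient_id"): "pid"})
    with pytest.raises(SchemaError, match="no physical table"):
        incomplete.validate_against(LOGICAL_SCHEMA)
    collapsed = SchemaDialect(
        "y",
        {t: t for t in LOGICAL_SCHEMA},
        {(t, c): ("same" if t == "patients" else c)
         for t, ts in LOGICAL_SCHEMA.items() for c in ts.column_names},
    )
    with pytest.raises(SchemaError, match="injective"):
        collapsed.validate_against(LOGICAL_SCHEMA)


def test_dialect_json_round_trip():
    d = dmy_dialect()
    d2 = SchemaDialect.from_json(d.to_json())
    assert d2 == d


def test_load_empty_database(tmp_path):
    for tname, ts in LOGICAL_SCHEMA.items():
        with open(tmp_path / f"{tname}.csv", "w", newline="") as fh:
            csv.writer(fh).writerow(ts.column_names)
    db = load_database(tmp_path, ISO_DIALECT, version_tag="empty")
    assert db.patient_ids() == []
    assert all(len(df) == 0 for df in db.tables.values())


def test_load_counts_match_fixture_files(tmp_path, db3):
    write_database(db3, tmp_path, ISO_DIALECT)
    # oracle: count data lines in the raw files directly
    raw_counts = {}
    for tname in LOGICAL_SCHEMA:
        with open(tmp_path / f"{tname}.csv") as fh:
            raw_counts[tname] = sum(1 for _ in fh) - 1
    loaded = load_database(tmp_path, ISO_DIALECT, version_tag="v1")
    assert raw_counts == {"patients": 3, "clinical_events": 5, "medications": 2}
    for tname, n in raw_counts.items():
        assert len(loaded.tables[tname]) == n


def test_two_dialects_one_logical_view(tmp_path, db3):
    write_database(db3, tmp_path / "a", ISO_DIALECT)
    write_database(db3, tmp_path / "b", dmy_dialect())
    a = load_database(tmp_path / "a", ISO_DIALECT, version_tag="v1")
    b = load_database(tmp_path / "b", dmy_dialect(), version_tag="v1")
    for tname in LOGICAL_SCHEMA:
        pd.testing.assert_frame_equal(a.tables[tname], b.tables[tname])


def test_dialect_round_trip_write_load_write(tmp_path, db3):
    """Write under A, load, write under B, load: logical views identical."""
    write_database(db3, tmp_path / "a", ISO_DIALECT)
    mid = load_database(tmp_path / "a", ISO_DIALECT)
    write_database(mid, tmp_path / "b", dmy_dialect())
    final = load_database(tmp_path / "b", dmy_dialect())
    for tname in LOGICAL_SCHEMA:
        pd.testing.assert_frame_equal(db3.tables[tname], final.tables[tname])


def test_codes_survive_round_trip_as_strings(tmp_path, db3):
    """Long digit codes stay verbatim: no exponent notation, no trailing '.0'."""
    db = rebuild_database(db3, [
        Insert("clinical_events", {"patient_id": "p1", "date": dt.date(2021, 1, 1),
                                   "code": "1000230000000015", "numeric_value": None}),
    ], "v2")
    write_database(db, tmp_path, ISO_DIALECT)
    text = (tmp_path / "clinical_events.csv").read_text()
    assert "1000230000000015" in text
    assert "E+" not in text and "e+" not in text
    reloaded = load_database(tmp_path, ISO_DIALECT)
    codes = list(reloaded.tables["clinical_events"]["code"])
    assert "1000230000000015" in codes
    assert not any(isinstance(c, str) and c.endswith(".0") for c in codes if c)


def test_missing_table_and_column_errors(tmp_path, db3):
    write_database(db3, tmp_path, ISO_DIALECT)
    (tmp_path / "medications.csv").unlink()
    with pytest.raises(SchemaError, match="medications"):
        load_database(tmp_path, ISO_DIALECT)
    # restore table but drop a column
    with open(tmp_path / "medications.csv", "w", newline="") as fh:
        csv.writer(fh).writerow(["patient_id", "date"])
    with pytest.raises(SchemaError, match="medications.code"):
        load_database(tmp_path, ISO_DIALECT)


def test_duplicate_patient_rejected_on_load(tmp_path, db3):
    write_database(db3, tmp_path, ISO_DIALECT)
    with open(tmp_path / "patients.csv", "a", newline="") as fh:
        csv.writer(fh).writerow(["p1", "1980-06-15", "F", "", "pr01"])
    with pytest.raises(IntegrityError, match="duplicate-patient"):
        load_database(tmp_path, ISO_DIALECT)


def test_validate_reports_each_violation(db3):
    assert validate_database(db3).ok
    orphan = db3.tables["clinical_events"].copy()
    orphan.loc[len(orphan)] = {"patient_id": "ghost", "date": None, "code": None,
                               "numeric_value": None}
    db3.tables["clinical_events"] = orphan
    report = validate_database(db3)
    assert [f.kind for f in report.findings] == ["orphan-row"]
    dup = db3.tables["patients"].copy()
    dup.loc[len(dup)] = dup.loc[0]
    db3.tables["patients"] = dup
    kinds = [f.kind for f in validate_database(db3).findings]
    assert kinds.count("duplicate-patient") == 1


def test_rebuild_empty_update_set(db3):
    db2 = rebuild_database(db3, [], "v2")
    assert db2.version_tag == "v2"
    for t in LOGICAL_SCHEMA:
        pd.testing.assert_frame_equal(db2.tables[t], db3.tables[t])


def test_rebuild_patient_deletion_cascades(db3):
    db2 = rebuild_database(db3, [Delete("patients", {"patient_id": "p3"})], "v2")
    # hand recount: p3 owned clinical events rows 4 and 5, and 1 medication
    assert len(db2.tables["patients"]) == 2
    assert len(db2.tables["clinical_events"]) == 3
    assert len(db2.tables["medications"]) == 1
    assert "p3" not in set(db2.tables["clinical_events"]["patient_id"])
    # prior version untouched
    assert len(db3.tables["patients"]) == 3
    assert len(db3.tables["clinical_events"]) == 5


def test_rebuild_immutability_of_prior_version(db3, demo_dd):
    before = execute(demo_dd, db3).to_csv_text()
    rebuild_database(db3, [Delete("patients", {"patient_id": "p1"})], "v2")
    assert execute(demo_dd, db3).to_csv_text() == before


def test_rebuild_edit_changes_only_derived_rows(db3, demo_dd):
    """Editing one event's date only perturbs output rows derived from that patient."""
    old = execute(demo_dd, db3)
    db2 = rebuild_database(db3, [
        Edit("clinical_events", {"patient_id": "p1", "code": "111000"},
             {"date": dt.date(2020, 2, 15)}),
    ], "v2")
    new = execute(demo_dd, db2)
    old_rows = {r[0]: r for r in old.cells()}
    new_rows = {r[0]: r for r in new.cells()}
    assert set(old_rows) == set(new_rows)
    changed = [pid for pid in old_rows if old_rows[pid] != new_rows[pid]]
    assert changed == ["p1"]
    # and both engines agree after the edit
    assert oracle_execute(demo_dd, db2).to_csv_text() == new.to_csv_text()


def test_rebuild_rejects_invariant_violation_without_partial_application(db3):
    updates = [
        Insert("medications", {"patient_id": "p1", "date": dt.date(2022, 1, 1), "code": "M999"}),
        Insert("clinical_events", {"patient_id": "nobody", "date": None, "code": None,
                                   "numeric_value": None}),
    ]
    with pytest.raises(IntegrityError):
        rebuild_database(db3, updates, "v2")
    # first insert must not have leaked into the source version
    assert len(db3.tables["medications"]) == 2


def test_rebuild_unknown_table_or_column(db3):
    with pytest.raises(SchemaError, match="unknown table"):
        rebuild_database(db3, [Insert("nope", {"patient_id": "p9"})], "v2")
    with pytest.raises(SchemaError, match="unknown columns"):
        rebuild_database(db3, [Insert("medications", {"patient_id": "p1", "dose": 5})], "v2")
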