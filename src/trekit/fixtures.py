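"""Deterministic generators for every test input.

Everything here is synthetic: codes, terms and patients carry no clinical
meaning. The 3-patient database is small enough to trace every extraction by
hand, and its expected demo extraction is frozen below as a literal golden
file. Randomized databases and dataset definitions (for property tests and
oracle cross-checks) draw from a caller-supplied seeded generator only.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .backend import (
    ISO_DIALECT,
    LOGICAL_SCHEMA,
    EHRDatabase,
    SchemaDialect,
    write_database,
)
from .codelists import Codelist, CodingSystemRelease, Concept, write_codelist_csv, write_release_csv
from .query import (
    DatasetDefinition,
    EventFrame,
    PatientFrame,
    add_months,
    age_as_of,
    aggregate,
    clinical_events,
    constant,
    difference_in_days,
    medications,
    patients,
    serialize,
)

# --------------------------------------------------------------------------
# Hand-traceable 3-patient database
# --------------------------------------------------------------------------

_D = dt.date


def _frame(table: str, rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(LOGICAL_SCHEMA[table].column_names), dtype=object)


def three_patient_database(version_tag: str = "v1") -> EHRDatabase:
    """3 patients, 5 clinical events (2 in the demo codelist), 2 medications."""
    tables = {
        "patients": _frame("patients", [
            {"patient_id": "p1", "date_of_birth": _D(1980, 6, 15), "sex": "F",
             "date_of_death": None, "practice_id": "pr01"},
            {"patient_id": "p2", "date_of_birth": _D(2000, 5, 10), "sex": "M",
             "date_of_death": None, "practice_id": "pr01"},
            {"patient_id": "p3", "date_of_birth": _D(1950, 1, 1), "sex": "F",
             "date_of_death": _D(2021, 3, 1), "practice_id": "pr02"},
        ]),
        "clinical_events": _frame("clinical_events", [
            {"patient_id": "p1", "date": _D(2020, 1, 1), "code": "111000", "numeric_value": 10.0},
            {"patient_id": "p1", "date": _D(2020, 3, 1), "code": "222000", "numeric_value": 30.0},
            {"patient_id": "p2", "date": _D(2020, 1, 1), "code": "111000", "numeric_value": None},
            {"patient_id": "p3", "date": _D(2019, 12, 31), "code": "333000", "numeric_value": 5.5},
            {"patient_id": "p3", "date": _D(2020, 3, 1), "code": "444000", "numeric_value": 7.5},
        ]),
        "medications": _frame("medications", [
            {"patient_id": "p1", "date": _D(2020, 2, 1), "code": "M111"},
            {"patient_id": "p3", "date": _D(2021, 1, 15), "code": "M222"},
        ]),
    }
    return EHRDatabase(version_tag=version_tag, dialect=ISO_DIALECT, tables=tables)


def dmy_dialect() -> SchemaDialect:
    """A second backend: renamed physical tables/columns, day-first slash dates."""
    return SchemaDialect(
        dialect_id="legacy-dmy",
        table_map={"patients": "Patient", "clinical_events": "CodedEvent",
                   "medications": "MedicationIssue"},
        column_map={
            ("patients", "patient_id"): "Patient_ID",
            ("patients", "date_of_birth"): "DateOfBirth",
            ("patients", "sex"): "Sex",
            ("patients", "date_of_death"): "DateOfDeath",
            ("patients", "practice_id"): "PracticeCode",
            ("clinical_events", "patient_id"): "Patient_ID",
            ("clinical_events", "date"): "EventDate",
            ("clinical_events", "code"): "EventCode",
            ("clinical_events", "numeric_value"): "Value1",
            ("medications", "patient_id"): "Patient_ID",
            ("medications", "date"): "IssueDate",
            ("medications", "code"): "DrugCode",
        },
        date_format="DMY-slash",
    )


def demo_codelist() -> Codelist:
    return Codelist(
        codelist_id="demo-concept",
        coding_system="generic",
        system_version="r1",
        entries=(("111000", "demo concept, primary form"),),
    )


def demo_definition() -> DatasetDefinition:
    """The bundled demo dataset definition, hand-traced against the 3-patient fixture."""
    cl = demo_codelist()
    matching = clinical_events.where(clinical_events.code.is_in(cl))
    first_match = matching.sort_by(matching.date).first_for_patient()
    return DatasetDefinition(
        population=matching.exists_for_patient(),
        variables={
            "age": age_as_of(patients.date_of_birth, _D(2023, 1, 1)),
            "sex": patients.sex,
            "n_events": matching.count_for_patient(),
            "first_match_date": first_match.date,
            "mean_value": aggregate(matching, "mean", "numeric_value"),
            "on_med": medications.exists_for_patient(),
        },
    )


#: Golden expected output of demo_definition() on three_patient_database(),
#: traced by hand: p1 and p2 have a code-111000 event (p3 does not); p1's
#: matching event is 2020-01-01 with value 10.0; p2's has a null value; only
#: p1 has a medication row.
EXPECTED_DEMO_EXTRACTION = (
    "patient_id,age,sex,n_events,first_match_date,mean_value,on_med\n"
    "p1,42,F,1,2020-01-01,10.0,true\n"
    "p2,22,M,1,2020-01-01,,false\n"
)


# --------------------------------------------------------------------------
# Codelist / release fixtures
# --------------------------------------------------------------------------

def clean_codelist() -> Codelist:
    """Four codes, all active and unchanged in release_base()."""
    return Codelist(
        codelist_id="cond-x",
        coding_system="generic",
        system_version="2023-01",
        entries=(
            ("111000", "condition x, type 1"),
            ("222000", "condition x, type 2"),
            ("333000", "condition x, unspecified"),
            ("60234000", "condition x with complication"),
        ),
    )


def corrupted_codelist() -> Codelist:
    """Spreadsheet-damaged codelist: exponent notation and a float-cast suffix."""
    return Codelist(
        codelist_id="cond-x-corrupt",
        coding_system="generic",
        system_version="2023-01",
        entries=(
            ("1.00023E+15", "condition x, type 1"),
            ("123456789.0", "condition x, type 2"),
            ("333000", "condition x, unspecified"),
        ),
    )


def clean_icd10_codelist() -> Codelist:
    """Alphanumeric codes: nothing for the corruption detector to flag."""
    return Codelist(
        codelist_id="cond-y-icd10",
        coding_system="ICD10",
        system_version="2023",
        entries=(("I10", "essential hypertension"), ("I11.9", "hypertensive heart disease"),
                 ("J45", "asthma")),
    )


def release_base() -> CodingSystemRelease:
    return CodingSystemRelease(
        system="generic",
        release_tag="2023-01",
        concepts={
            "111000": Concept("condition x, type 1", "active"),
            "222000": Concept("condition x, type 2", "active"),
            "333000": Concept("condition x, unspecified", "active"),
            "60234000": Concept("condition x with complication", "active"),
        },
    )


def release_updated() -> CodingSystemRelease:
    """One retirement-with-replacement among the four codes (rot score 0.25)."""
    return CodingSystemRelease(
        system="generic",
        release_tag="2024-01",
        concepts={
            "111000": Concept("condition x, type 1", "active"),
            "222000": Concept("condition x, type 2", "active"),
            "333000": Concept("condition x, unspecified", "retired", replaced_by="555000"),
            "555000": Concept("condition x, not otherwise specified", "active"),
            "60234000": Concept("condition x with complication", "active"),
        },
    )


def search_release() -> CodingSystemRelease:
    """Six terms, two containing 'hypertension', for search fixtures."""
    return CodingSystemRelease(
        system="generic",
        release_tag="2023-06",
        concepts={
            "100001": Concept("essential hypertension", "active"),
            "100002": Concept("secondary hypertension", "active"),
            "100003": Concept("hypotension", "active"),
            "100004": Concept("type 2 diabetes", "active"),
            "100005": Concept("asthma", "active"),
            "100006": Concept("migraine", "active"),
        },
    )


# --------------------------------------------------------------------------
# Project pipeline fixtures
# --------------------------------------------------------------------------

def chain_project_yaml() -> str:
    return """\
version: "1.0"
actions:
  generate_dataset:
    run: extract --definition analysis/definition.json --db database --output output/dataset.csv
    environment: trekit:v1
    outputs:
      highly_sensitive:
        - output/dataset.csv
  summarise:
    run: exec-script analysis/summarise.py
    environment: python:v1
    needs: [generate_dataset]
    outputs:
      moderately_sensitive:
        - output/summary.csv
  plot:
    run: exec-script analysis/plot.py
    environment: python:v1
    needs: [summarise]
    outputs:
      moderately_sensitive:
        - output/figure.csv
"""


def diamond_project_yaml() -> str:
    """Six actions: extract fans out to two branches that re-join and finish."""
    return """\
version: "1.0"
actions:
  extract_cohort:
    run: extract --definition analysis/definition.json --db database --output output/dataset.csv
    environment: trekit:v1
    outputs:
      highly_sensitive:
        - output/dataset.csv
  branch_counts:
    run: exec-script analysis/counts.py
    environment: python:v1
    needs: [extract_cohort]
    outputs:
      moderately_sensitive:
        - output/counts.csv
  branch_values:
    run: exec-script analysis/values.py
    environment: python:v1
    needs: [extract_cohort]
    outputs:
      moderately_sensitive:
        - output/values.csv
  join_tables:
    run: exec-script analysis/join.py
    environment: python:v1
    needs: [branch_counts, branch_values]
    outputs:
      moderately_sensitive:
        - output/joined.csv
  report:
    run: exec-script analysis/report.py
    environment: python:v2
    needs: [join_tables]
    outputs:
      moderately_sensitive:
        - output/report.csv
  audit_note:
    run: exec-script analysis/note.py
    environment: python:v1
    needs: [extract_cohort]
    outputs:
      moderately_sensitive:
        - output/note.csv
"""


def cyclic_project_yaml() -> str:
    return """\
version: "1.0"
actions:
  alpha:
    run: exec-script a.py
    environment: python:v1
    needs: [beta]
    outputs:
      moderately_sensitive:
        - out/a.csv
  beta:
    run: exec-script b.py
    environment: python:v1
    needs: [alpha]
    outputs:
      moderately_sensitive:
        - out/b.csv
"""


# --------------------------------------------------------------------------
# Randomized instances for property tests
# --------------------------------------------------------------------------

CODE_POOL = ("111000", "222000", "333000", "444000", "60234000")
MED_POOL = ("M111", "M222", "M333")


def random_database(rng: np.random.Generator, n_patients: int = 20,
                    version_tag: str = "rand") -> EHRDatabase:
    """Small random database with deliberate date ties, nulls and orphan-free events."""
    base = _D(2020, 1, 1)
    prows, ce_rows, med_rows = [], [], []
    for i in range(n_patients):
        pid = f"p{i + 1:03d}"
        dob = _D(1940, 1, 1) + dt.timedelta(days=int(rng.integers(0, 25000)))
        prows.append({
            "patient_id": pid,
            "date_of_birth": dob,
            "sex": ("F", "M")[int(rng.integers(0, 2))],
            "date_of_death": (base + dt.timedelta(days=int(rng.integers(0, 700))))
                             if rng.integers(0, 10) == 0 else None,
            "practice_id": f"pr{int(rng.integers(1, 4))}",
        })
        for _ in range(int(rng.integers(0, 5))):
            ce_rows.append({
                "patient_id": pid,
                # narrow date range so sort ties happen often
                "date": None if rng.integers(0, 20) == 0
                        else base + dt.timedelta(days=int(rng.integers(0, 60))),
                "code": None if rng.integers(0, 20) == 0
                        else CODE_POOL[int(rng.integers(0, len(CODE_POOL)))],
                "numeric_value": None if rng.integers(0, 5) == 0
                                 else int(rng.integers(0, 200)) / 2.0,
            })
        for _ in range(int(rng.integers(0, 3))):
            med_rows.append({
                "patient_id": pid,
                "date": base + dt.timedelta(days=int(rng.integers(0, 60))),
                "code": MED_POOL[int(rng.integers(0, len(MED_POOL)))],
            })
    tables = {
        "patients": _frame("patients", prows),
        "clinical_events": _frame("clinical_events", ce_rows),
        "medications": _frame("medications", med_rows),
    }
    return EHRDatabase(version_tag=version_tag, dialect=ISO_DIALECT, tables=tables)


def _random_codelist(rng: np.random.Generator) -> tuple[str, ...]:
    k = int(rng.integers(1, len(CODE_POOL)))
    idx = rng.permutation(len(CODE_POOL))[:k]
    return tuple(sorted(CODE_POOL[i] for i in idx))


def random_definition(rng: np.random.Generator) -> DatasetDefinition:
    """A random but well-formed definition exercising filters, aggregates,
    first/last picks, date arithmetic and three-valued logic."""
    cl = _random_codelist(rng)
    filtered = clinical_events.where(clinical_events.code.is_in(cl))
    ref = _D(2021, 1, 1)

    population_choices = [
        lambda: filtered.exists_for_patient(),
        lambda: filtered.count_for_patient() >= int(rng.integers(1, 3)),
        lambda: (age_as_of(patients.date_of_birth, ref) >= int(rng.integers(10, 60)))
                & clinical_events.exists_for_patient(),
        lambda: medications.exists_for_patient() | filtered.exists_for_patient(),
    ]
    population = population_choices[int(rng.integers(0, len(population_choices)))]()

    sorted_f = filtered.sort_by(filtered.date)
    sorted_all = clinical_events.sort_by(clinical_events.date, clinical_events.code)
    variable_builders = {
        "age": lambda: age_as_of(patients.date_of_birth, ref),
        "sex": lambda: patients.sex,
        "dead": lambda: ~patients.date_of_death.is_null(),
        "n_match": lambda: filtered.count_for_patient(),
        "any_med": lambda: medications.exists_for_patient(),
        "first_date": lambda: sorted_f.first_for_patient().date,
        "last_code": lambda: sorted_all.last_for_patient().code,
        "first_value": lambda: sorted_all.first_for_patient().numeric_value,
        "max_value": lambda: aggregate(filtered, "max", "numeric_value"),
        "mean_value": lambda: aggregate(clinical_events, "mean", "numeric_value"),
        "sum_value": lambda: aggregate(filtered, "sum", "numeric_value"),
        "earliest": lambda: aggregate(clinical_events, "min", "date"),
        "days_to_ref": lambda: difference_in_days(
            constant(ref), sorted_f.first_for_patient().date),
        "anniversary": lambda: add_months(patients.date_of_birth, int(rng.integers(1, 14))),
        "high_load": lambda: clinical_events.count_for_patient() >= int(rng.integers(2, 5)),
    }
    names = sorted(variable_builders)
    k = int(rng.integers(2, 6))
    picked = [names[i] for i in rng.permutation(len(names))[:k]]
    variables = {name: variable_builders[name]() for name in sorted(picked)}
    return DatasetDefinition(population=population, variables=variables)


# --------------------------------------------------------------------------
# Fixture suite on disk
# --------------------------------------------------------------------------

@dataclass
class FixtureSuite:
    root: Path
    seed: int
    db_iso: Path
    db_dmy: Path
    db_random: Path
    definition: Path
    expected_extraction: Path
    codelist_clean: Path
    codelist_corrupted: Path
    release_base: Path
    release_updated: Path
    project_chain: Path
    project_diamond: Path
    project_cyclic: Path


def make_suite(seed: int, out_dir: str | Path) -> FixtureSuite:
    """Write every fixture to a directory; identical bytes for identical seeds."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    db = three_patient_database()
    db_iso = root / "db-iso"
    db_dmy = root / "db-dmy"
    write_database(db, db_iso, ISO_DIALECT)
    write_database(db, db_dmy, dmy_dialect())
    rng = np.random.default_rng(seed)
    db_random = root / "db-random"
    write_database(random_database(rng, n_patients=20), db_random, ISO_DIALECT)

    definition = root / "demo_definition.json"
    definition.write_text(serialize(demo_definition()))
    expected = root / "expected_extraction.csv"
    expected.write_text(EXPECTED_DEMO_EXTRACTION)

    (root / "dialect-dmy.json").write_text(dmy_dialect().to_json())

    cl_clean = root / "codelist_clean.csv"
    cl_bad = root / "codelist_corrupted.csv"
    write_codelist_csv(clean_codelist(), cl_clean)
    write_codelist_csv(corrupted_codelist(), cl_bad)
    rel_base = root / "release_base.csv"
    rel_new = root / "release_updated.csv"
    write_release_csv(release_base(), rel_base)
    write_release_csv(release_updated(), rel_new)

    p_chain = root / "project_chain.yaml"
    p_diamond = root / "project_diamond.yaml"
    p_cyclic = root / "project_cyclic.yaml"
    p_chain.write_text(chain_project_yaml())
    p_diamond.write_text(diamond_project_yaml())
    p_cyclic.write_text(cyclic_project_yaml())

    return FixtureSuite(
        root=root, seed=seed, db_iso=db_iso, db_dmy=db_dmy, db_random=db_random,
        definition=definition, expected_extraction=expected,
        codelist_clean=cl_clean, codelist_corrupted=cl_bad,
        release_base=rel_base, release_updated=rel_new,
        project_chain=p_chain, project_diamond=p_diamond, project_cyclic=p_cyclic,
    )


def suite_digest(root: str | Path) -> str:
    """Single digest over every fixture file, for determinism checks."""
    root = Path(root)
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(root).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()
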