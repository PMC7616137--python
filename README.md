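# trekit

A desk-scale toolkit for **reproducible research on electronic health
records**, modelled on how trusted research environments (TREs) keep analyses
auditable without ever exposing row-level patient data. It is aimed at
epidemiologists, health-data scientists and research-software engineers who
want to prototype, teach or test TRE-style workflows on synthetic data.

The toolkit covers the full path from database to released result:

* **Query language** — a lazy, serializable expression algebra over a patient
  table and event tables. A *dataset definition* pairs a boolean population
  predicate with named patient-level variables and compiles to a
  one-row-per-patient analytic dataset. The same definition runs unchanged
  against any *schema dialect* (renamed physical columns, different date
  encodings), and a definition's canonical JSON form hashes identically
  however it was built. Semantics: Kleene three-valued logic (population
  requires literal `True`), aggregation as the only event→patient transition
  (`exists=False`/`count=0` for empty groups), first/last selection with
  null-smallest ordering and load-order tie-breaks, truncating year
  differences and month-end-clamping month addition.
* **Dummy data** — seeded, structure-matching databases generated from the
  definition alone (never from real data), with rejection sampling calibrated
  to a target population fraction and self-verifying deposit bundles.
* **Codelists** — versioned code/term lists with recorded search strategies,
  *rot* detection against coding-system releases (score = fraction of codes no
  longer active-unchanged), policy-driven updates with provenance, and
  detection of spreadsheet float-cast corruption of long integer codes.
* **Pipelines** — YAML-declared action DAGs with pinned environments,
  content-hash caching, undeclared-input/output refusal, and an append-only,
  hash-chained job log in which any tampering is detected.
* **Disclosure control** — small-cell suppression (with secondary suppression
  and a linear-recovery guard), base-5 rounding, and a release gate that
  refuses row-level, undeclared or stale files and manifests what leaves.

A per-patient reference interpreter (`oracle_execute`) re-implements the query
semantics independently of the production executor; the two are compared
cell-for-cell on randomized instances throughout the test suite.

## Worked example

```python
import datetime as dt
from trekit import (clinical_events, medications, patients,
                    age_as_of, aggregate, execute, serialize, DatasetDefinition)
from trekit.fixtures import three_patient_database, demo_codelist

matching = clinical_events.where(clinical_events.code.is_in(demo_codelist()))
first = matching.sort_by(matching.date).first_for_patient()

dd = DatasetDefinition(
    population=matching.exists_for_patient(),
    variables={
        "age": age_as_of(patients.date_of_birth, dt.date(2023, 1, 1)),
        "sex": patients.sex,
        "n_events": matching.count_for_patient(),
        "first_match_date": first.date,
        "mean_value": aggregate(matching, "mean", "numeric_value"),
        "on_med": medications.exists_for_patient(),
    },
)
print(execute(dd, three_patient_database()).to_csv_text())
```

prints

```
patient_id,age,sex,n_events,first_match_date,mean_value,on_med
p1,42,F,1,2020-01-01,10.0,true
p2,22,M,1,2020-01-01,,false
```

Two of the three fixture patients have an event coded `111000` and so enter
the population. `age` is whole years at 2023-01-01 (p1, born 1980-06-15, is
42 — the birthday has not passed). `mean_value` is empty for p2 because their
only matching event has a null measurement and an all-null group aggregates to
null; `on_med` is `false` for p2 because empty groups exist-aggregate to
false, never null. Deleting a patient with `rebuild_database` leaves this
version's output byte-identical — extractions are reproducible per database
version.

The same workflow is available from the shell:

```bash
trekit fixtures make --seed 7 --out fx
trekit extract --definition fx/demo_definition.json --db fx/db-iso --out dataset.csv
trekit dummy-data --definition fx/demo_definition.json --n 100 --seed 7 --out bundle
trekit codelist check-rot --codelist fx/codelist_clean.csv --release fx/release_updated.csv
trekit run --workspace myproject        # executes project.yaml, logs every action
trekit log verify --workspace myproject
trekit release --workspace myproject output/summary.csv
```

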