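"""Seeded dummy databases with the same structure as a real extraction.

Dummy data lets all study code be developed and tested without ever touching
real records. It is *not* synthetic data: the generator takes no real database
argument, so independence from real data holds by construction, and no
statistical fidelity to real marginal or joint distributions is attempted.
What is guaranteed is structure — a dummy extraction has exactly the columns
and dtypes a real one would — plus seeded byte-reproducibility and an
approximate target fraction of patients satisfying the population predicate
(per-patient rejection sampling against the declared value domains, padding
with non-qualifying patients when the retry cap is hit).

All randomness flows through one integer-seeded generator drawn in a fixed
order, so the same (definition, spec) pair reproduces the same files anywhere.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .backend import ISO_DIALECT, EHRDatabase, LOGICAL_SCHEMA, write_database
from .errors import GenerationError
from .oracle import _eval_for_patient
from .query import (
    AnalyticDataset,
    ColumnRef,
    DatasetDefinition,
    InCodes,
    definition_digest,
    deserialize,
    execute,
    serialize,
    _walk,
)

DEFAULT_DATE_RANGE = (dt.date(1920, 1, 1), dt.date(2024, 12, 31))


@dataclass(frozen=True)
class ValueDomains:
    """Per-column generator domains; defaults exercise both match and non-match paths."""

    date_range: tuple[dt.date, dt.date] = DEFAULT_DATE_RANGE
    numeric_range: tuple[float, float] = (0.0, 100.0)
    category_domains: Mapping[str, tuple[str, ...]] = field(default_factory=lambda: {
        "sex": ("F", "M"),
        "practice_id": ("pr01", "pr02", "pr03", "pr04", "pr05"),
    })
    code_pools: Mapping[str, tuple[str, ...]] | None = None  # event table -> pool
    mean_events_per_table: float = 2.0
    max_retries: int = 1000


@dataclass(frozen=True)
class DummySpec:
    n_patients: int
    seed: int
    target_population_fraction: float = 0.5
    value_domains: ValueDomains = field(default_factory=ValueDomains)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise GenerationError("n_patients must be >= 1")
        if not (0.0 < self.target_population_fraction <= 1.0):
            raise GenerationError("target_population_fraction must be in (0, 1]")


def _referenced_codes(dd: DatasetDefinition) -> dict[str, set[str]]:
    """Codes each event table's membership tests reference in the definition."""
    pools: dict[str, set[str]] = {}
    roots = [dd.population.node] + [s.node for s in dd.variables.values()]
    for root in roots:
        for node in _walk(root):
            if isinstance(node, InCodes):
                tables = {n.table for n in _walk(node.arg) if isinstance(n, ColumnRef)}
                for t in tables:
                    pools.setdefault(t, set()).update(node.codes)
    return pools


def _code_pool(dd: DatasetDefinition, table: str, domains: ValueDomains,
               rng: np.random.Generator) -> tuple[str, ...]:
    if domains.code_pools and table in domains.code_pools:
        return tuple(domains.code_pools[table])
    referenced = sorted(_referenced_codes(dd).get(table, set()))
    if not referenced:
        referenced = [f"{d}00000" for d in range(100, 105)]
    # decoys: ~20% extra codes outside every codelist, so non-matches occur
    n_decoys = max(1, round(0.2 * len(referenced)))
    decoys = []
    taken = set(referenced)
    while len(decoys) < n_decoys:
        cand = "9" + "".join(str(rng.integers(0, 10)) for _ in range(7))
        if cand not in taken:
            taken.add(cand)
            decoys.append(cand)
    return tuple(referenced + decoys)


def _random_date(rng: np.random.Generator, lo: dt.date, hi: dt.date) -> dt.date:
    return dt.date.fromordinal(int(rng.integers(lo.toordinal(), hi.toordinal() + 1)))


def _candidate_patient(pid: str, rng: np.random.Generator, domains: ValueDomains,
                       code_pools: Mapping[str, tuple[str, ...]]):
    lo, hi = domains.date_range
    dob = _random_date(rng, lo, hi)
    sex = domains.category_domains["sex"][int(rng.integers(0, len(domains.category_domains["sex"])))]
    dod = _random_date(rng, dob, hi) if rng.integers(0, 10) == 0 else None
    practices = domains.category_domains["practice_id"]
    prow = {
        "patient_id": pid,
        "date_of_birth": dob,
        "sex": sex,
        "date_of_death": dod,
        "practice_id": practices[int(rng.integers(0, len(practices)))],
    }
    events: dict[str, list[dict]] = {}
    n_lo, n_hi = domains.numeric_range
    steps = max(1, int(round((n_hi - n_lo) * 10)))
    for table, ts in LOGICAL_SCHEMA.items():
        if ts.kind != "event":
            continue
        rows = []
        for _ in range(int(rng.poisson(domains.mean_events_per_table))):
            row: dict = {"patient_id": pid}
            for cname in ts.column_names:
                if cname == "patient_id":
                    continue
                ctype = ts.column_type(cname)
                if ctype == "date":
                    row[cname] = None if rng.integers(0, 20) == 0 else _random_date(rng, lo, hi)
                elif ctype == "code":
                    pool = code_pools[table]
                    row[cname] = None if rng.integers(0, 20) == 0 else pool[int(rng.integers(0, len(pool)))]
                elif ctype == "numeric":
                    row[cname] = None if rng.integers(0, 5) == 0 else n_lo + int(rng.integers(0, steps + 1)) / 10.0
                elif ctype == "category":
                    dom = domains.category_domains.get(cname, ("A", "B"))
                    row[cname] = dom[int(rng.integers(0, len(dom)))]
                else:
                    row[cname] = bool(rng.integers(0, 2))
            rows.append(row)
        events[table] = rows
    return prow, events


def generate_dummy_database(dd: DatasetDefinition, spec: DummySpec) -> EHRDatabase:
    """Generate a seeded dummy database whose extraction structure matches ``dd``.

    For each patient a qualifying/non-qualifying status is drawn at the target
    fraction, then candidates are rejection-sampled against the population
    predicate until the status is met or the retry cap is reached (padding with
    a non-qualifying patient). If qualifying patients were requested but none
    could ever be generated, the population is unreachable under the declared
    value domains and a :class:`GenerationError` advises widening them.
    """
    rng = np.random.default_rng(spec.seed)
    domains = spec.value_domains
    code_pools = {t: _code_pool(dd, t, domains, rng)
                  for t, ts in LOGICAL_SCHEMA.items() if ts.kind == "event"}
    patients: list[dict] = []
    events: dict[str, list[dict]] = {t: [] for t, ts in LOGICAL_SCHEMA.items() if ts.kind == "event"}
    wanted_true = 0
    achieved_true = 0
    for i in range(spec.n_patients):
        pid = f"p{i + 1:05d}"
        want = rng.random() < spec.target_population_fraction
        wanted_true += int(want)
        chosen = None
        for _ in range(domains.max_retries):
            prow, ev = _candidate_patient(pid, rng, domains, code_pools)
            qualifies = _eval_for_patient(
                dd.population.node, prow,
                {t: list(enumerate(rows)) for t, rows in ev.items()}) is True
            if qualifies == want:
                chosen = (prow, ev, qualifies)
                break
            if not want and chosen is None:
                pass
        if chosen is None:
            # retry cap hit: pad with a non-qualifying patient
            for _ in range(domains.max_retries):
                prow, ev = _candidate_patient(pid, rng, domains, code_pools)
                qualifies = _eval_for_patient(
                    dd.population.node, prow,
                    {t: list(enumerate(rows)) for t, rows in ev.items()}) is True
                if not qualifies:
                    chosen = (prow, ev, False)
                    break
        if chosen is None:
            raise GenerationError(
                "could not generate a patient with the requested population status; "
                "widen the value domains or raise max_retries")
        prow, ev, qualifies = chosen
        achieved_true += int(qualifies)
        patients.append(prow)
        for t, rows in ev.items():
            events[t].extend(rows)
    if wanted_true > 0 and achieved_true == 0:
        raise GenerationError(
            "population predicate is unreachable under the declared value domains; "
            "widen date/numeric ranges or the code pools")
    tables = {"patients": pd.DataFrame(patients,
                                       columns=list(LOGICAL_SCHEMA["patients"].column_names),
                                       dtype=object)}
    for t, rows in events.items():
        tables[t] = pd.DataFrame(rows, columns=list(LOGICAL_SCHEMA[t].column_names), dtype=object)
    return EHRDatabase(version_tag=f"dummy-seed{spec.seed}", dialect=ISO_DIALECT, tables=tables)


# --------------------------------------------------------------------------
# Structural conformance
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConformanceFinding:
    kind: str  # "columns" | "dtype" | "value"
    message: str


@dataclass
class ConformanceReport:
    findings: list[ConformanceFinding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings


_PYTYPES = {
    "date": (dt.date,),
    "boolean": (bool,),
    "numeric": (int, float),
    "code": (str,),
    "category": (str,),
}


def conformance_check(dataset: AnalyticDataset, dd: DatasetDefinition) -> ConformanceReport:
    """Verify a dataset has exactly the columns, order and dtypes ``dd`` emits."""
    findings: list[ConformanceFinding] = []
    expected_cols = dd.output_columns()
    if dataset.columns != expected_cols:
        findings.append(ConformanceFinding(
            "columns", f"columns {dataset.columns} != expected {expected_cols}"))
    expected_dtypes = dd.output_dtypes()
    for col in dataset.columns:
        if col not in expected_dtypes:
            continue  # already reported as a column mismatch
        want = expected_dtypes[col]
        if dataset.dtypes.get(col) != want:
            findings.append(ConformanceFinding(
                "dtype", f"column {col!r}: dtype {dataset.dtypes.get(col)!r} != {want!r}"))
            continue
        bad = [v for v in dataset.frame[col]
               if v is not None and not isinstance(v, _PYTYPES[want])
               or isinstance(v, bool) and want == "numeric"]
        if bad:
            findings.append(ConformanceFinding(
                "value", f"column {col!r}: {len(bad)} cell(s) are not {want} "
                         f"(first offender: {bad[0]!r})"))
    return ConformanceReport(findings)


def load_dataset_csv(path: str | Path, dd: DatasetDefinition) -> AnalyticDataset:
    """Read a dataset CSV back, parsing cells per the definition's dtypes.

    Cells that fail to parse are kept as raw strings so conformance_check can
    flag them as value findings rather than this loader raising.
    """
    import csv as _csv

    dtypes = dd.output_dtypes()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = _csv.reader(fh)
        rows = list(reader)
    header = rows[0] if rows else []
    records = []
    for raw in rows[1:]:
        rec = {}
        for col, cell in zip(header, raw):
            want = dtypes.get(col)
            if cell == "":
                rec[col] = None
            elif want == "date":
                try:
                    rec[col] = dt.date.fromisoformat(cell)
                except ValueError:
                    rec[col] = cell
            elif want == "numeric":
                try:
                    rec[col] = int(cell)
                except ValueError:
                    try:
                        rec[col] = float(cell)
                    except ValueError:
                        rec[col] = cell
            elif want == "boolean":
                rec[col] = True if cell == "true" else False if cell == "false" else cell
            else:
                rec[col] = cell
        records.append(rec)
    frame = pd.DataFrame(records, columns=header, dtype=object)
    return AnalyticDataset(frame=frame, dtypes={c: dtypes.get(c, "category") for c in header})


# --------------------------------------------------------------------------
# Self-verifying bundles
# --------------------------------------------------------------------------

def _sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def deposit_bundle(dd: DatasetDefinition, spec: DummySpec, out_dir: str | Path) -> dict:
    """Write dummy database + extracted dummy dataset + manifest to a directory.

    The manifest records the seed, the definition digest and a SHA-256 per
    file; re-running deposit with the same inputs reproduces every byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    db = generate_dummy_database(dd, spec)
    write_database(db, out_dir / "database", ISO_DIALECT)
    (out_dir / "definition.json").write_text(serialize(dd))
    execute(dd, db).to_csv(out_dir / "dataset.csv")
    files = sorted(p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": spec.seed,
        "n_patients": spec.n_patients,
        "target_population_fraction": spec.target_population_fraction,
        "definition_digest": definition_digest(dd),
        "files": {p.relative_to(out_dir).as_posix(): _sha256_bytes(p.read_bytes())
                  for p in files},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return manifest


def verify_bundle(out_dir: str | Path) -> dict:
    """Check every file against the manifest; raises naming the first mismatch."""
    from .errors import IntegrityError

    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    for relpath, digest in sorted(manifest["files"].items()):
        f = out_dir / relpath
        if not f.is_file():
            raise IntegrityError(f"bundle file missing: {relpath}")
        if _sha256_bytes(f.read_bytes()) != digest:
            raise IntegrityError(f"bundle file modified: {relpath}")
    dd = deserialize((out_dir / "definition.json").read_text())
    if definition_digest(dd) != manifest["definition_digest"]:
        raise IntegrityError("bundle definition digest mismatch")
    return manifest


def reproduce_bundle(out_dir: str | Path, target_dir: str | Path) -> dict:
    """Regenerate a bundle from its manifest alone; byte-identical by construction."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    dd = deserialize((out_dir / "definition.json").read_text())
    spec = DummySpec(
        n_patients=manifest["n_patients"],
        seed=manifest["seed"],
        target_population_fraction=manifest["target_population_fraction"],
    )
    return deposit_bundle(dd, spec, target_dir)
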