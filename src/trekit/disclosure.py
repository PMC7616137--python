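"""Automated statistical disclosure control for outputs leaving the workspace.

Aggregate tables are gated by two conventional rules before release:

* **small-cell suppression** — any count in ``(0, threshold]`` is replaced by a
  redaction token; *secondary* suppression then protects redacted cells from
  subtraction recovery: whenever a row or column group with a visible total
  has exactly one redacted cell, the next-smallest cell in that group is also
  redacted, iterated to a fixpoint, followed by a linear-algebra guard that
  keeps suppressing until no redacted value is uniquely determined by the
  remaining cells and totals;
* **rounding** — counts are rounded to the nearest multiple of a base, with
  midpoints rounding up.

:func:`release` is the only way to mark files as released: it refuses
row-level (``highly_sensitive``) or undeclared outputs, refuses files whose
bytes changed since their action ran, re-checks tabular content (no
``patient_id`` column, no unsuppressed small cells) and records the release in
the job log with a manifest of digests and the rules applied.
"""

from __future__ import annotations

import csv
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .errors import ReleaseError
from .pipeline import ProjectSpec, _sha256_file, append_log_entry, read_log


@dataclass(frozen=True)
class DisclosureRules:
    small_cell_threshold: int = 5
    rounding_base: int = 5
    redaction_token: str = "[REDACTED]"

    def __post_init__(self) -> None:
        if self.small_cell_threshold < 0:
            raise ValueError("small_cell_threshold must be >= 0")
        if self.rounding_base < 1:
            raise ValueError("rounding_base must be >= 1")


@dataclass(frozen=True)
class SuppressionFinding:
    row: int
    column: str
    reason: str  # "small-cell" | "secondary" | "non-integer"
    original: object


# --------------------------------------------------------------------------
# Small-cell suppression
# --------------------------------------------------------------------------

def _as_count(value):
    """Integer value of a count cell, or None if it is not a clean integer."""
    if isinstance(value, bool) or value is None:
        return None
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, (float, np.floating)):
        return int(value) if float(value).is_integer() else None
    if isinstance(value, str):
        try:
            return int(value)
        except ValueError:
            return None
    return None


def _detect_total_column(count_columns: Sequence[str]) -> str | None:
    for c in count_columns:
        if c.lower() == "total":
            return c
    return None


def _detect_total_row(table: pd.DataFrame, label_column: str | None) -> int | None:
    if label_column is None or label_column not in table.columns:
        return None
    for i, v in enumerate(table[label_column]):
        if isinstance(v, str) and v.lower() == "total":
            return i
    return None


def _determined_cells(values: np.ndarray, redacted: np.ndarray,
                      data_cols: list[int], data_rows: list[int],
                      total_col: int | None, total_row: int | None) -> list[tuple[int, int]]:
    """Redacted cells uniquely determined by the visible cells and totals.

    Builds the linear system of every usable group equation (a row or column
    whose total cell exists) over the redacted cells as unknowns; an unknown
    is recoverable iff every null-space vector vanishes in its coordinate.
    """
    unknowns = [(r, c) for r in range(values.shape[0]) for c in range(values.shape[1])
                if redacted[r, c]]
    if not unknowns:
        return []
    index = {cell: k for k, cell in enumerate(unknowns)}
    rows_a = []
    if total_col is not None:
        # every row (the total row included: its cells sum to the grand total)
        all_rows = data_rows + ([total_row] if total_row is not None else [])
        for r in all_rows:
            group = [(r, c) for c in data_cols] + [(r, total_col)]
            if any(redacted[cell] for cell in group):
                coeff = np.zeros(len(unknowns))
                for c in data_cols:
                    if redacted[r, c]:
                        coeff[index[(r, c)]] += 1.0
                if redacted[r, total_col]:
                    coeff[index[(r, total_col)]] -= 1.0
                rows_a.append(coeff)
    if total_row is not None:
        all_cols = data_cols + ([total_col] if total_col is not None else [])
        for c in all_cols:
            group = [(r, c) for r in data_rows] + [(total_row, c)]
            if any(redacted[cell] for cell in group):
                coeff = np.zeros(len(unknowns))
                for r in data_rows:
                    if redacted[r, c]:
                        coeff[index[(r, c)]] += 1.0
                if redacted[total_row, c]:
                    coeff[index[(total_row, c)]] -= 1.0
                rows_a.append(coeff)
    if not rows_a:
        return []
    a = np.array(rows_a)
    ns = null_space(a)
    if ns.shape[1] == 0:
        return list(unknowns)
    free = np.abs(ns).max(axis=1) > 1e-9
    return [cell for k, cell in enumerate(unknowns) if not free[k]]


def suppress_small_counts(table: pd.DataFrame, count_columns: Sequence[str],
                          rules: DisclosureRules | None = None,
                          label_column: str | None = None
                          ) -> tuple[pd.DataFrame, list[SuppressionFinding]]:
    """Redact small counts and whatever else is needed to keep them hidden.

    ``count_columns`` are the columns holding counts; a column named ``total``
    (case-insensitive) among them, or a row whose ``label_column`` value is
    ``total``, is treated as a group total and used for secondary suppression.
    Non-integer count cells are redacted defensively with a finding.
    """
    rules = rules or DisclosureRules()
    out = table.copy(deep=True).astype(object)
    findings: list[SuppressionFinding] = []
    n_rows = len(out)
    cols = list(count_columns)
    total_col_name = _detect_total_column(cols)
    total_row_idx = _detect_total_row(out, label_column)

    values = np.zeros((n_rows, len(cols)), dtype=float)
    redacted = np.zeros((n_rows, len(cols)), dtype=bool)
    for j, cname in enumerate(cols):
        for i in range(n_rows):
            v = _as_count(out.iloc[i][cname])
            if v is None:
                redacted[i, j] = True
                findings.append(SuppressionFinding(i, cname, "non-integer",
                                                   out.iloc[i][cname]))
                values[i, j] = np.nan
            else:
                values[i, j] = v

    # primary suppression
    for j, cname in enumerate(cols):
        for i in range(n_rows):
            if not redacted[i, j] and 0 < values[i, j] <= rules.small_cell_threshold:
                redacted[i, j] = True
                findings.append(SuppressionFinding(i, cname, "small-cell", int(values[i, j])))

    total_col = cols.index(total_col_name) if total_col_name else None
    data_cols = [j for j in range(len(cols)) if j != total_col]
    data_rows = [i for i in range(n_rows) if i != total_row_idx]

    def secondary_pass() -> bool:
        changed = False
        groups: list[tuple[list[tuple[int, int]], tuple[int, int] | None]] = []
        if total_col is not None:
            all_rows = data_rows + ([total_row_idx] if total_row_idx is not None else [])
            for i in all_rows:
                groups.append(([(i, j) for j in data_cols], (i, total_col)))
        if total_row_idx is not None:
            for j in data_cols + ([total_col] if total_col is not None else []):
                groups.append(([(i, j) for i in data_rows], (total_row_idx, j)))
        for cells, total_cell in groups:
            if total_cell is not None and redacted[total_cell]:
                continue  # total hidden: no subtraction possible within this group
            hit = [cell for cell in cells if redacted[cell]]
            if len(hit) == 1:
                candidates = [(values[cell], cell) for cell in cells
                              if not redacted[cell] and values[cell] > 0]
                if candidates:
                    _, cell = min(candidates)
                else:
                    cell = total_cell
                redacted[cell] = True
                findings.append(SuppressionFinding(
                    cell[0], cols[cell[1]], "secondary", int(values[cell])))
                changed = True
        return changed

    while secondary_pass():
        pass

    # linear-recovery guard: suppress until nothing is uniquely determined
    for _ in range(values.size):
        determined = _determined_cells(values, redacted, data_cols, data_rows,
                                       total_col, total_row_idx)
        if not determined:
            break
        r, c = determined[0]
        # hide the smallest visible cell sharing a group with the recoverable
        # one (zero cells count: hiding them still breaks the equation chain),
        # falling back to any visible count cell at all
        row_mates = [(values[r, j], (r, j)) for j in range(len(cols)) if not redacted[r, j]]
        col_mates = [(values[i, c], (i, c)) for i in range(n_rows) if not redacted[i, c]]
        candidates = row_mates + col_mates
        if not candidates:
            candidates = [(values[i, j], (i, j)) for i in range(n_rows)
                          for j in range(len(cols)) if not redacted[i, j]]
        if not candidates:  # pragma: no cover - everything already hidden
            break
        _, cell = min(candidates)
        redacted[cell] = True
        findings.append(SuppressionFinding(cell[0], cols[cell[1]], "secondary",
                                           int(values[cell])))
        while secondary_pass():
            pass

    for j, cname in enumerate(cols):
        for i in range(n_rows):
            if redacted[i, j]:
                out.iloc[i, out.columns.get_loc(cname)] = rules.redaction_token
    return out, findings


# --------------------------------------------------------------------------
# Rounding
# --------------------------------------------------------------------------

def round_count(c: int, base: int) -> int:
    """Nearest multiple of ``base``; midpoints round up. Base 1 is the identity."""
    return ((c + base // 2) // base) * base


def round_counts(table: pd.DataFrame, count_columns: Sequence[str],
                 rules: DisclosureRules | None = None) -> pd.DataFrame:
    rules = rules or DisclosureRules()
    out = table.copy(deep=True).astype(object)
    for cname in count_columns:
        loc = out.columns.get_loc(cname)
        for i in range(len(out)):
            v = _as_count(out.iloc[i][cname])
            if v is not None:
                out.iloc[i, loc] = round_count(v, rules.rounding_base)
    return out


# --------------------------------------------------------------------------
# Release gate
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReleaseFinding:
    path: str
    rule: str
    message: str


@dataclass
class ReleaseManifest:
    files: list[dict] = field(default_factory=list)  # {path, digest, checks_passed}
    timestamp: str = ""
    rules: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"files": self.files, "timestamp": self.timestamp,
                           "rules": self.rules}, sort_keys=True, indent=2) + "\n"


def _check_table_file(path: Path, rules: DisclosureRules) -> tuple[list[str], list[ReleaseFinding]]:
    """Content rules for a tabular file: no patient_id column, no raw small cells."""
    findings: list[ReleaseFinding] = []
    passed: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if not rows:
        return ["non-empty"], [ReleaseFinding(path.name, "non-empty", "file is empty")]
    header = rows[0]
    if any(h.lower() == "patient_id" for h in header):
        findings.append(ReleaseFinding(path.name, "no-patient-id",
                                       "row-level patient identifier column present"))
    else:
        passed.append("no-patient-id")
    small = []
    for i, row in enumerate(rows[1:], start=2):
        for h, cell in zip(header, row):
            v = _as_count(cell)
            if v is not None and 0 < v <= rules.small_cell_threshold:
                small.append(f"line {i}, column {h!r}: {v}")
    if small:
        findings.append(ReleaseFinding(path.name, "small-cell",
                                       "unsuppressed small counts: " + "; ".join(small)))
    else:
        passed.append("small-cell")
    return passed, findings


def release(workspace: str | Path, paths: Iterable[str],
            rules: DisclosureRules | None = None,
            spec: ProjectSpec | None = None) -> tuple[ReleaseManifest, list[ReleaseFinding]]:
    """Gate files for release out of the workspace.

    Raises :class:`ReleaseError` for paths that may never be released
    (row-level, undeclared, or stale since their action ran); files that merely
    fail a content rule are rejected with findings and omitted from the
    manifest. A passing release is recorded in the job log.
    """
    rules = rules or DisclosureRules()
    workspace = Path(workspace)
    if spec is None:
        from .pipeline import parse_project
        project_file = workspace / "project.yaml"
        if not project_file.exists():
            raise ReleaseError("no project.yaml in workspace and no spec given")
        spec = parse_project(project_file.read_text())
    entries = read_log(workspace)

    manifest = ReleaseManifest(
        timestamp=dt.datetime.now(dt.timezone.utc).isoformat(timespec="seconds"),
        rules={"small_cell_threshold": rules.small_cell_threshold,
               "rounding_base": rules.rounding_base,
               "redaction_token": rules.redaction_token},
    )
    findings: list[ReleaseFinding] = []
    for relpath in paths:
        covering = spec.output_level(relpath)
        if covering is None:
            raise ReleaseError(f"{relpath!r} is not a declared output of any action")
        action, level = covering
        if level != "moderately_sensitive":
            raise ReleaseError(f"{relpath!r} is declared {level}; it never leaves the workspace")
        f = workspace / relpath
        if not f.is_file():
            raise ReleaseError(f"{relpath!r} does not exist in the workspace")
        recorded = None
        for entry in reversed(entries):
            if entry.get("action") == action and entry.get("status") in ("succeeded", "cached"):
                recorded = entry.get("output_digests", {}).get(relpath)
                break
        if recorded is None:
            raise ReleaseError(f"{relpath!r}: no successful run of action {action!r} on record")
        digest = _sha256_file(f)
        if digest != recorded:
            raise ReleaseError(f"{relpath!r} was modified after action {action!r} produced it")
        if f.suffix.lower() == ".csv":
            passed, file_findings = _check_table_file(f, rules)
        else:
            passed, file_findings = (["declared-aggregate"], [])
        if file_findings:
            findings.extend(file_findings)
            continue
        manifest.files.append({"path": relpath, "digest": digest, "checks_passed": passed})

    releases_dir = workspace / "metadata" / "releases"
    releases_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = releases_dir / f"release-{len(list(releases_dir.glob('release-*.json'))) + 1}.json"
    manifest_path.write_text(manifest.to_json())
    append_log_entry(workspace, entries, {
        "timestamp": manifest.timestamp,
        "action": "__release__",
        "command": "release " + " ".join(paths),
        "environment_id": "trekit:v1",
        "input_hashes": {f["path"]: f["digest"] for f in manifest.files},
        "output_digests": {manifest_path.relative_to(workspace).as_posix():
                           hashlib.sha256(manifest.to_json().encode()).hexdigest()},
        "status": "succeeded",
        "cache_key": "",
        "workspace_id": workspace.name,
    })
    return manifest, findings


def revalidate_manifest(workspace: str | Path, manifest: ReleaseManifest,
                        rules: DisclosureRules | None = None) -> list[ReleaseFinding]:
    """Re-run every content check on the files a manifest lists; empty = still safe."""
    rules = rules or DisclosureRules()
    workspace = Path(workspace)
    findings: list[ReleaseFinding] = []
    for item in manifest.files:
        f = workspace / item["path"]
        if not f.is_file() or _sha256_file(f) != item["digest"]:
            findings.append(ReleaseFinding(item["path"], "digest", "file missing or modified"))
            continue
        if f.suffix.lower() == ".csv":
            _, file_findings = _check_table_file(f, rules)
            findings.extend(file_findings)
    return findings
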