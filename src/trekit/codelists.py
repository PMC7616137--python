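"""Codelist building, versioning, rot detection and corruption guards.

A codelist is a curated list of clinical codes defining a concept (e.g. all
hypertension diagnoses), pinned to the coding-system release it was built
from, together with the search strategies used to build it. Coding systems
are themselves versioned: concepts are added, retired or re-termed between
releases, so a codelist degrades over time ("codelist rot"). This module
quantifies that degradation against a release, upgrades codelists under an
explicit policy with full provenance, and flags the classic spreadsheet
corruption signatures (large integer codes cast to floating point).

Codes are identifiers, never numbers: they are stored, compared and
round-tripped as verbatim strings.
"""

from __future__ import annotations

import csv
import datetime as dt
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .errors import CodelistError

CODING_SYSTEMS = ("SNOMEDCT", "dmd", "ICD10", "generic")
ROT_CATEGORIES = (
    "active-unchanged",
    "term-changed",
    "retired-with-replacement",
    "retired-no-replacement",
    "unknown-to-release",
)


@dataclass(frozen=True)
class SearchRecord:
    """One recorded search: the query, what it matched, and the curator's decisions."""

    query_text: str
    matched_codes: tuple[str, ...]
    timestamp: str
    included: tuple[str, ...] = ()
    excluded: tuple[str, ...] = ()


@dataclass(frozen=True)
class Codelist:
    codelist_id: str
    coding_system: str
    system_version: str
    entries: tuple[tuple[str, str], ...]  # (code, term), ordered
    searches: tuple[SearchRecord, ...] = ()
    manual_additions: tuple[str, ...] = ()
    version: int = 1
    parent_version: int | None = None
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.coding_system not in CODING_SYSTEMS:
            raise CodelistError(f"unknown coding system {self.coding_system!r}")
        if self.version < 1:
            raise CodelistError("version must be >= 1")
        codes = [c for c, _ in self.entries]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise CodelistError(f"duplicate codes: {sorted(dupes)}")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.entries)


@dataclass(frozen=True)
class Concept:
    term: str
    status: str  # "active" | "retired"
    replaced_by: str | None = None


@dataclass(frozen=True)
class CodingSystemRelease:
    system: str
    release_tag: str
    concepts: Mapping[str, Concept]

    def __post_init__(self) -> None:
        for code, concept in self.concepts.items():
            if concept.replaced_by is not None and concept.replaced_by not in self.concepts:
                raise CodelistError(
                    f"concept {code!r}: replaced_by {concept.replaced_by!r} not in release")


# --------------------------------------------------------------------------
# CSV round-trips (codes verbatim, no numeric parsing anywhere)
# --------------------------------------------------------------------------

def read_codelist_csv(path: str | Path, codelist_id: str | None = None,
                      coding_system: str = "generic", system_version: str = "unknown") -> Codelist:
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "code" not in reader.fieldnames:
            raise CodelistError(f"{path.name}: missing required 'code' column")
        entries = []
        seen = set()
        for row in reader:
            code = row["code"]
            if code in seen:
                raise CodelistError(f"{path.name}: duplicate code {code!r}")
            seen.add(code)
            entries.append((code, row.get("term", "") or ""))
    return Codelist(
        codelist_id=codelist_id or path.stem,
        coding_system=coding_system,
        system_version=system_version,
        entries=tuple(entries),
    )


def write_codelist_csv(cl: Codelist, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "term"])
        for code, term in cl.entries:
            writer.writerow([code, term])


def read_release_csv(path: str | Path, system: str = "generic",
                     release_tag: str | None = None) -> CodingSystemRelease:
    """Release CSV columns: code,term,status,replaced_by (empty = none)."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        needed = {"code", "term", "status"}
        if reader.fieldnames is None or not needed <= set(reader.fieldnames):
            raise CodelistError(f"{path.name}: release CSV needs columns {sorted(needed)}")
        concepts = {}
        for row in reader:
            concepts[row["code"]] = Concept(
                term=row["term"],
                status=row["status"],
                replaced_by=row.get("replaced_by") or None,
            )
    return CodingSystemRelease(system=system, release_tag=release_tag or path.stem,
                               concepts=concepts)


def write_release_csv(release: CodingSystemRelease, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "term", "status", "replaced_by"])
        for code, c in release.concepts.items():
            writer.writerow([code, c.term, c.status, c.replaced_by or ""])


# --------------------------------------------------------------------------
# Corruption detection (spreadsheet float-cast signatures)
# --------------------------------------------------------------------------

_EXPONENT_RE = re.compile(r"^\d+(\.\d+)?[eE][+-]?\d+$")
_FLOAT_CAST_RE = re.compile(r"^\d+\.0+$")


@dataclass(frozen=True)
class CorruptionFinding:
    code: str
    kind: str  # "exponent-notation" | "float-cast" | "suspicious-zero-run"
    message: str


@dataclass
class CorruptionReport:
    findings: list[CorruptionFinding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings


def detect_corruption(cl: Codelist, zero_run_suspicion_length: int = 4) -> CorruptionReport:
    """Flag codes matching the signatures a spreadsheet's float cast leaves behind.

    Long integer codes opened in a spreadsheet come back in exponent notation,
    with a trailing ``.0``, or silently rounded so the trailing digits become
    zeros. The zero-run heuristic only fires when a sibling code shares the
    rounded prefix, since genuine codes can end in zeros.
    """
    findings: list[CorruptionFinding] = []
    all_codes = set(cl.codes)
    for code in cl.codes:
        if _EXPONENT_RE.match(code):
            findings.append(CorruptionFinding(
                code, "exponent-notation",
                f"code {code!r} looks like a float in scientific notation"))
            continue
        if _FLOAT_CAST_RE.match(code):
            findings.append(CorruptionFinding(
                code, "float-cast", f"code {code!r} carries a float-cast '.0' suffix"))
            continue
        if code.isdigit():
            stripped = code.rstrip("0")
            run = len(code) - len(stripped)
            if run > zero_run_suspicion_length and stripped:
                prefix = code[:len(stripped)]
                siblings = [c for c in all_codes
                            if c != code and len(c) == len(code) and c.startswith(prefix)]
                if siblings:
                    findings.append(CorruptionFinding(
                        code, "suspicious-zero-run",
                        f"code {code!r} ends in {run} zeros and shares its rounded prefix "
                        f"with {siblings[0]!r}"))
    return CorruptionReport(findings)


# --------------------------------------------------------------------------
# Rot detection and policy-driven updates
# --------------------------------------------------------------------------

@dataclass
class RotReport:
    release_tag: str
    categories: dict[str, str]  # code -> rot category
    replacements: dict[str, str]  # retired code -> suggested replacement

    @property
    def rot_score(self) -> float:
        """Fraction of codes that are not active and unchanged in the release."""
        if not self.categories:
            return 0.0
        rotten = sum(1 for c in self.categories.values() if c != "active-unchanged")
        return rotten / len(self.categories)

    def codes_in(self, category: str) -> list[str]:
        return [code for code, cat in self.categories.items() if cat == category]


def check_rot(cl: Codelist, release: CodingSystemRelease) -> RotReport:
    """Partition the codelist's codes by their fate in a coding-system release."""
    if release.system != cl.coding_system:
        raise CodelistError(
            f"release is for system {release.system!r}, codelist uses {cl.coding_system!r}")
    categories: dict[str, str] = {}
    replacements: dict[str, str] = {}
    for code, term in cl.entries:
        concept = release.concepts.get(code)
        if concept is None:
            categories[code] = "unknown-to-release"
        elif concept.status == "retired":
            if concept.replaced_by:
                categories[code] = "retired-with-replacement"
                replacements[code] = concept.replaced_by
            else:
                categories[code] = "retired-no-replacement"
        elif concept.term != term:
            categories[code] = "term-changed"
        else:
            categories[code] = "active-unchanged"
    return RotReport(release_tag=release.release_tag, categories=categories,
                     replacements=replacements)


def update_to_release(cl: Codelist, release: CodingSystemRelease, policy: str,
                      manual_resolutions: Mapping[str, str | None] | None = None) -> Codelist:
    """Produce version n+1 of the codelist against a newer release.

    Policies: ``accept_replacements`` swaps retired codes for their successors,
    ``drop_retired`` removes retired/unknown codes, ``manual`` requires an
    explicit resolution (replacement code or None to drop) per problem code.
    The input version is untouched; every change is recorded as a provenance
    note on the new version.
    """
    if policy not in ("accept_replacements", "drop_retired", "manual"):
        raise CodelistError(f"unknown policy {policy!r}")
    report = check_rot(cl, release)
    manual_resolutions = dict(manual_resolutions or {})
    problem = [c for c, cat in report.categories.items()
               if cat in ("retired-with-replacement", "retired-no-replacement",
                          "unknown-to-release")]
    if policy == "manual":
        unresolved = [c for c in problem if c not in manual_resolutions]
        if unresolved:
            raise CodelistError(f"pending decisions for codes: {sorted(unresolved)}")
    new_entries: list[tuple[str, str]] = []
    notes: list[str] = []
    for code, term in cl.entries:
        cat = report.categories[code]
        if cat == "active-unchanged":
            new_entries.append((code, term))
        elif cat == "term-changed":
            new_term = release.concepts[code].term
            new_entries.append((code, new_term))
            notes.append(f"term updated for {code}: {term!r} -> {new_term!r}")
        elif policy == "manual":
            resolution = manual_resolutions[code]
            if resolution is None:
                notes.append(f"dropped {code} ({cat}) by manual decision")
            else:
                new_entries.append((resolution, release.concepts[resolution].term))
                notes.append(f"replaced {code} -> {resolution} by manual decision")
        elif policy == "accept_replacements" and code in report.replacements:
            repl = report.replacements[code]
            new_entries.append((repl, release.concepts[repl].term))
            notes.append(f"replaced retired {code} -> {repl} ({release.release_tag})")
        elif policy == "accept_replacements":
            new_entries.append((code, term))
            notes.append(f"kept {code} ({cat}; no replacement available)")
        else:  # drop_retired
            notes.append(f"dropped {code} ({cat}; {release.release_tag})")
    # replacements may collide with codes already present; keep first occurrence
    seen: set[str] = set()
    deduped = []
    for code, term in new_entries:
        if code not in seen:
            seen.add(code)
            deduped.append((code, term))
    return replace(
        cl,
        entries=tuple(deduped),
        system_version=release.release_tag,
        version=cl.version + 1,
        parent_version=cl.version,
        notes=cl.notes + tuple(notes),
    )


def record_search(cl: Codelist, query_text: str, release: CodingSystemRelease,
                  include: Iterable[str] | None = None,
                  exclude: Iterable[str] | None = None,
                  timestamp: str | None = None) -> tuple[Codelist, SearchRecord]:
    """Run a case-insensitive substring search over release terms and record it.

    Only explicitly included matches join the codelist; the record keeps the
    full match set and both decisions so the build logic stays reconstructible.
    """
    if not query_text:
        raise CodelistError("search query must be non-empty")
    needle = query_text.lower()
    matched = tuple(sorted(
        code for code, concept in release.concepts.items() if needle in concept.term.lower()))
    include = tuple(sorted(set(include or ())))
    exclude = tuple(sorted(set(exclude or ())))
    unknown = [c for c in include if c not in matched]
    if unknown:
        raise CodelistError(f"cannot include codes the search did not match: {unknown}")
    record = SearchRecord(
        query_text=query_text,
        matched_codes=matched,
        timestamp=timestamp or dt.datetime.now(dt.timezone.utc).isoformat(timespec="seconds"),
        included=include,
        excluded=exclude,
    )
    existing = set(cl.codes)
    new_entries = list(cl.entries)
    for code in include:
        if code not in existing:
            new_entries.append((code, release.concepts[code].term))
            existing.add(code)
    updated = replace(cl, entries=tuple(new_entries), searches=cl.searches + (record,))
    return updated, record


def add_manual(cl: Codelist, code: str, term: str) -> Codelist:
    """Add a code outside any search, keeping it traceable as a manual addition."""
    if code in set(cl.codes):
        raise CodelistError(f"code {code!r} already present")
    return replace(cl, entries=cl.entries + ((code, term),),
                   manual_additions=cl.manual_additions + (code,))


def reconstruct_entries(cl: Codelist, release: CodingSystemRelease) -> tuple[str, ...]:
    """Replay recorded searches plus manual additions; should equal the entry set."""
    codes: list[str] = []
    seen: set[str] = set()
    for record in cl.searches:
        needle = record.query_text.lower()
        matched = {c for c, concept in release.concepts.items() if needle in concept.term.lower()}
        for code in record.included:
            if code in matched and code not in seen:
                seen.add(code)
                codes.append(code)
    for code in cl.manual_additions:
        if code not in seen:
            seen.add(code)
            codes.append(code)
    return tuple(codes)


def version_chain(versions: Iterable[Codelist]) -> list[Codelist]:
    """Order codelist versions by walking parent links back to version 1.

    Raises if the history has gaps, cycles, or does not terminate at version 1.
    """
    by_version = {cl.version: cl for cl in versions}
    if not by_version:
        return []
    head = by_version[max(by_version)]
    chain = [head]
    seen = {head.version}
    current = head
    while current.parent_version is not None:
        parent = by_version.get(current.parent_version)
        if parent is None:
            raise CodelistError(f"missing parent version {current.parent_version}")
        if parent.version in seen or parent.version >= current.version:
            raise CodelistError("version history is not acyclic")
        chain.append(parent)
        seen.add(parent.version)
        current = parent
    if current.version != 1:
        raise CodelistError("version history does not reach version 1")
    return list(reversed(chain))
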