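# Methods

`trekit` is a desk-scale model of the workflow used by trusted research
environments (TREs) for electronic health records: researchers never see
row-level data; they write a serializable *dataset definition* that is compiled
against a versioned database, develop their code on structurally identical
dummy data, run everything through a declared action pipeline with a
tamper-evident audit log, and release only aggregates that pass automated
disclosure control. This note records the models, conventions and design
choices behind each component, and what the tests do and do not demonstrate.

## Data model

The logical schema is deliberately minimal: one patient table
(`patients(patient_id, date_of_birth, sex, date_of_death, practice_id)`, one
row per patient) and two event tables
(`clinical_events(patient_id, date, code, numeric_value)` and
`medications(patient_id, date, code)`). This is enough to express every
behaviour the toolkit exercises — codelist membership, per-patient
aggregation, first/last event selection, date arithmetic — and is extensible
through `TableSchema`. Real deployments have many linked tables with varying
update schedules; the inventory here is an artifact choice, not a claim about
any production system.

Dates are held internally as ISO calendar dates and codes as verbatim strings;
a `SchemaDialect` affects only on-disk names and date text (`ISO8601` or
day-first `DD/MM/YYYY`). Because all query semantics operate on the logical
view, the same definition produces cell-identical output from any dialect —
the portability property the tests check by round-tripping one database
through two dialects. The empty string on disk is null; `patient_id` is never
null.

Databases are immutable snapshots tagged with a version. `rebuild_database`
returns a *new* snapshot, so re-executing a definition against an old version
reproduces old results exactly, which is how the toolkit models weekly
database rebuilds making extractions version-dependent. Deleting a patient
cascades to their events (patients leave when they change practice).

## Query language

Dataset definitions are lazy expression graphs over typed series in two
domains: patient (one value per patient) and event (one value per event row).
Fixed semantic conventions, chosen here because query languages in this space
rarely document them and determinism demands *some* rule:

* **Three-valued logic.** Null propagates through comparisons, arithmetic and
  date operations; `AND`/`OR`/`NOT` are Kleene. Population membership requires
  a literal `True`, so patients with missing data are never silently included.
* **Aggregation** is the only event→patient transition. Empty groups give
  `exists = False`, `count = 0`, and null for min/max/sum/mean; nulls inside a
  group are skipped (an all-null group aggregates to null).
* **First/last selection** requires explicit sort keys; nulls sort smallest,
  and ties are broken by the stable row ordinal from load order (so `last`
  prefers the latest-loaded row among ties). This makes extraction
  deterministic for a fixed database version.
* **Date arithmetic.** Whole-year differences truncate toward zero (so an age
  increments exactly on the birthday); month addition clamps to the end of the
  target month (`2020-01-31 + 1 month = 2020-02-29`); day arithmetic is exact.
* **No event-table joins.** Variables combine only in the patient domain,
  which keeps the one-row-per-patient contract and the reference interpreter
  tractable.

Serialization is canonical JSON with content-addressed node ids (SHA-256 of
each node's canonical encoding): the same graph yields the same bytes
regardless of construction order, so definitions can be hashed into the audit
log and compared for equality as text.

Correctness of the executor rests on a dual-route check: `execute` evaluates
column-at-a-time with per-node caching over pandas containers, while
`oracle_execute` is a deliberately naive per-patient recursive interpreter
over plain Python lists. The suite compares them cell-for-cell on the
hand-traced fixture, on the empty database, and on 100+ seeded random
(definition, database) pairs drawn from generators that force date ties,
nulls and empty groups.

## Dummy data

The generator takes a dataset definition and a `DummySpec` — never a real
database — so independence from real data holds by construction; there is no
code path that could fit distributions to real records. Structure is the only
fidelity target: dummy extractions have exactly the columns and dtypes a real
extraction would, which the conformance checker verifies. Relationships
between variables in the dummy data are meaningless by design, so passing
tests say nothing about statistical properties of real data and the dummy
data cannot be used for feasibility assessment.

Per patient, a qualifying/non-qualifying status is drawn at
`target_population_fraction` (default 0.5), and candidates are
rejection-sampled against the population predicate (cap 1000 tries, then pad
with a non-qualifying patient); the qualifying count is therefore
Binomial(n, fraction), which the tests check against the central 99% interval
at n = 100. If qualifying patients were requested and none could ever be
generated, generation fails with advice to widen the value domains.

Default value domains: dates uniform over [1920-01-01, 2024-12-31] (a fixed
upper bound rather than the current date, so that a seed reproduces identical
bytes on any day), numerics uniform on [0, 100] in steps of 0.1, categories
uniform over declared sets, and codes uniform over the codes referenced by the
definition's membership tests plus ~20% decoy codes, so both match and
non-match paths are exercised. All draws come from one integer-seeded
generator in a fixed order — no float-ordering dependence — giving
byte-identical bundles across runs and platforms. `deposit_bundle` writes the
database, the extracted dataset, the definition and a SHA-256 manifest;
`verify_bundle` and `reproduce_bundle` make the bundle self-verifying and
regenerable from the manifest alone.

## Codelists

Codes are identifiers: read, stored, compared and written as verbatim strings,
never parsed as numbers. The corruption detector flags the signatures left by
spreadsheet float-casting of long integer codes: scientific notation
(`1.00023E+15`), a trailing `.0`, and — more cautiously — all-digit codes
ending in a run of more than 4 zeros *when* a sibling code shares the rounded
prefix (codes genuinely ending in zeros exist, so the heuristic needs
corroboration).

*Codelist rot* is quantified against a coding-system release by partitioning
codes into `active-unchanged`, `term-changed`, `retired-with-replacement`,
`retired-no-replacement` and `unknown-to-release`; the rot score is the
fraction not active-unchanged. The score is an artifact metric — the
phenomenon is real, the quantity is ours — and is monotone in retirements by
construction. `update_to_release` produces version n+1 with a parent link and
per-entry provenance notes under an explicit policy (`accept_replacements`,
`drop_retired`, or `manual` with per-code resolutions); the original version
is immutable, and `version_chain` checks that any history walks back to
version 1 without cycles.

Searches over a release are case-insensitive substring matches on terms
(hierarchy traversal is out of scope); each search is recorded with its match
set and the curator's include/exclude decisions, so replaying all records plus
manual additions reconstructs the entry set exactly.

## Pipelines and the audit log

A project is a YAML map of actions (`run`, pinned `environment`, `needs`,
`outputs` at `highly_sensitive` or `moderately_sensitive` level). Validation
reports *every* failure at once. Planning is Kahn's algorithm with
lexicographic tie-breaking over the closure of the requested targets — the
order is deterministic across platforms, and tests cross-check it against an
independent graph library on random DAGs.

Environments are pinned identifiers (`name:version`) resolved against a
manifest registry rather than actual container execution; old identifiers stay
resolvable, so old pipelines remain runnable. Execution is single-machine and
sequential; any order consistent with the plan would be equally valid.

Caching: an action's cache key is the SHA-256 of its command, environment id
and all input digests (upstream declared outputs plus files its command
references). It is skipped as `cached` only when a prior successful entry has
the same key *and* its recorded output digests still match the files on disk —
i.e. only when re-execution would be byte-identical, which the suite verifies
by forcing re-execution and comparing bytes.

Confinement is enforced at the declaration level, not by OS sandboxing: an
action whose command references another action's declared output without
listing that action among its (transitive) needs fails, and files created
outside the action's declared output patterns fail the action, naming them.

Every attempt — succeeded, cached or failed — is appended to a JSON-lines job
log in which each entry embeds the previous entry's digest and its own digest
over the canonicalized entry body. `verify_log` recomputes the chain; any
byte-level mutation of any historical entry is detected at the first affected
link (the acceptance suite flips every byte of a 5-entry log in turn).

## Disclosure control

Defaults: small-cell threshold 5, rounding base 5, both configurable and
recorded in the release manifest; real TREs publish their own thresholds, and
these values are conventional rather than normative. Rounding is to the
nearest multiple of the base with midpoints rounding up (base 1 is the
identity), so the error is bounded by base/2.

Suppression first redacts every count in (0, threshold] (zero is not
disclosive), then protects against subtraction recovery: whenever a row or
column group with a visible total contains exactly one redacted cell, the
next-smallest cell in the group is also redacted, iterated to a fixpoint.
Because row and column equations interact, the fixpoint alone cannot guarantee
safety, so a final guard builds the linear system of all margin equations over
the redacted cells and keeps suppressing (smallest visible cell sharing a
group with the exposed one) until no redacted cell is uniquely determined —
checked via the null space of the equation matrix. Full minimum-cost cell
suppression is NP-hard and out of scope; the guard trades a few extra redacted
cells for a provable no-recovery property, which the tests confirm with an
independent exact-rational elimination oracle on random margin tables.

`release` is the only path that marks files released. It refuses — rather than
merely failing — paths that are `highly_sensitive`, undeclared, or whose bytes
changed since their producing action ran (digest mismatch against the job
log). Files it does consider are content-checked: a tabular file must not
contain a `patient_id` column and must not contain unsuppressed small counts.
Passing files are listed in a manifest (path, digest, checks, rules) and the
release itself becomes a job-log entry. The small-cell content check treats
every integer cell as a potential count; a table of genuine small-valued
measurements would be rejected conservatively — a deliberate bias toward
non-disclosure.

## Fixtures and problem sizes

All test inputs are generated by code: a hand-traceable 3-patient database
(whose demo extraction is frozen as a golden file and re-derived on every
run), the same database under a renamed day-first dialect, codelist and
release fixtures with one injected retirement (rot score 0.25) and injected
spreadsheet corruption, and chain/diamond/cyclic project fixtures. Problem
sizes in the test and acceptance runs — 100 random query instances at 20
patients, 100 random DAGs, 80 random disclosure tables up to 5×5, dummy
populations of 100 — were chosen so each property is exercised across its edge
cases while the whole suite completes in seconds; all scale linearly if larger
runs are wanted.

## Known limitations

* No real SQL backend, pseudonymisation/linkage, free text, or measurement
  units; no SQL optimizer.
* The surface syntax is this package's own; it is not a re-implementation of
  any production query language.
* Environments are manifests, not containers; executor confinement is
  declaration-checking, not an OS sandbox.
* Disclosure rules are automated stand-ins for human output checking; the
  secondary-suppression guard protects against linear recovery from one
  table's margins, not against cross-table or longitudinal attacks.
* Codelist search is flat substring matching; no coding-system hierarchy.
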