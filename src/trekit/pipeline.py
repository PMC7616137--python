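"""Project pipelines: YAML-defined action DAGs with caching and an audit log.

A project is a set of *actions* — each a command, a pinned runtime
environment, the actions it depends on, and the outputs it declares at a
disclosure level (``highly_sensitive`` row-level data or
``moderately_sensitive`` aggregates). The runner executes actions in a
deterministic topological order, skips an action as *cached* when its command,
environment and input digests match a prior successful run, rejects undeclared
output files, and appends every attempt to an append-only, hash-chained job
log. Tampering with any historical entry breaks the chain and is detected by
:func:`verify_log` — the log is the audit trail of everything ever run.

Environments are pinned identifiers (``name:version``) resolved against a
manifest registry; old identifiers stay resolvable so old pipelines remain
re-executable.
"""

from __future__ import annotations

import datetime as dt
import fnmatch
import hashlib
import heapq
import json
import subprocess
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import yaml

from .errors import ExecutorError, ProjectError

SENSITIVITY_LEVELS = ("highly_sensitive", "moderately_sensitive")
LOG_RELPATH = Path("metadata") / "joblog.jsonl"


@dataclass(frozen=True)
class Action:
    name: str
    run: str
    environment_id: str
    needs: tuple[str, ...] = ()
    outputs: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def executor(self) -> str:
        return self.run.split()[0]

    @property
    def args(self) -> list[str]:
        return self.run.split()[1:]

    def output_patterns(self) -> list[str]:
        return [p for patterns in self.outputs.values() for p in patterns]


@dataclass
class ProjectSpec:
    version: str
    actions: dict[str, Action]

    def output_level(self, relpath: str) -> tuple[str, str] | None:
        """(action, level) whose declared patterns cover the path, if any."""
        for action in self.actions.values():
            for level, patterns in action.outputs.items():
                for pattern in patterns:
                    if fnmatch.fnmatch(relpath, pattern):
                        return action.name, level
        return None


#: Pinned runtime environments; identifiers never change meaning, old versions
#: stay resolvable so any historical pipeline can be re-run.
DEFAULT_ENVIRONMENTS: dict[str, dict] = {
    "trekit:v1": {"tools": {"python": sys.version.split()[0], "trekit": "0.1.0"}},
    "python:v1": {"tools": {"python": sys.version.split()[0]}},
    "python:v2": {"tools": {"python": sys.version.split()[0]}},
}


def _find_cycle(actions: Mapping[str, Action]) -> list[str] | None:
    colour = {name: 0 for name in actions}  # 0 new, 1 active, 2 done
    stack: list[str] = []

    def visit(name: str) -> list[str] | None:
        colour[name] = 1
        stack.append(name)
        for dep in actions[name].needs:
            if dep not in actions:
                continue
            if colour[dep] == 1:
                return stack[stack.index(dep):]
            if colour[dep] == 0:
                found = visit(dep)
                if found:
                    return found
        stack.pop()
        colour[name] = 2
        return None

    for name in sorted(actions):
        if colour[name] == 0:
            found = visit(name)
            if found:
                return found
    return None


def parse_project(yaml_text: str) -> ProjectSpec:
    """Parse and validate a project file, reporting *every* failure at once."""
    failures: list[str] = []
    try:
        doc = yaml.safe_load(yaml_text)
    except yaml.YAMLError as exc:
        raise ProjectError([f"invalid YAML: {exc}"]) from exc
    if not isinstance(doc, dict):
        raise ProjectError(["project file must be a mapping"])
    version = doc.get("version")
    if not version:
        failures.append("missing project version")
    raw_actions = doc.get("actions")
    if not isinstance(raw_actions, dict) or not raw_actions:
        failures.append("project must define at least one action")
        raise ProjectError(failures)

    actions: dict[str, Action] = {}
    declared_paths: dict[str, str] = {}
    for name, body in raw_actions.items():
        if not isinstance(name, str) or not name.isidentifier():
            failures.append(f"action name {name!r} is not a valid identifier")
            continue
        if not isinstance(body, dict):
            failures.append(f"action {name!r}: body must be a mapping")
            continue
        run = body.get("run")
        if not run or not isinstance(run, str) or not run.split():
            failures.append(f"action {name!r}: missing run command")
            run = ""
        env = body.get("environment", "")
        if not env or ":" not in env:
            failures.append(f"action {name!r}: environment must be pinned as name:version")
        needs = body.get("needs", [])
        if not isinstance(needs, list):
            failures.append(f"action {name!r}: needs must be a list")
            needs = []
        outputs_raw = body.get("outputs", {})
        outputs: dict[str, tuple[str, ...]] = {}
        if not isinstance(outputs_raw, dict) or not outputs_raw:
            failures.append(f"action {name!r}: must declare at least one output")
        else:
            for level, patterns in outputs_raw.items():
                if level not in SENSITIVITY_LEVELS:
                    failures.append(f"action {name!r}: unknown output level {level!r}")
                    continue
                if not isinstance(patterns, list) or not patterns:
                    failures.append(f"action {name!r}: output level {level!r} lists no paths")
                    continue
                outputs[level] = tuple(str(p) for p in patterns)
                for p in outputs[level]:
                    if p in declared_paths:
                        failures.append(
                            f"output path {p!r} declared by both {declared_paths[p]!r} and {name!r}")
                    else:
                        declared_paths[p] = name
        actions[name] = Action(name=name, run=run, environment_id=env,
                               needs=tuple(str(n) for n in needs), outputs=outputs)

    for name, action in actions.items():
        for dep in action.needs:
            if dep not in actions:
                failures.append(f"action {name!r}: unknown dependency {dep!r}")
    cycle = _find_cycle(actions)
    if cycle:
        failures.append("dependency cycle: " + " -> ".join(sorted(set(cycle))))
    if failures:
        raise ProjectError(failures)
    return ProjectSpec(version=str(version), actions=actions)


def plan(spec: ProjectSpec, targets: Iterable[str] | None = None) -> list[str]:
    """Minimal closure of the targets under `needs`, in deterministic topological
    order (ties broken lexicographically)."""
    if targets is None:
        wanted = set(spec.actions)
    else:
        wanted = set()
        frontier = list(targets)
        for t in frontier:
            if t not in spec.actions:
                raise ProjectError([f"unknown target action {t!r}"])
        while frontier:
            name = frontier.pop()
            if name in wanted:
                continue
            wanted.add(name)
            frontier.extend(spec.actions[name].needs)
    indegree = {name: sum(1 for d in spec.actions[name].needs if d in wanted) for name in wanted}
    ready = [name for name, deg in indegree.items() if deg == 0]
    heapq.heapify(ready)
    order: list[str] = []
    dependents: dict[str, list[str]] = {name: [] for name in wanted}
    for name in wanted:
        for dep in spec.actions[name].needs:
            if dep in wanted:
                dependents[dep].append(name)
    while ready:
        name = heapq.heappop(ready)
        order.append(name)
        for child in dependents[name]:
            indegree[child] -= 1
            if indegree[child] == 0:
                heapq.heappush(ready, child)
    if len(order) != len(wanted):  # pragma: no cover - cycles rejected at parse
        raise ProjectError(["dependency cycle detected during planning"])
    return order


# --------------------------------------------------------------------------
# Job log: append-only, hash-chained
# --------------------------------------------------------------------------

def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _entry_digest(entry: dict) -> str:
    body = {k: v for k, v in entry.items() if k != "entry_digest"}
    blob = json.dumps(body, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def read_log(workspace: Path) -> list[dict]:
    path = Path(workspace) / LOG_RELPATH
    if not path.exists():
        return []
    entries = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                entries.append(json.loads(line))
    return entries


def append_log_entry(workspace: Path, entries: list[dict], payload: dict) -> dict:
    """Chain a new entry onto the log and persist it; returns the full entry."""
    entry = dict(payload)
    entry["sequence_no"] = len(entries) + 1
    entry["prev_digest"] = entries[-1]["entry_digest"] if entries else ""
    entry["entry_digest"] = _entry_digest(entry)
    path = Path(workspace) / LOG_RELPATH
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(entry, sort_keys=True, separators=(",", ":")) + "\n")
    entries.append(entry)
    return entry


def verify_log(entries: list[dict]) -> tuple[bool, int | None]:
    """Recompute the hash chain; returns (ok, index of first broken link)."""
    prev = ""
    for i, entry in enumerate(entries):
        if entry.get("prev_digest") != prev:
            return False, i
        if entry.get("sequence_no") != i + 1:
            return False, i
        if _entry_digest(entry) != entry.get("entry_digest"):
            return False, i
        prev = entry["entry_digest"]
    return True, None


def render_log(entries: list[dict]) -> str:
    """Human-readable audit report mirroring a public job log page."""
    if not entries:
        return "job log is empty\n"
    lines = ["seq  status     action                command"]
    for e in entries:
        lines.append(f"{e['sequence_no']:<4} {e['status']:<10} {e.get('action', ''):<21} "
                     f"{e.get('command', '')}")
        lines.append(f"     at {e.get('timestamp', '?')}  env {e.get('environment_id', '?')}")
        for path, digest in sorted(e.get("output_digests", {}).items()):
            lines.append(f"     out {path} {digest[:12]}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Execution
# --------------------------------------------------------------------------

Executor = Callable[[list[str], Path], None]


def extract_executor(args: list[str], workspace: Path) -> None:
    """Built-in `extract` action: run a dataset definition against a database."""
    from .backend import identity_dialect, load_database, SchemaDialect
    from .query import deserialize, execute

    opts = _parse_args(args, {"--definition", "--db", "--dialect", "--output"})
    for required in ("--definition", "--db", "--output"):
        if required not in opts:
            raise ExecutorError(f"extract: missing {required}")
    dd = deserialize((workspace / opts["--definition"]).read_text())
    if "--dialect" in opts:
        dialect = SchemaDialect.from_json((workspace / opts["--dialect"]).read_text())
    else:
        dialect = identity_dialect()
    db = load_database(workspace / opts["--db"], dialect)
    out = workspace / opts["--output"]
    out.parent.mkdir(parents=True, exist_ok=True)
    execute(dd, db).to_csv(out)


def exec_script_executor(args: list[str], workspace: Path) -> None:
    """Built-in `exec-script` action: run a Python script confined to the workspace."""
    if not args:
        raise ExecutorError("exec-script: missing script path")
    script = workspace / args[0]
    if not script.exists():
        raise ExecutorError(f"exec-script: script {args[0]!r} not found in workspace")
    proc = subprocess.run([sys.executable, str(script), *args[1:]], cwd=workspace,
                          capture_output=True, text=True)
    if proc.returncode != 0:
        raise ExecutorError(
            f"exec-script: {args[0]} exited with {proc.returncode}: {proc.stderr.strip()[-500:]}")


def _parse_args(args: list[str], known: set[str]) -> dict[str, str]:
    opts = {}
    i = 0
    while i < len(args):
        if args[i] in known and i + 1 < len(args):
            opts[args[i]] = args[i + 1]
            i += 2
        else:
            raise ExecutorError(f"unrecognised argument {args[i]!r}")
    return opts


DEFAULT_REGISTRY: dict[str, Executor] = {
    "extract": extract_executor,
    "exec-script": exec_script_executor,
}


@dataclass
class ExecutionReport:
    statuses: dict[str, str]  # action -> succeeded | cached | failed | skipped
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(s in ("succeeded", "cached") for s in self.statuses.values())


def _workspace_files(workspace: Path) -> set[str]:
    out = set()
    for p in workspace.rglob("*"):
        if p.is_file():
            rel = p.relative_to(workspace).as_posix()
            if not rel.startswith("metadata/"):
                out.add(rel)
    return out


def _matching_files(workspace: Path, patterns: Iterable[str]) -> list[str]:
    files = _workspace_files(workspace)
    return sorted({f for f in files for pat in patterns if fnmatch.fnmatch(f, pat)})


def _transitive_needs(spec: ProjectSpec, name: str) -> set[str]:
    seen: set[str] = set()
    frontier = list(spec.actions[name].needs)
    while frontier:
        dep = frontier.pop()
        if dep not in seen:
            seen.add(dep)
            frontier.extend(spec.actions[dep].needs)
    return seen


def run(spec: ProjectSpec, workspace: str | Path,
        registry: Mapping[str, Executor] | None = None,
        environments: Mapping[str, dict] | None = None,
        targets: Iterable[str] | None = None,
        force: bool = False) -> ExecutionReport:
    """Execute the planned actions sequentially with caching and full logging.

    An action is skipped as *cached* only when its command, environment and
    every input digest match a prior succeeded entry whose recorded outputs
    still match the files on disk — i.e. only when re-execution would be
    byte-identical. Every attempt (succeeded, cached or failed) is appended to
    the job log; dependents of a failed action are skipped and reported.
    """
    workspace = Path(workspace)
    registry = dict(registry or DEFAULT_REGISTRY)
    environments = dict(environments or DEFAULT_ENVIRONMENTS)
    order = plan(spec, targets)
    entries = read_log(workspace)
    statuses: dict[str, str] = {}
    failures: dict[str, str] = {}

    for name in order:
        action = spec.actions[name]
        blocked = [d for d in action.needs if statuses.get(d) in ("failed", "skipped")]
        if blocked:
            statuses[name] = "skipped"
            failures[name] = f"upstream failure in {sorted(blocked)}"
            continue
        if action.executor not in registry:
            raise ExecutorError(f"action {name!r}: no executor registered for {action.executor!r}")
        if action.environment_id not in environments:
            raise ExecutorError(
                f"action {name!r}: environment {action.environment_id!r} is not resolvable")

        # inputs: upstream declared outputs plus command-referenced workspace files
        input_files: set[str] = set()
        upstream = _transitive_needs(spec, name)
        for dep in action.needs:
            input_files.update(_matching_files(workspace, spec.actions[dep].output_patterns()))
        own_patterns = action.output_patterns()
        for arg in action.args:
            candidate = workspace / arg
            own_output = any(fnmatch.fnmatch(arg, p) for p in own_patterns)
            if not own_output:
                covering = spec.output_level(arg)
                if covering is not None and covering[0] != name and covering[0] not in upstream:
                    statuses[name] = "failed"
                    failures[name] = (f"undeclared input {arg!r}: produced by {covering[0]!r} "
                                      f"which is not among this action's needs")
                    break
            if candidate.is_file() and not own_output:
                input_files.add(arg)
            elif candidate.is_dir():
                for f in sorted(candidate.rglob("*")):
                    if f.is_file():
                        input_files.add(f.relative_to(workspace).as_posix())
        if statuses.get(name) == "failed":
            _log_attempt(workspace, entries, action, {}, {}, "failed")
            continue
        input_hashes = {f: _sha256_file(workspace / f) for f in sorted(input_files)
                        if (workspace / f).is_file()}
        cache_key = hashlib.sha256(json.dumps(
            {"command": action.run, "environment_id": action.environment_id,
             "inputs": input_hashes}, sort_keys=True).encode()).hexdigest()

        if not force:
            hit = _cache_lookup(entries, name, cache_key, workspace)
            if hit is not None:
                statuses[name] = "cached"
                _log_attempt(workspace, entries, action, input_hashes, hit, "cached",
                             cache_key=cache_key)
                continue

        before = _workspace_files(workspace)
        try:
            registry[action.executor](action.args, workspace)
        except ExecutorError as exc:
            statuses[name] = "failed"
            failures[name] = str(exc)
            _log_attempt(workspace, entries, action, input_hashes, {}, "failed",
                         cache_key=cache_key)
            continue
        after = _workspace_files(workspace)
        new_files = after - before
        undeclared = sorted(f for f in new_files
                            if not any(fnmatch.fnmatch(f, p) for p in own_patterns))
        produced = _matching_files(workspace, own_patterns)
        if undeclared:
            statuses[name] = "failed"
            failures[name] = f"undeclared output files: {undeclared}"
            _log_attempt(workspace, entries, action, input_hashes, {}, "failed",
                         cache_key=cache_key)
            continue
        if not produced:
            statuses[name] = "failed"
            failures[name] = "action produced none of its declared outputs"
            _log_attempt(workspace, entries, action, input_hashes, {}, "failed",
                         cache_key=cache_key)
            continue
        output_digests = {f: _sha256_file(workspace / f) for f in produced}
        statuses[name] = "succeeded"
        _log_attempt(workspace, entries, action, input_hashes, output_digests, "succeeded",
                     cache_key=cache_key)
    return ExecutionReport(statuses=statuses, failures=failures)


def _cache_lookup(entries: list[dict], action: str, cache_key: str,
                  workspace: Path) -> dict | None:
    """Most recent succeeded entry with the same cache key whose outputs are intact."""
    for entry in reversed(entries):
        if entry.get("action") != action or entry.get("cache_key") != cache_key:
            continue
        if entry.get("status") not in ("succeeded", "cached"):
            continue
        digests = entry.get("output_digests", {})
        if not digests:
            continue
        for relpath, digest in digests.items():
            f = workspace / relpath
            if not f.is_file() or _sha256_file(f) != digest:
                return None
        return digests
    return None


def _log_attempt(workspace: Path, entries: list[dict], action: Action,
                 input_hashes: dict, output_digests: dict, status: str,
                 cache_key: str | None = None) -> None:
    append_log_entry(workspace, entries, {
        "timestamp": dt.datetime.now(dt.timezone.utc).isoformat(timespec="seconds"),
        "action": action.name,
        "command": action.run,
        "environment_id": action.environment_id,
        "input_hashes": input_hashes,
        "output_digests": output_digests,
        "status": status,
        "cache_key": cache_key or "",
        "workspace_id": Path(workspace).name,
    })
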