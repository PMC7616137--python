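"""A small, serializable cohort query language over patient and event tables.

A *dataset definition* pairs a boolean population predicate with named
patient-level variable expressions. Definitions are lazy expression graphs:
building one touches no data. Execution compiles the graph against a logical
database snapshot and emits an analysis-ready table with exactly one row per
qualifying patient, identically for every backend dialect the snapshot was
stored under.

Semantics fixed here (and documented in docs/methods.md):

* three-valued logic — null propagates through comparisons, arithmetic and
  date operations; ``AND``/``OR`` follow Kleene logic; population membership
  requires a literal ``True``;
* aggregation is the only event→patient domain change; patients with no
  qualifying events get ``exists=False``, ``count=0`` and null otherwise;
* first/last row selection sorts nulls smallest and breaks ties by the stable
  row ordinal from load order;
* whole-year date differences truncate toward zero; month addition clamps to
  the end of the target month.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import keyword
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .backend import LOGICAL_SCHEMA, EHRDatabase, TableSchema, patient_table_name
from .errors import DefinitionError, SchemaError, SerializationError

# --------------------------------------------------------------------------
# Expression graph nodes (immutable, content-addressable)
# --------------------------------------------------------------------------

COMPARISONS = ("eq", "ne", "lt", "le", "gt", "ge")
BOOL_OPS = ("and", "or")
ARITH_OPS = ("add", "sub", "mul")
DATE_OPS = ("difference_in_years", "difference_in_days", "add_days", "add_months", "age_as_of")
AGG_OPS = ("exists", "count", "min", "max", "sum", "mean")


class Node:
    """Marker base class for expression-graph nodes."""


@dataclass(frozen=True)
class Constant(Node):
    value: object
    dtype: str


@dataclass(frozen=True)
class ColumnRef(Node):
    table: str
    column: str


@dataclass(frozen=True)
class UnaryOp(Node):
    op: str  # "not" | "is_null"
    arg: Node


@dataclass(frozen=True)
class BinaryOp(Node):
    op: str
    lhs: Node
    rhs: Node


@dataclass(frozen=True)
class InCodes(Node):
    arg: Node
    codes: tuple[str, ...]


@dataclass(frozen=True)
class DateOp(Node):
    op: str
    args: tuple[Node, ...]


@dataclass(frozen=True)
class FrameNode(Node):
    table: str
    filters: tuple[Node, ...] = ()


@dataclass(frozen=True)
class Aggregate(Node):
    op: str
    frame: FrameNode
    column: str | None = None


@dataclass(frozen=True)
class PickColumn(Node):
    frame: FrameNode
    sort_keys: tuple[Node, ...]
    which: str  # "first" | "last"
    column: str


# --------------------------------------------------------------------------
# Domain / dtype inference
# --------------------------------------------------------------------------

PATIENT_DOMAIN = "patient"


def _schema_dtype(ctype: str) -> str:
    return "code" if ctype == "patient_id" else ctype


def infer_domain(node: Node, schema: Mapping[str, TableSchema] = LOGICAL_SCHEMA):
    """Return 'patient', ('event', table) or None (domain-free constant)."""
    if isinstance(node, Constant):
        return None
    if isinstance(node, ColumnRef):
        ts = schema.get(node.table)
        if ts is None:
            raise SchemaError(f"unknown table {node.table!r}")
        return PATIENT_DOMAIN if ts.kind == "patient" else ("event", node.table)
    if isinstance(node, UnaryOp):
        return infer_domain(node.arg, schema)
    if isinstance(node, BinaryOp):
        return _unify_domains(infer_domain(node.lhs, schema), infer_domain(node.rhs, schema))
    if isinstance(node, InCodes):
        return infer_domain(node.arg, schema)
    if isinstance(node, DateOp):
        dom = None
        for a in node.args:
            dom = _unify_domains(dom, infer_domain(a, schema))
        return dom
    if isinstance(node, (Aggregate, PickColumn)):
        return PATIENT_DOMAIN
    raise DefinitionError(f"cannot infer domain of {type(node).__name__}")


def _unify_domains(a, b):
    if a is None:
        return b
    if b is None or a == b:
        return a
    raise DefinitionError(f"cannot combine series of domain {a!r} with domain {b!r}")


def infer_dtype(node: Node, schema: Mapping[str, TableSchema] = LOGICAL_SCHEMA) -> str:
    if isinstance(node, Constant):
        return node.dtype
    if isinstance(node, ColumnRef):
        return _schema_dtype(schema[node.table].column_type(node.column))
    if isinstance(node, UnaryOp):
        return "boolean"
    if isinstance(node, BinaryOp):
        if node.op in COMPARISONS or node.op in BOOL_OPS:
            return "boolean"
        return "numeric"
    if isinstance(node, InCodes):
        return "boolean"
    if isinstance(node, DateOp):
        return "date" if node.op in ("add_days", "add_months") else "numeric"
    if isinstance(node, Aggregate):
        if node.op == "exists":
            return "boolean"
        if node.op in ("count", "sum", "mean"):
            return "numeric"
        return infer_dtype(ColumnRef(node.frame.table, node.column), schema)
    if isinstance(node, PickColumn):
        return infer_dtype(ColumnRef(node.frame.table, node.column), schema)
    raise DefinitionError(f"cannot infer dtype of {type(node).__name__}")


# --------------------------------------------------------------------------
# User-facing Series / frame API
# --------------------------------------------------------------------------

def _wrap(value, like: "Series") -> "Series":
    """Coerce a Python literal into a constant Series matching ``like``'s dtype."""
    if isinstance(value, Series):
        return value
    if value is None:
        return Series(Constant(None, like.dtype), like.dtype, None)
    if isinstance(value, bool):
        return Series(Constant(value, "boolean"), "boolean", None)
    if isinstance(value, (int, float)):
        return Series(Constant(float(value) if isinstance(value, float) else int(value), "numeric"),
                      "numeric", None)
    if isinstance(value, dt.date):
        return Series(Constant(value, "date"), "date", None)
    if isinstance(value, str):
        dtype = like.dtype if like.dtype in ("code", "category") else "category"
        return Series(Constant(value, dtype), dtype, None)
    raise DefinitionError(f"cannot use {type(value).__name__} as a query constant")


@dataclass(eq=False)
class Series:
    """A typed, lazily evaluated column in either the patient or an event domain."""

    node: Node
    dtype: str
    domain: object  # "patient", ("event", table) or None for constants

    # -- comparisons (value semantics: these build expression nodes) --------
    def __eq__(self, other):  # type: ignore[override]
        return self._compare("eq", other)

    def __ne__(self, other):  # type: ignore[override]
        return self._compare("ne", other)

    def __lt__(self, other):
        return self._ordered("lt", other)

    def __le__(self, other):
        return self._ordered("le", other)

    def __gt__(self, other):
        return self._ordered("gt", other)

    def __ge__(self, other):
        return self._ordered("ge", other)

    __hash__ = object.__hash__

    def _compare(self, op: str, other) -> "Series":
        other = _wrap(other, self)
        if other.dtype != self.dtype:
            raise DefinitionError(f"cannot compare {self.dtype} with {other.dtype}")
        return Series(BinaryOp(op, self.node, other.node), "boolean",
                      _unify_domains(self.domain, other.domain))

    def _ordered(self, op: str, other) -> "Series":
        if self.dtype not in ("date", "numeric"):
            raise DefinitionError(f"ordering not defined for dtype {self.dtype!r}")
        return self._compare(op, other)

    # -- boolean algebra -----------------------------------------------------
    def _boolean(self, op: str, other) -> "Series":
        other = _wrap(other, self)
        if self.dtype != "boolean" or other.dtype != "boolean":
            raise DefinitionError("boolean operators require boolean series")
        return Series(BinaryOp(op, self.node, other.node), "boolean",
                      _unify_domains(self.domain, other.domain))

    def __and__(self, other):
        return self._boolean("and", other)

    def __or__(self, other):
        return self._boolean("or", other)

    def __invert__(self):
        if self.dtype != "boolean":
            raise DefinitionError("~ requires a boolean series")
        return Series(UnaryOp("not", self.node), "boolean", self.domain)

    # -- arithmetic ----------------------------------------------------------
    def _arith(self, op: str, other) -> "Series":
        other = _wrap(other, self)
        if self.dtype != "numeric" or other.dtype != "numeric":
            raise DefinitionError("arithmetic requires numeric series")
        return Series(BinaryOp(op, self.node, other.node), "numeric",
                      _unify_domains(self.domain, other.domain))

    def __add__(self, other):
        return self._arith("add", other)

    def __sub__(self, other):
        return self._arith("sub", other)

    def __mul__(self, other):
        return self._arith("mul", other)

    # -- null / membership ----------------------------------------------------
    def is_null(self) -> "Series":
        return Series(UnaryOp("is_null", self.node), "boolean", self.domain)

    def is_in(self, codes) -> "Series":
        """Membership of a code series in a codelist, by exact string equality."""
        if self.dtype != "code":
            raise DefinitionError(f"is_in requires a code series, got {self.dtype!r}")
        entries = getattr(codes, "codes", None)
        code_tuple = tuple(sorted(set(entries if entries is not None else codes)))
        if not all(isinstance(c, str) for c in code_tuple):
            raise DefinitionError("codelist entries must be strings")
        if not code_tuple:
            warnings.warn("membership test against an empty codelist is always false",
                          stacklevel=2)
        return Series(InCodes(self.node, code_tuple), "boolean", self.domain)


def constant(value, dtype: str | None = None) -> Series:
    """Build a constant series, inferring the dtype from the Python type."""
    if dtype is not None:
        return Series(Constant(value, dtype), dtype, None)
    if isinstance(value, bool):
        return Series(Constant(value, "boolean"), "boolean", None)
    if isinstance(value, (int, float)):
        return Series(Constant(value, "numeric"), "numeric", None)
    if isinstance(value, dt.date):
        return Series(Constant(value, "date"), "date", None)
    if isinstance(value, str):
        return Series(Constant(value, "category"), "category", None)
    if value is None:
        raise DefinitionError("a null constant needs an explicit dtype")
    raise DefinitionError(f"cannot infer dtype for constant {value!r}")


class PatientFrame:
    """The one-row-per-patient table; columns are patient-domain series."""

    def __init__(self, table: str = None, schema: Mapping[str, TableSchema] = LOGICAL_SCHEMA):
        self._schema = schema
        self._table = table or patient_table_name(schema)
        if schema[self._table].kind != "patient":
            raise SchemaError(f"{self._table!r} is not a patient table")

    def column(self, name: str) -> Series:
        ctype = self._schema[self._table].column_type(name)
        return Series(ColumnRef(self._table, name), _schema_dtype(ctype), PATIENT_DOMAIN)

    def __getattr__(self, name: str) -> Series:
        try:
            return self.column(name)
        except SchemaError as exc:
            raise AttributeError(str(exc)) from exc


class EventFrame:
    """A (possibly filtered) event table; filters accumulate conjunctively and lazily."""

    def __init__(self, table: str, filters: tuple[Node, ...] = (),
                 schema: Mapping[str, TableSchema] = LOGICAL_SCHEMA):
        if schema[table].kind != "event":
            raise SchemaError(f"{table!r} is not an event table")
        self._schema = schema
        self.table = table
        self.filters = filters

    @property
    def node(self) -> FrameNode:
        return FrameNode(self.table, self.filters)

    def column(self, name: str) -> Series:
        ctype = self._schema[self.table].column_type(name)
        return Series(ColumnRef(self.table, name), _schema_dtype(ctype), ("event", self.table))

    def __getattr__(self, name: str) -> Series:
        try:
            return self.column(name)
        except SchemaError as exc:
            raise AttributeError(str(exc)) from exc

    def where(self, predicate: Series) -> "EventFrame":
        if predicate.dtype != "boolean":
            raise DefinitionError("where() requires a boolean predicate")
        dom = _unify_domains(("event", self.table), predicate.domain)
        if dom != ("event", self.table):  # pragma: no cover - unify raises first
            raise DefinitionError(
                f"predicate domain {predicate.domain!r} does not match frame domain "
                f"{('event', self.table)!r}")
        return EventFrame(self.table, self.filters + (predicate.node,), self._schema)

    def sort_by(self, *keys: Series) -> "SortedEventFrame":
        if not keys:
            raise DefinitionError("sort_by requires at least one sort key")
        for k in keys:
            _unify_domains(("event", self.table), k.domain)
        return SortedEventFrame(self, tuple(k.node for k in keys))

    def first_for_patient(self):
        raise DefinitionError("first_for_patient requires sort keys; call sort_by(...) first")

    def last_for_patient(self):
        raise DefinitionError("last_for_patient requires sort keys; call sort_by(...) first")

    # -- aggregations: the only event→patient domain change -------------------
    def exists_for_patient(self) -> Series:
        return Series(Aggregate("exists", self.node), "boolean", PATIENT_DOMAIN)

    def count_for_patient(self) -> Series:
        return Series(Aggregate("count", self.node), "numeric", PATIENT_DOMAIN)


class SortedEventFrame:
    """An event frame with sort keys, ready for first/last row selection."""

    def __init__(self, frame: EventFrame, sort_keys: tuple[Node, ...]):
        self.frame = frame
        self.sort_keys = sort_keys

    def first_for_patient(self) -> "PatientRowView":
        return PatientRowView(self, "first")

    def last_for_patient(self) -> "PatientRowView":
        return PatientRowView(self, "last")


class PatientRowView:
    """Per patient, the extreme row of a sorted frame; columns become patient series."""

    def __init__(self, sorted_frame: SortedEventFrame, which: str):
        self._sf = sorted_frame
        self._which = which

    def column(self, name: str) -> Series:
        frame = self._sf.frame
        ctype = frame._schema[frame.table].column_type(name)
        node = PickColumn(frame.node, self._sf.sort_keys, self._which, name)
        return Series(node, _schema_dtype(ctype), PATIENT_DOMAIN)

    def __getattr__(self, name: str) -> Series:
        try:
            return self.column(name)
        except SchemaError as exc:
            raise AttributeError(str(exc)) from exc


def aggregate(frame: EventFrame, op: str, column: str | None = None) -> Series:
    """Aggregate an event frame to the patient domain.

    ``exists`` is false and ``count`` zero for patients with no rows; the
    other aggregates are null for them. Nulls in the aggregated column are
    skipped; all-null groups yield null.
    """
    if op not in AGG_OPS:
        raise DefinitionError(f"unknown aggregate {op!r}")
    if op in ("exists", "count"):
        column = None
    else:
        if column is None:
            raise DefinitionError(f"aggregate {op!r} requires a column")
        ctype = _schema_dtype(frame._schema[frame.table].column_type(column))
        if op in ("sum", "mean") and ctype != "numeric":
            raise DefinitionError(f"aggregate {op!r} requires a numeric column, got {ctype!r}")
        if op in ("min", "max") and ctype not in ("numeric", "date"):
            raise DefinitionError(f"aggregate {op!r} requires an orderable column, got {ctype!r}")
    return Series(Aggregate(op, frame.node, column), infer_dtype(Aggregate(op, frame.node, column),
                                                                 frame._schema), PATIENT_DOMAIN)


# -- date arithmetic ---------------------------------------------------------

def _date_series(x) -> Series:
    if isinstance(x, Series):
        if x.dtype != "date":
            raise DefinitionError(f"expected a date series, got {x.dtype!r}")
        return x
    if isinstance(x, dt.date):
        return Series(Constant(x, "date"), "date", None)
    raise DefinitionError(f"expected a date, got {type(x).__name__}")


def _numeric_series(x) -> Series:
    if isinstance(x, Series):
        if x.dtype != "numeric":
            raise DefinitionError(f"expected a numeric series, got {x.dtype!r}")
        return x
    if isinstance(x, (int, float)) and not isinstance(x, bool):
        return Series(Constant(int(x) if isinstance(x, int) else float(x), "numeric"), "numeric", None)
    raise DefinitionError(f"expected a number, got {type(x).__name__}")


def _date_op(op: str, *parts: Series) -> Series:
    dom = None
    for p in parts:
        dom = _unify_domains(dom, p.domain)
    node = DateOp(op, tuple(p.node for p in parts))
    return Series(node, infer_dtype(node), dom)


def difference_in_years(a, b) -> Series:
    """Whole years from ``b`` to ``a``, truncated toward zero."""
    return _date_op("difference_in_years", _date_series(a), _date_series(b))


def difference_in_days(a, b) -> Series:
    return _date_op("difference_in_days", _date_series(a), _date_series(b))


def add_days(d, n) -> Series:
    return _date_op("add_days", _date_series(d), _numeric_series(n))


def add_months(d, n) -> Series:
    """Calendar-month addition, clamping to the end of the target month."""
    return _date_op("add_months", _date_series(d), _numeric_series(n))


def age_as_of(date_of_birth, reference) -> Series:
    """Age in whole years at the reference date (birthday not yet reached counts down)."""
    return _date_op("age_as_of", _date_series(date_of_birth), _date_series(reference))


# Frames bound to the default logical schema, for direct use in definitions.
patients = PatientFrame()
clinical_events = EventFrame("clinical_events")
medications = EventFrame("medications")


# --------------------------------------------------------------------------
# Dataset definition
# --------------------------------------------------------------------------

@dataclass
class DatasetDefinition:
    """Population predicate plus ordered, named patient-level variables."""

    population: Series
    variables: dict[str, Series] = field(default_factory=dict)
    schema: Mapping[str, TableSchema] = field(default_factory=lambda: LOGICAL_SCHEMA)

    def __post_init__(self) -> None:
        if self.population.dtype != "boolean":
            raise DefinitionError("population must be a boolean series")
        if self.population.domain not in (PATIENT_DOMAIN, None):
            raise DefinitionError("population must be a patient-domain series")
        for name, series in self.variables.items():
            if not name.isidentifier() or keyword.iskeyword(name) or name == "patient_id":
                raise DefinitionError(f"invalid variable name {name!r}")
            if series.domain not in (PATIENT_DOMAIN, None):
                raise DefinitionError(f"variable {name!r} is not patient-domain; aggregate it first")

    def output_columns(self) -> list[str]:
        return ["patient_id"] + list(self.variables)

    def output_dtypes(self) -> dict[str, str]:
        out = {"patient_id": "code"}
        for name, series in self.variables.items():
            out[name] = series.dtype
        return out


# --------------------------------------------------------------------------
# Canonical serialization (content-addressed node ids, stable bytes)
# --------------------------------------------------------------------------

FORMAT_TAG = "trekit-dataset-definition/1"


def _encode_value(value):
    if isinstance(value, dt.date):
        return {"__date__": value.isoformat()}
    return value


def _decode_value(value):
    if isinstance(value, dict) and "__date__" in value:
        return dt.date.fromisoformat(value["__date__"])
    return value


def _node_id(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _collect(node: Node, nodes: dict[str, dict]) -> str:
    """Encode a node (children first) and return its content-addressed id."""
    if isinstance(node, Constant):
        payload = {"kind": "constant", "dtype": node.dtype, "value": _encode_value(node.value)}
    elif isinstance(node, ColumnRef):
        payload = {"kind": "column", "table": node.table, "column": node.column}
    elif isinstance(node, UnaryOp):
        payload = {"kind": "unary", "op": node.op, "arg": _collect(node.arg, nodes)}
    elif isinstance(node, BinaryOp):
        payload = {"kind": "binary", "op": node.op,
                   "lhs": _collect(node.lhs, nodes), "rhs": _collect(node.rhs, nodes)}
    elif isinstance(node, InCodes):
        payload = {"kind": "in_codes", "arg": _collect(node.arg, nodes), "codes": list(node.codes)}
    elif isinstance(node, DateOp):
        payload = {"kind": "date_op", "op": node.op,
                   "args": [_collect(a, nodes) for a in node.args]}
    elif isinstance(node, FrameNode):
        payload = {"kind": "frame", "table": node.table,
                   "filters": [_collect(f, nodes) for f in node.filters]}
    elif isinstance(node, Aggregate):
        payload = {"kind": "aggregate", "op": node.op,
                   "frame": _collect(node.frame, nodes), "column": node.column}
    elif isinstance(node, PickColumn):
        payload = {"kind": "pick", "frame": _collect(node.frame, nodes),
                   "sort_keys": [_collect(k, nodes) for k in node.sort_keys],
                   "which": node.which, "column": node.column}
    else:
        raise SerializationError(f"cannot serialize node {type(node).__name__}")
    nid = _node_id(payload)
    nodes[nid] = payload
    return nid


def serialize(dd: DatasetDefinition) -> str:
    """Canonical text form: same graph → same bytes, regardless of build order."""
    nodes: dict[str, dict] = {}
    pop_id = _collect(dd.population.node, nodes)
    variables = [[name, _collect(series.node, nodes)] for name, series in dd.variables.items()]
    doc = {
        "format": FORMAT_TAG,
        "nodes": {nid: nodes[nid] for nid in sorted(nodes)},
        "population": pop_id,
        "variables": variables,
    }
    return json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n"


def definition_digest(dd: DatasetDefinition) -> str:
    return hashlib.sha256(serialize(dd).encode()).hexdigest()


def _build_node(nid: str, raw: Mapping[str, dict], memo: dict[str, Node]) -> Node:
    if nid in memo:
        return memo[nid]
    if nid not in raw:
        raise SerializationError("dangling node reference", location=f"node {nid}")
    p = raw[nid]
    kind = p.get("kind")
    try:
        if kind == "constant":
            node: Node = Constant(_decode_value(p["value"]), p["dtype"])
        elif kind == "column":
            node = ColumnRef(p["table"], p["column"])
        elif kind == "unary":
            node = UnaryOp(p["op"], _build_node(p["arg"], raw, memo))
        elif kind == "binary":
            node = BinaryOp(p["op"], _build_node(p["lhs"], raw, memo),
                            _build_node(p["rhs"], raw, memo))
        elif kind == "in_codes":
            node = InCodes(_build_node(p["arg"], raw, memo), tuple(p["codes"]))
        elif kind == "date_op":
            node = DateOp(p["op"], tuple(_build_node(a, raw, memo) for a in p["args"]))
        elif kind == "frame":
            node = FrameNode(p["table"], tuple(_build_node(f, raw, memo) for f in p["filters"]))
        elif kind == "aggregate":
            frame = _build_node(p["frame"], raw, memo)
            if not isinstance(frame, FrameNode):
                raise SerializationError("aggregate frame is not a frame node", location=f"node {nid}")
            node = Aggregate(p["op"], frame, p["column"])
        elif kind == "pick":
            frame = _build_node(p["frame"], raw, memo)
            if not isinstance(frame, FrameNode):
                raise SerializationError("pick frame is not a frame node", location=f"node {nid}")
            node = PickColumn(frame, tuple(_build_node(k, raw, memo) for k in p["sort_keys"]),
                              p["which"], p["column"])
        else:
            raise SerializationError(f"unknown node kind {kind!r}", location=f"node {nid}")
    except KeyError as exc:
        raise SerializationError(f"missing field {exc}", location=f"node {nid}") from exc
    memo[nid] = node
    return node


def deserialize(text: str, schema: Mapping[str, TableSchema] = LOGICAL_SCHEMA) -> DatasetDefinition:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SerializationError(f"malformed JSON: {exc.msg}",
                                 location=f"line {exc.lineno}, column {exc.colno}") from exc
    if not isinstance(doc, dict) or doc.get("format") != FORMAT_TAG:
        raise SerializationError(f"not a {FORMAT_TAG} document", location="top level")
    raw = doc.get("nodes", {})
    memo: dict[str, Node] = {}
    pop_node = _build_node(doc["population"], raw, memo)
    population = Series(pop_node, infer_dtype(pop_node, schema), infer_domain(pop_node, schema))
    variables: dict[str, Series] = {}
    for name, nid in doc.get("variables", []):
        node = _build_node(nid, raw, memo)
        variables[name] = Series(node, infer_dtype(node, schema), infer_domain(node, schema))
    return DatasetDefinition(population=population, variables=variables, schema=schema)


# --------------------------------------------------------------------------
# Analytic dataset container
# --------------------------------------------------------------------------

def format_dataset_cell(value, dtype: str) -> str:
    if value is None:
        return ""
    if dtype == "date":
        return value.isoformat()
    if dtype == "boolean":
        return "true" if value else "false"
    if dtype == "numeric":
        if isinstance(value, int):
            return str(value)
        return repr(float(value))
    return str(value)


@dataclass
class AnalyticDataset:
    """One-row-per-patient output table with its column dtypes."""

    frame: pd.DataFrame  # object dtype; patient_id first, variables in declaration order
    dtypes: dict[str, str]

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def to_csv_text(self) -> str:
        lines = [",".join(self.columns)]
        for _, row in self.frame.iterrows():
            lines.append(",".join(format_dataset_cell(row[c], self.dtypes[c]) for c in self.columns))
        return "\n".join(lines) + "\n"

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write(self.to_csv_text())

    def cells(self) -> list[tuple]:
        return list(self.frame.itertuples(index=False, name=None))


# --------------------------------------------------------------------------
# Three-valued scalar semantics (shared helpers, used column-at-a-time here)
# --------------------------------------------------------------------------

def kleene_and(a, b):
    if a is False or b is False:
        return False
    if a is None or b is None:
        return None
    return True


def kleene_or(a, b):
    if a is True or b is True:
        return True
    if a is None or b is None:
        return None
    return False


def kleene_not(a):
    return None if a is None else (not a)


_CMP = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
}
_ARITH = {
    "add": lambda a, b: a + b,
    "sub": lambda a, b: a - b,
    "mul": lambda a, b: a * b,
}


def whole_years_between(a: dt.date, b: dt.date) -> int:
    """Whole calendar years from b to a, truncated toward zero."""
    if a < b:
        return -whole_years_between(b, a)
    years = a.year - b.year
    if (a.month, a.day) < (b.month, b.day):
        years -= 1
    return years


def shift_months(d: dt.date, n: int) -> dt.date:
    """Add n calendar months, clamping the day to the end of the target month."""
    total = d.year * 12 + (d.month - 1) + n
    year, month0 = divmod(total, 12)
    month = month0 + 1
    # last day of target month
    if month == 12:
        last = 31
    else:
        last = (dt.date(year, month + 1, 1) - dt.timedelta(days=1)).day
    return dt.date(year, month, min(d.day, last))


def eval_date_op(op: str, values: Sequence):
    if any(v is None for v in values):
        return None
    if op == "difference_in_years":
        return whole_years_between(values[0], values[1])
    if op == "difference_in_days":
        return (values[0] - values[1]).days
    if op == "add_days":
        return values[0] + dt.timedelta(days=int(values[1]))
    if op == "add_months":
        return shift_months(values[0], int(values[1]))
    if op == "age_as_of":
        return whole_years_between(values[1], values[0])
    raise DefinitionError(f"unknown date op {op!r}")


def sort_token(value):
    """Order nulls smallest, then by value; usable inside a tuple sort key."""
    return (0, None) if value is None else (1, value)


# --------------------------------------------------------------------------
# Execution (column-at-a-time evaluator over the logical tables)
# --------------------------------------------------------------------------

def _walk(node: Node):
    yield node
    for child in _children(node):
        yield from _walk(child)


def _children(node: Node):
    if isinstance(node, UnaryOp):
        return (node.arg,)
    if isinstance(node, BinaryOp):
        return (node.lhs, node.rhs)
    if isinstance(node, InCodes):
        return (node.arg,)
    if isinstance(node, DateOp):
        return node.args
    if isinstance(node, FrameNode):
        return node.filters
    if isinstance(node, Aggregate):
        return (node.frame,)
    if isinstance(node, PickColumn):
        return (node.frame,) + node.sort_keys
    return ()


def resolve_definition(dd: DatasetDefinition, schema: Mapping[str, TableSchema]) -> None:
    """Compile-time resolution: every referenced table/column must exist."""
    problems = []
    roots = [dd.population.node] + [s.node for s in dd.variables.values()]
    for root in roots:
        for node in _walk(root):
            if isinstance(node, ColumnRef):
                if node.table not in schema:
                    problems.append(f"unknown table {node.table!r}")
                elif node.column not in schema[node.table].column_names:
                    problems.append(f"unknown column {node.table}.{node.column}")
            elif isinstance(node, FrameNode):
                if node.table not in schema:
                    problems.append(f"unknown table {node.table!r}")
                elif schema[node.table].kind != "event":
                    problems.append(f"{node.table!r} is not an event table")
            elif isinstance(node, (Aggregate, PickColumn)) and node.column is not None:
                t = node.frame.table
                if t in schema and node.column not in schema[t].column_names:
                    problems.append(f"unknown column {t}.{node.column}")
    if problems:
        raise SchemaError("; ".join(sorted(set(problems))))


class _Evaluator:
    """Evaluates expression nodes column-at-a-time with per-node caching."""

    def __init__(self, db: EHRDatabase):
        self.db = db
        self.schema = db.schema
        self.patient_ids = db.patient_ids()
        self._pindex = {pid: i for i, pid in enumerate(self.patient_ids)}
        self._pcache: dict[Node, list] = {}
        self._ecache: dict[tuple[Node, str], list] = {}
        self._rows_cache: dict[FrameNode, list[int]] = {}

    # -- patient domain --------------------------------------------------
    def patient(self, node: Node) -> list:
        if node in self._pcache:
            return self._pcache[node]
        n = len(self.patient_ids)
        if isinstance(node, Constant):
            out = [node.value] * n
        elif isinstance(node, ColumnRef):
            out = list(self.db.tables[node.table][node.column])
        elif isinstance(node, UnaryOp):
            arg = self.patient(node.arg)
            fn = kleene_not if node.op == "not" else (lambda v: v is None)
            out = [fn(v) for v in arg]
        elif isinstance(node, BinaryOp):
            lhs, rhs = self.patient(node.lhs), self.patient(node.rhs)
            out = [_apply_binary(node.op, a, b) for a, b in zip(lhs, rhs)]
        elif isinstance(node, InCodes):
            codes = set(node.codes)
            out = [None if v is None else v in codes for v in self.patient(node.arg)]
        elif isinstance(node, DateOp):
            cols = [self.patient(a) for a in node.args]
            out = [eval_date_op(node.op, vals) for vals in zip(*cols)]
        elif isinstance(node, Aggregate):
            out = self._aggregate(node)
        elif isinstance(node, PickColumn):
            out = self._pick(node)
        else:
            raise DefinitionError(f"cannot evaluate {type(node).__name__} in patient domain")
        self._pcache[node] = out
        return out

    # -- event domain ------------------------------------------------------
    def event(self, node: Node, table: str) -> list:
        key = (node, table)
        if key in self._ecache:
            return self._ecache[key]
        n = len(self.db.tables[table])
        if isinstance(node, Constant):
            out = [node.value] * n
        elif isinstance(node, ColumnRef):
            if node.table != table:
                raise DefinitionError(
                    f"series over table {node.table!r} used in context of table {table!r}")
            out = list(self.db.tables[table][node.column])
        elif isinstance(node, UnaryOp):
            arg = self.event(node.arg, table)
            fn = kleene_not if node.op == "not" else (lambda v: v is None)
            out = [fn(v) for v in arg]
        elif isinstance(node, BinaryOp):
            lhs, rhs = self.event(node.lhs, table), self.event(node.rhs, table)
            out = [_apply_binary(node.op, a, b) for a, b in zip(lhs, rhs)]
        elif isinstance(node, InCodes):
            codes = set(node.codes)
            out = [None if v is None else v in codes for v in self.event(node.arg, table)]
        elif isinstance(node, DateOp):
            cols = [self.event(a, table) for a in node.args]
            out = [eval_date_op(node.op, vals) for vals in zip(*cols)]
        else:
            raise DefinitionError(f"cannot evaluate {type(node).__name__} in event domain")
        self._ecache[key] = out
        return out

    def _frame_rows(self, frame: FrameNode) -> list[int]:
        """Row ordinals of the table kept by the frame's conjunctive filters."""
        if frame in self._rows_cache:
            return self._rows_cache[frame]
        table = self.db.tables[frame.table]
        keep = list(range(len(table)))
        for pred in frame.filters:
            col = self.event(pred, frame.table)
            keep = [i for i in keep if col[i] is True]
        self._rows_cache[frame] = keep
        return keep

    def _groups(self, frame: FrameNode) -> dict[str, list[int]]:
        pids = list(self.db.tables[frame.table]["patient_id"])
        groups: dict[str, list[int]] = {}
        for i in self._frame_rows(frame):
            groups.setdefault(pids[i], []).append(i)
        return groups

    def _aggregate(self, node: Aggregate) -> list:
        groups = self._groups(node.frame)
        values = None
        if node.column is not None:
            values = list(self.db.tables[node.frame.table][node.column])
        out = []
        for pid in self.patient_ids:
            rows = groups.get(pid, [])
            if node.op == "exists":
                out.append(bool(rows))
                continue
            if node.op == "count":
                out.append(len(rows))
                continue
            vals = [values[i] for i in rows if values[i] is not None]
            if not vals:
                out.append(None)
            elif node.op == "min":
                out.append(min(vals))
            elif node.op == "max":
                out.append(max(vals))
            elif node.op == "sum":
                out.append(sum(vals))
            elif node.op == "mean":
                out.append(sum(vals) / len(vals))
            else:
                raise DefinitionError(f"unknown aggregate {node.op!r}")
        return out

    def _pick(self, node: PickColumn) -> list:
        groups = self._groups(node.frame)
        keys = [self.event(k, node.frame.table) for k in node.sort_keys]
        values = list(self.db.tables[node.frame.table][node.column])
        pick = min if node.which == "first" else max
        out = []
        for pid in self.patient_ids:
            rows = groups.get(pid, [])
            if not rows:
                out.append(None)
            else:
                best = pick(rows, key=lambda i: tuple(sort_token(k[i]) for k in keys) + (i,))
                out.append(values[best])
        return out


def _apply_binary(op: str, a, b):
    if op in BOOL_OPS:
        return kleene_and(a, b) if op == "and" else kleene_or(a, b)
    if a is None or b is None:
        return None
    if op in _CMP:
        return _CMP[op](a, b)
    if op in _ARITH:
        return _ARITH[op](a, b)
    raise DefinitionError(f"unknown binary op {op!r}")


def execute(dd: DatasetDefinition, db: EHRDatabase) -> AnalyticDataset:
    """Compile and run a dataset definition against a database snapshot.

    Output contains exactly the patients whose population predicate is
    literally true (null excludes), one row each, columns in declaration
    order. Deterministic for a fixed (definition, database version).
    """
    resolve_definition(dd, db.schema)
    ev = _Evaluator(db)
    pop = ev.patient(dd.population.node)
    keep = [i for i, v in enumerate(pop) if v is True]
    data: dict[str, list] = {"patient_id": [ev.patient_ids[i] for i in keep]}
    for name, series in dd.variables.items():
        col = ev.patient(series.node)
        data[name] = [col[i] for i in keep]
    frame = pd.DataFrame(data, columns=dd.output_columns(), dtype=object)
    return AnalyticDataset(frame=frame, dtypes=dd.output_dtypes())
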