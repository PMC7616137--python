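"""Reference interpreter for dataset definitions.

Evaluates a definition one patient at a time by direct recursion over the
expression graph, using plain Python lists and dicts — no pandas, no caching,
no column-at-a-time evaluation. It re-derives the query semantics from scratch
and therefore serves as an independent cross-check of :func:`trekit.query.execute`:
the two must agree cell-for-cell on every input.
"""

from __future__ import annotations

import pandas as pd

from .backend import EHRDatabase
from .errors import DefinitionError
from .query import (
    Aggregate,
    AnalyticDataset,
    BinaryOp,
    ColumnRef,
    Constant,
    DatasetDefinition,
    DateOp,
    FrameNode,
    InCodes,
    PickColumn,
    UnaryOp,
    eval_date_op,
    kleene_and,
    kleene_not,
    kleene_or,
    resolve_definition,
    sort_token,
)

_CMP = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
}
_ARITH = {"add": lambda a, b: a + b, "sub": lambda a, b: a - b, "mul": lambda a, b: a * b}


def _scalar_binary(op, a, b):
    if op == "and":
        return kleene_and(a, b)
    if op == "or":
        return kleene_or(a, b)
    if a is None or b is None:
        return None
    if op in _CMP:
        return _CMP[op](a, b)
    if op in _ARITH:
        return _ARITH[op](a, b)
    raise DefinitionError(f"unknown binary op {op!r}")


def _eval_for_row(node, patient_row: dict, row: tuple[int, dict], table: str):
    """Evaluate an event-domain expression for one event row (ordinal, values)."""
    if isinstance(node, Constant):
        return node.value
    if isinstance(node, ColumnRef):
        if node.table != table:
            raise DefinitionError(f"series over {node.table!r} in context of {table!r}")
        return row[1][node.column]
    if isinstance(node, UnaryOp):
        v = _eval_for_row(node.arg, patient_row, row, table)
        return kleene_not(v) if node.op == "not" else v is None
    if isinstance(node, BinaryOp):
        return _scalar_binary(node.op,
                              _eval_for_row(node.lhs, patient_row, row, table),
                              _eval_for_row(node.rhs, patient_row, row, table))
    if isinstance(node, InCodes):
        v = _eval_for_row(node.arg, patient_row, row, table)
        return None if v is None else v in node.codes
    if isinstance(node, DateOp):
        return eval_date_op(node.op, [_eval_for_row(a, patient_row, row, table) for a in node.args])
    raise DefinitionError(f"cannot evaluate {type(node).__name__} per event row")


def _frame_rows(frame: FrameNode, patient_row, events):
    rows = events[frame.table]
    for pred in frame.filters:
        rows = [r for r in rows if _eval_for_row(pred, patient_row, r, frame.table) is True]
    return rows


def _eval_for_patient(node, patient_row: dict, events: dict[str, list]):
    if isinstance(node, Constant):
        return node.value
    if isinstance(node, ColumnRef):
        return patient_row[node.column]
    if isinstance(node, UnaryOp):
        v = _eval_for_patient(node.arg, patient_row, events)
        return kleene_not(v) if node.op == "not" else v is None
    if isinstance(node, BinaryOp):
        return _scalar_binary(node.op,
                              _eval_for_patient(node.lhs, patient_row, events),
                              _eval_for_patient(node.rhs, patient_row, events))
    if isinstance(node, InCodes):
        v = _eval_for_patient(node.arg, patient_row, events)
        return None if v is None else v in node.codes
    if isinstance(node, DateOp):
        return eval_date_op(node.op, [_eval_for_patient(a, patient_row, events) for a in node.args])
    if isinstance(node, Aggregate):
        rows = _frame_rows(node.frame, patient_row, events)
        if node.op == "exists":
            return bool(rows)
        if node.op == "count":
            return len(rows)
        vals = [r[1][node.column] for r in rows if r[1][node.column] is not None]
        if not vals:
            return None
        if node.op == "min":
            return min(vals)
        if node.op == "max":
            return max(vals)
        if node.op == "sum":
            return sum(vals)
        if node.op == "mean":
            return sum(vals) / len(vals)
        raise DefinitionError(f"unknown aggregate {node.op!r}")
    if isinstance(node, PickColumn):
        rows = _frame_rows(node.frame, patient_row, events)
        if not rows:
            return None
        table = node.frame.table

        def key(r):
            return tuple(sort_token(_eval_for_row(k, patient_row, r, table))
                         for k in node.sort_keys) + (r[0],)

        chosen = (min if node.which == "first" else max)(rows, key=key)
        return chosen[1][node.column]
    raise DefinitionError(f"cannot evaluate {type(node).__name__} per patient")


def oracle_execute(dd: DatasetDefinition, db: EHRDatabase) -> AnalyticDataset:
    """Per-patient reference execution; must equal ``execute`` on every input."""
    resolve_definition(dd, db.schema)
    patient_rows = db.tables[db.patient_table].to_dict("records")
    event_tables = {
        t: list(enumerate(db.tables[t].to_dict("records")))
        for t, ts in db.schema.items() if ts.kind == "event"
    }
    out_rows = []
    for prow in patient_rows:
        events = {
            t: [r for r in rows if r[1]["patient_id"] == prow["patient_id"]]
            for t, rows in event_tables.items()
        }
        if _eval_for_patient(dd.population.node, prow, events) is not True:
            continue
        record = {"patient_id": prow["patient_id"]}
        for name, series in dd.variables.items():
            record[name] = _eval_for_patient(series.node, prow, events)
        out_rows.append(record)
    frame = pd.DataFrame(out_rows, columns=dd.output_columns(), dtype=object)
    return AnalyticDataset(frame=frame, dtypes=dd.output_dtypes())
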