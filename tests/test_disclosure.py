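import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trekit.disclosure import (
    DisclosureRules,
    release,
    revalidate_manifest,
    round_count,
    round_counts,
    suppress_small_counts,
)
from trekit.errors import ReleaseError
from trekit.fixtures import diamond_project_yaml
from trekit.pipeline import parse_project, run

from oracles import recoverable_cells

RULES = DisclosureRules()  # threshold 5, base 5


# ------------------------------------------------------------- suppression

def test_primary_suppression_redacts_small_counts():
    t = pd.DataFrame({"group": ["a", "b", "c"], "n": [12, 3, 40]})
    out, findings = suppress_small_counts(t, ["n"], RULES)
    assert list(out["n"]) == [12, RULES.redaction_token, 40]
    assert [(f.reason, f.original) for f in findings] == [("small-cell", 3)]


def test_secondary_suppression_with_total_column():
    t = pd.DataFrame({"group": ["a", "b"], "n": [3, 40], "total": [10, 45]})
    out, _ = suppress_small_counts(t, ["n", "total"], RULES)
    # n=3 is redacted; its row total would recover it, so the total goes too
    assert out.iloc[0]["n"] == RULES.redaction_token
    assert out.iloc[0]["total"] == RULES.redaction_token
    assert out.iloc[1]["n"] == 40


def test_all_counts_above_threshold_unchanged():
    t = pd.DataFrame({"n": [6, 10, 100], "total": [116, 116, 116]})
    out, findings = suppress_small_counts(t, ["n", "total"], RULES)
    assert findings == []
    assert list(out["n"]) == [6, 10, 100]


def test_zero_counts_are_not_suppressed():
    t = pd.DataFrame({"n": [0, 20]})
    out, findings = suppress_small_counts(t, ["n"], RULES)
    assert list(out["n"]) == [0, 20]
    assert findings == []


def test_non_integer_count_redacted_defensively():
    t = pd.DataFrame({"n": [12.5, 20]})
    out, findings = suppress_small_counts(t, ["n"], RULES)
    assert out.iloc[0]["n"] == RULES.redaction_token
    assert findings[0].reason == "non-integer"


def test_no_redacted_cell_recoverable_on_random_margin_tables(rng):
    """Brute-force subtraction/elimination oracle on random tables with both
    row and column totals: nothing redacted may be uniquely determined."""
    checked = 0
    for _ in range(120):
        nrows, ncols = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        body = rng.integers(0, 12, size=(nrows, ncols))
        full = np.zeros((nrows + 1, ncols + 1), dtype=int)
        full[:nrows, :ncols] = body
        full[:nrows, ncols] = body.sum(axis=1)
        full[nrows, :ncols] = body.sum(axis=0)
        full[nrows, ncols] = body.sum()
        cols = [f"c{j}" for j in range(ncols)] + ["total"]
        df = pd.DataFrame(full, columns=cols)
        df.insert(0, "label", [f"r{i}" for i in range(nrows)] + ["total"])
        out, _ = suppress_small_counts(df, cols, RULES, label_column="label")
        redacted = [[out.iloc[r][c] == RULES.redaction_token for c in cols]
                    for r in range(nrows + 1)]
        if any(any(row) for row in redacted):
            checked += 1
        assert recoverable_cells(redacted, nrows, ncols) == []
    assert checked > 50  # the property was actually exercised


# ----------------------------------------------------------------- rounding

@pytest.mark.parametrize("c,base,expected", [(13, 5, 15), (12, 5, 10), (10, 5, 10),
                                             (2, 4, 4), (0, 5, 0), (7, 1, 7)])
def test_round_count_examples(c, base, expected):
    assert round_count(c, base) == expected


@settings(max_examples=300, deadline=None, derandomize=True)
@given(c=st.integers(min_value=0, max_value=10**6), base=st.integers(min_value=1, max_value=100))
def test_rounding_error_bounded_by_half_base(c, base):
    r = round_count(c, base)
    assert r % base == 0
    assert abs(r - c) <= base / 2


def test_round_counts_table_and_identity_base():
    t = pd.DataFrame({"g": ["a", "b"], "n": [13, 2]})
    rounded = round_counts(t, ["n"], DisclosureRules(rounding_base=5))
    assert list(rounded["n"]) == [15, 0]
    same = round_counts(t, ["n"], DisclosureRules(rounding_base=1))
    assert list(same["n"]) == [13, 2]


# ------------------------------------------------------------------ release

@pytest.fixture
def ran_workspace(diamond_workspace):
    spec = parse_project((diamond_workspace / "project.yaml").read_text())
    report = run(spec, diamond_workspace)
    assert report.ok
    return diamond_workspace


def test_clean_aggregate_released_with_manifest(ran_workspace):
    # values.csv holds a safe aggregate (mean_age 32 > threshold is fine: not
    # a count <= 5)
    manifest, findings = release(ran_workspace, ["output/values.csv"], RULES)
    assert findings == []
    assert [f["path"] for f in manifest.files] == ["output/values.csv"]
    assert revalidate_manifest(ran_workspace, manifest, RULES) == []


def test_small_count_rejected_with_finding(ran_workspace):
    # counts.csv holds 'all,2' (the demo extraction has 2 rows): small cell
    manifest, findings = release(ran_workspace, ["output/counts.csv"], RULES)
    assert manifest.files == []
    assert findings and findings[0].rule == "small-cell"


def test_highly_sensitive_path_refused(ran_workspace):
    with pytest.raises(ReleaseError, match="highly_sensitive"):
        release(ran_workspace, ["output/dataset.csv"], RULES)


def test_undeclared_path_refused(ran_workspace):
    (ran_workspace / "output" / "rogue.csv").write_text("a,b\n9,9\n")
    with pytest.raises(ReleaseError, match="rogue"):
        release(ran_workspace, ["output/rogue.csv"], RULES)


def test_stale_file_refused(ran_workspace):
    victim = ran_workspace / "output" / "values.csv"
    victim.write_text(victim.read_text() + "tampered,1000000\n")
    with pytest.raises(ReleaseError, match="modified"):
        release(ran_workspace, ["output/values.csv"], RULES)


def test_released_files_never_contain_patient_id(ran_workspace, db3, demo_dd):
    """A row-level table laundered through a moderately_sensitive path is still
    rejected by the schema check."""
    from trekit.query import execute
    # overwrite values.csv with row-level data, re-running its action so the
    # digest matches (simulating a badly written action)
    (ran_workspace / "analysis" / "values.py").write_text(
        "open('output/values.csv', 'w').write(open('output/dataset.csv').read())\n")
    spec = parse_project((ran_workspace / "project.yaml").read_text())
    run(spec, ran_workspace)
    manifest, findings = release(ran_workspace, ["output/values.csv"], RULES)
    assert manifest.files == []
    assert any(f.rule == "no-patient-id" for f in findings)


def test_release_is_idempotent_modulo_timestamp(ran_workspace):
    m1, _ = release(ran_workspace, ["output/values.csv"], RULES)
    m2, _ = release(ran_workspace, ["output/values.csv"], RULES)
    assert m1.files == m2.files
    assert m1.rules == m2.rules


def test_release_recorded_in_job_log(ran_workspace):
    from trekit.pipeline import read_log, verify_log
    release(ran_workspace, ["output/values.csv"], RULES)
    entries = read_log(ran_workspace)
    assert entries[-1]["action"] == "__release__"
    assert verify_log(entries) == (True, None)
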