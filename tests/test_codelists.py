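import pytest

from trekit.codelists import (
    Codelist,
    CodingSystemRelease,
    Concept,
    add_manual,
    check_rot,
    detect_corruption,
    read_codelist_csv,
    read_release_csv,
    reconstruct_entries,
    record_search,
    update_to_release,
    version_chain,
    write_codelist_csv,
    write_release_csv,
)
from trekit.errors import CodelistError
from trekit.fixtures import (
    clean_codelist,
    clean_icd10_codelist,
    corrupted_codelist,
    release_base,
    release_updated,
    search_release,
)


# ------------------------------------------------------------- CSV round trip

def test_csv_round_trip_lossless(tmp_path):
    cl = clean_codelist()
    write_codelist_csv(cl, tmp_path / "cl.csv")
    back = read_codelist_csv(tmp_path / "cl.csv", codelist_id=cl.codelist_id,
                             coding_system=cl.coding_system,
                             system_version=cl.system_version)
    assert back.entries == cl.entries


def test_snomed_length_code_survives(tmp_path):
    cl = Codelist("x", "SNOMEDCT", "r", (("60234000", "a term"),))
    write_codelist_csv(cl, tmp_path / "cl.csv")
    assert read_codelist_csv(tmp_path / "cl.csv").entries[0][0] == "60234000"


def test_duplicate_code_named_in_error(tmp_path):
    (tmp_path / "dup.csv").write_text("code,term\n111000,a\n111000,b\n")
    with pytest.raises(CodelistError, match="111000"):
        read_codelist_csv(tmp_path / "dup.csv")


def test_missing_code_column(tmp_path):
    (tmp_path / "bad.csv").write_text("id,term\n1,a\n")
    with pytest.raises(CodelistError, match="code"):
        read_codelist_csv(tmp_path / "bad.csv")


def test_release_csv_round_trip(tmp_path):
    rel = release_updated()
    write_release_csv(rel, tmp_path / "r.csv")
    back = read_release_csv(tmp_path / "r.csv", system="generic", release_tag=rel.release_tag)
    assert back.concepts == dict(rel.concepts)


# ------------------------------------------------------------- corruption

def test_exponent_and_float_cast_flagged():
    report = detect_corruption(corrupted_codelist())
    kinds = {f.code: f.kind for f in report.findings}
    assert kinds == {"1.00023E+15": "exponent-notation", "123456789.0": "float-cast"}


def test_clean_lists_pass():
    assert detect_corruption(clean_codelist()).ok
    assert detect_corruption(clean_icd10_codelist()).ok


def test_zero_run_needs_a_rounded_sibling():
    lonely = Codelist("a", "generic", "r", (("12300000", "x"),))
    assert detect_corruption(lonely).ok  # no sibling: could be genuine
    pair = Codelist("b", "generic", "r", (("12300000", "x"), ("12345678", "y")))
    report = detect_corruption(pair)
    assert [f.kind for f in report.findings] == ["suspicious-zero-run"]
    assert report.findings[0].code == "12300000"


# --------------------------------------------------------------------- rot

def test_same_release_rot_score_zero():
    report = check_rot(clean_codelist(), release_base())
    assert report.rot_score == 0.0
    assert set(report.categories.values()) == {"active-unchanged"}


def test_one_retirement_in_four_scores_quarter():
    report = check_rot(clean_codelist(), release_updated())
    assert report.rot_score == pytest.approx(0.25)
    assert report.categories["333000"] == "retired-with-replacement"
    assert report.replacements == {"333000": "555000"}


def test_unknown_code_categorised():
    cl = add_manual(clean_codelist(), "777777", "made up")
    report = check_rot(cl, release_updated())
    assert report.categories["777777"] == "unknown-to-release"


def test_system_mismatch_rejected():
    with pytest.raises(CodelistError, match="system"):
        check_rot(clean_icd10_codelist(), release_base())


def test_rot_monotone_in_retirements():
    """Retiring more concepts never lowers the rot score."""
    cl = clean_codelist()
    base = release_base()
    score = check_rot(cl, base).rot_score
    concepts = dict(base.concepts)
    for code in list(concepts):
        concepts[code] = Concept(concepts[code].term, "retired")
        more = CodingSystemRelease("generic", "r+", dict(concepts))
        new_score = check_rot(cl, more).rot_score
        assert new_score >= score
        score = new_score
    assert score == 1.0


# ----------------------------------------------------------------- updates

def test_update_no_rot_only_metadata_changes():
    cl = clean_codelist()
    new = update_to_release(cl, release_base(), "accept_replacements")
    assert new.entries == cl.entries
    assert (new.version, new.parent_version) == (2, 1)
    assert cl.version == 1  # original untouched


def test_accept_replacements_swaps_retired_code():
    new = update_to_release(clean_codelist(), release_updated(), "accept_replacements")
    codes = new.codes
    assert "333000" not in codes and "555000" in codes
    assert len(codes) == 4
    assert any("333000 -> 555000" in n for n in new.notes)


def test_drop_retired_shrinks_by_retired_count():
    new = update_to_release(clean_codelist(), release_updated(), "drop_retired")
    assert len(new.codes) == 3
    assert "333000" not in new.codes


def test_manual_policy_requires_resolutions():
    with pytest.raises(CodelistError, match="333000"):
        update_to_release(clean_codelist(), release_updated(), "manual")
    new = update_to_release(clean_codelist(), release_updated(), "manual",
                            manual_resolutions={"333000": None})
    assert len(new.codes) == 3


def test_version_chain_walks_to_version_one():
    v1 = clean_codelist()
    v2 = update_to_release(v1, release_updated(), "accept_replacements")
    v3 = update_to_release(v2, release_updated(), "accept_replacements")
    chain = version_chain([v1, v2, v3])
    assert [c.version for c in chain] == [1, 2, 3]
    with pytest.raises(CodelistError, match="parent"):
        version_chain([v1, v3])


# ------------------------------------------------------------------ search

def test_search_matches_substring_case_insensitively():
    empty = Codelist("scratch", "generic", "2023-06", ())
    _, record = record_search(empty, "Hypertension", search_release())
    assert record.matched_codes == ("100001", "100002")


def test_search_repeat_reproduces_matches():
    empty = Codelist("scratch", "generic", "2023-06", ())
    _, r1 = record_search(empty, "hypertension", search_release())
    _, r2 = record_search(empty, "hypertension", search_release())
    assert r1.matched_codes == r2.matched_codes


def test_empty_query_rejected():
    with pytest.raises(CodelistError, match="non-empty"):
        record_search(clean_codelist(), "", search_release())


def test_only_included_matches_join_the_list():
    empty = Codelist("scratch", "generic", "2023-06", ())
    updated, record = record_search(empty, "hypertension", search_release(),
                                    include=["100001"], exclude=["100002"])
    assert updated.codes == ("100001",)
    assert record.excluded == ("100002",)


def test_replaying_searches_reconstructs_entries():
    rel = search_release()
    cl = Codelist("built", "generic", rel.release_tag, ())
    cl, _ = record_search(cl, "hypertension", rel, include=["100001", "100002"])
    cl, _ = record_search(cl, "asthma", rel, include=["100005"])
    cl = add_manual(cl, "100006", "migraine")
    assert reconstruct_entries(cl, rel) == cl.codes
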