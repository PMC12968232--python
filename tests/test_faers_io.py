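"""Parsing, deduplication and case assembly."""

from datetime import date

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import faerspv as f
from faerspv.faers_io import (
    MissingTableError,
    normalize_age,
    normalize_weight,
    read_delimited,
)

from conftest import PT_SOC, write_demo_file


# ---------------------------------------------------------------------- dates
@pytest.mark.parametrize(
    "raw, kind, value",
    [
        ("20150801", "full", date(2015, 8, 1)),
        ("20160229", "full", date(2016, 2, 29)),  # leap day
        ("201508", "partial", None),
        ("2015", "partial", None),
        ("", "invalid", None),
        ("20151340", "invalid", None),  # impossible month
        ("20150231", "invalid", None),  # impossible day
        ("201513", "invalid", None),
        ("8/1/2015", "invalid", None),
        (None, "invalid", None),
    ],
)
def test_parse_faers_date(raw, kind, value):
    d = f.parse_faers_date(raw)
    assert d.kind == kind
    assert d.value == value


def test_partial_date_keeps_year_for_tabulation():
    d = f.parse_faers_date("201508")
    assert (d.year, d.month) == (2015, 8)


# ------------------------------------------------------------------- reading
def test_demo_row_count_is_lines_minus_header(tmp_path):
    p = write_demo_file(
        tmp_path / "DEMO15Q3.txt",
        ["1$10$20200101$$$$$$$$", "2$11$20200102$$$$$$$$"],
    )
    df, issues = read_delimited(p)
    assert len(df) == 2
    assert issues["bad_rows"] == 0


def test_trailing_delimiter_and_malformed_rows(tmp_path):
    p = tmp_path / "odd.txt"
    p.write_text(
        "primaryid$caseid$fda_dt$\n1$10$20200101$\n2$11$20200101$extra$junk$x\n",
        encoding="utf-8",
    )
    df, issues = read_delimited(p)
    assert list(df.columns) == ["primaryid", "caseid", "fda_dt"]
    assert len(df) == 1
    assert issues["bad_rows"] == 1


def test_latin1_fallback_counts_suspect_bytes(tmp_path):
    p = tmp_path / "enc.txt"
    p.write_bytes(b"primaryid$caseid$fda_dt\n1$10\xe9$20200101\n")
    df, issues = read_delimited(p)
    assert len(df) == 1
    assert issues["suspect_bytes"] == 1


def test_read_quarter_parses_typed_rows(tiny_quarter):
    t = f.read_quarter(tiny_quarter, "2015Q3")
    assert len(t.demo) == 3
    assert set(t.drug["role"]) == {"PS", "C"}
    ps = t.drug[t.drug["role"] == "PS"]
    assert "Orkambi" in set(ps["drugname"])


def test_read_quarter_missing_table_names_it(tiny_quarter):
    (tiny_quarter / "OUTC15Q3.txt").unlink()
    with pytest.raises(MissingTableError, match="OUTC"):
        f.read_quarter(tiny_quarter, "15Q3")


def test_synthetic_round_trip_equality(tmp_path, small_dataset):
    cfg, tables, _ = small_dataset
    out, _ = f.generate_dataset(cfg, tmp_path)
    back = f.read_quarter(out, cfg.quarter)
    for name in ("demo", "drug", "reac", "indi", "ther", "outc"):
        cols = list(tables.table(name).columns)
        a = tables.table(name).fillna("").sort_values(cols).reset_index(drop=True)
        b = back.table(name).fillna("").sort_values(cols).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
    assert back.deleted_caseids == tables.deleted_caseids


# -------------------------------------------------------------- deduplication
def test_dedup_keeps_most_recent_fda_dt():
    demo = pd.DataFrame(
        {"primaryid": ["1001", "1002"], "caseid": ["100", "100"],
         "fda_dt": ["20160101", "20170101"]}
    )
    assert f.deduplicate(demo) == {"1002"}


def test_dedup_tie_keeps_highest_primaryid():
    demo = pd.DataFrame(
        {"primaryid": ["2001", "2002"], "caseid": ["200", "200"],
         "fda_dt": ["20200101", "20200101"]}
    )
    assert f.deduplicate(demo) == {"2002"}


def test_dedup_single_row_and_unparseable_sorts_oldest():
    demo = pd.DataFrame(
        {"primaryid": ["1", "2", "3"], "caseid": ["9", "8", "8"],
         "fda_dt": ["20200101", "", "20000101"]}
    )
    # caseid 8: the unparseable date loses even to an old valid date
    assert f.deduplicate(demo) == {"1", "3"}


def test_dedup_duplicate_primaryid_is_error():
    demo = pd.DataFrame(
        {"primaryid": ["1", "1"], "caseid": ["9", "8"],
         "fda_dt": ["20200101", "20200102"]}
    )
    with pytest.raises(ValueError, match="duplicate primaryid"):
        f.deduplicate(demo)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 30), st.sampled_from(["20200101", "20210601", ""])),
        min_size=1,
        max_size=40,
    )
)
def test_dedup_idempotent_and_bounded(rows):
    demo = pd.DataFrame(
        {
            "primaryid": [str(i) for i in range(len(rows))],
            "caseid": [str(c) for c, _ in rows],
            "fda_dt": [d for _, d in rows],
        }
    )
    kept = f.deduplicate(demo)
    assert len(kept) == demo["caseid"].nunique()
    again = f.deduplicate(demo[demo["primaryid"].isin(kept)])
    assert again == kept


def test_remove_deleted_cases():
    demo = pd.DataFrame(
        {"primaryid": ["1001", "1002"], "caseid": ["100", "101"],
         "fda_dt": ["20200101", "20200101"]}
    )
    kept = {"1001", "1002"}
    assert f.remove_deleted_cases(kept, set(), demo) == kept
    assert f.remove_deleted_cases(kept, {"101"}, demo) == {"1001"}


def test_planted_deletions_remove_exactly_that_many(small_dataset):
    cfg, tables, truth = small_dataset
    retained = f.deduplicate(tables.demo)
    after = f.remove_deleted_cases(retained, tables.deleted_caseids, tables.demo)
    assert len(retained) - len(after) == len(truth.deleted_caseids)
    assert len(after) == truth.n_reports_final


# ------------------------------------------------------------------ selection
def test_select_drug_reports_role_and_case_insensitive():
    drug = pd.DataFrame(
        {
            "primaryid": ["1", "2", "3"],
            "role": ["PS", "C", "PS"],
            "drugname": ["Orkambi", "ORKAMBI", "KALYDECO"],
        }
    )
    assert f.select_drug_reports(drug, {"ORKAMBI"}) == {"1"}
    assert f.select_drug_reports(drug, {"KALYDECO", "IVACAFTOR"}) == {"3"}
    with pytest.raises(ValueError):
        f.select_drug_reports(drug, set())


def test_exact_match_does_not_substring():
    drug = pd.DataFrame(
        {"primaryid": ["1"], "role": ["PS"], "drugname": ["LUMACAFTOR/IVACAFTOR"]}
    )
    assert f.select_drug_reports(drug, {"IVACAFTOR"}) == set()
    assert f.select_drug_reports(drug, {"LUMACAFTOR/IVACAFTOR"}) == {"1"}


def test_normalize_drug_name():
    assert f.normalize_drug_name(" Orkambi. ") == "ORKAMBI"
    assert f.normalize_drug_name("VX-809/VX-770") == "VX 809 VX 770"


# ------------------------------------------------------------------- assembly
def test_unit_normalization():
    assert normalize_age(24, "MON") == pytest.approx(2.0)
    assert normalize_age(3, "DEC") == pytest.approx(30.0)
    assert normalize_weight(110, "LBS") == pytest.approx(49.9, abs=0.05)
    assert normalize_age("", "YR") is None
    assert normalize_weight(-4, "KG") is None


def test_assemble_cases_from_tiny_quarter(tiny_quarter):
    t = f.read_quarter(tiny_quarter, "15Q3")
    cases = f.assemble_cases(t, {"1001", "1002", "1003"}, PT_SOC, ("ORKAMBI",))
    by_id = {c.primaryid: c for c in cases}
    c1 = by_id["1001"]
    assert c1.age_years == pytest.approx(2.0)
    assert c1.weight_kg == pytest.approx(49.9, abs=0.05)
    assert c1.pts == {"Cough", "Dyspnoea"} and c1.n_records == 2
    assert c1.earliest_target_start == date(2015, 8, 1)
    assert c1.event_date == date(2015, 9, 13)
    assert not c1.is_monotherapy(("ORKAMBI",))
    c2 = by_id["1002"]
    assert c2.fatal and c2.frequency == "QD"
    assert c2.earliest_target_start is None  # partial start date unusable
    # 1003's drug is not a target synonym: no target rows, still a case
    assert by_id["1003"].target_drug_rows == []


def test_every_pt_gets_exactly_one_soc(assembled):
    cfg, truth, retained, target_ids, cases, records = assembled
    assert records["soc"].notna().all()
    for c in cases:
        assert c.socs <= set(cfg.pt_to_soc.values()) | {"UNMAPPED"}


def test_record_table_matches_truth(assembled):
    cfg, truth, retained, target_ids, cases, records = assembled
    assert len(records) == truth.n_records
    assert sum(c.n_records for c in cases) == records.merge(
        pd.DataFrame({"primaryid": [c.primaryid for c in cases]}), on="primaryid"
    ).shape[0]
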