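"""Disproportionality statistics and screening."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import faerspv as f
from faerspv.signals import SignalResult


def brute_force_cells(records, term, level="pt"):
    """Independent nested-loop recount of the 2x2 for one term."""
    a = b = c = d = 0
    for row in records.itertuples(index=False):
        t = getattr(row, level)
        if row.is_target and t == term:
            a += 1
        elif row.is_target:
            b += 1
        elif t == term:
            c += 1
        else:
            d += 1
    return a, b, c, d


# ---------------------------------------------------------------- contingency
def test_build_contingency_exhaustive_four_records():
    rec = pd.DataFrame(
        {
            "primaryid": ["1", "1", "2", "2"],
            "pt": ["p", "q", "p", "q"],
            "is_target": [True, True, False, False],
        }
    )
    t = f.build_contingency(rec, rec["is_target"], rec["pt"] == "p")
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
    with pytest.raises(ValueError):
        f.build_contingency(rec.iloc[:0], lambda r: r["is_target"], lambda r: r["pt"] == "p")


def test_contingency_validates_cells():
    with pytest.raises(ValueError):
        f.ContingencyTable(-1, 1, 1, 1)
    with pytest.raises(ValueError):
        f.ContingencyTable(0, 0, 0, 0)


# ------------------------------------------------------------------------ ROR
def test_ror_uniform_table():
    ror, lo, hi, corr = f.ror_estimate(f.ContingencyTable(10, 10, 10, 10))
    assert ror == pytest.approx(1.0)
    assert math.log(lo) == pytest.approx(-math.log(hi))
    assert not corr


def test_ror_hand_arithmetic():
    ror, lo, hi, _ = f.ror_estimate(f.ContingencyTable(20, 80, 100, 800))
    assert ror == pytest.approx(2.000)
    assert lo == pytest.approx(1.174, abs=0.005)
    assert hi == pytest.approx(3.407, abs=0.005)


def test_ror_haldane_correction():
    t = f.ContingencyTable(0, 10, 10, 100)
    ror, lo, hi, corr = f.ror_estimate(t)
    assert corr
    expect = (0.5 * 100.5) / (10.5 * 10.5)
    assert ror == pytest.approx(expect)
    r2 = f.ror_estimate(t, haldane=False)
    assert math.isnan(r2[0]) and not r2[3]


def test_ror_row_swap_is_reciprocal():
    t = f.ContingencyTable(7, 13, 31, 59)
    swapped = f.ContingencyTable(31, 59, 7, 13)
    assert f.ror_estimate(t)[0] == pytest.approx(1.0 / f.ror_estimate(swapped)[0])


@given(st.integers(1, 100), st.integers(100, 500), st.integers(100, 500),
       st.integers(100, 2000))
@settings(max_examples=60, deadline=None)
def test_ror_and_ic_monotone_in_a(a, b, c, d):
    """More target-event records -> strictly stronger signal.  (For the
    shrunk IC this holds when the a cell does not dominate its margins,
    which the strategy enforces; the ROR is monotone unconditionally.)"""
    t1 = f.ContingencyTable(a, b, c, d)
    t2 = f.ContingencyTable(a + 1, b, c, d)
    assert f.ror_estimate(t2)[0] > f.ror_estimate(t1)[0]
    assert f.bcpnn_ic(t2)[0] > f.bcpnn_ic(t1)[0]


# ---------------------------------------------------------------------- BCPNN
def test_ic_zero_under_independence():
    ic, ic025 = f.bcpnn_ic(f.ContingencyTable(5, 5, 5, 5))
    assert ic == pytest.approx(0.0)
    assert ic025 < 0


def test_ic_hand_arithmetic():
    # N=1000, a=20, a+b=100, a+c=120 -> E=12
    t = f.ContingencyTable(20, 80, 100, 800)
    ic, ic025 = f.bcpnn_ic(t)
    assert ic == pytest.approx(math.log2(20.5 / 12.5), abs=1e-9)
    assert ic025 == pytest.approx(ic - 3.3 / math.sqrt(20.5) - 2 / 20.5**1.5, abs=1e-9)
    assert ic025 == pytest.approx(-0.037, abs=2e-3)


@given(st.integers(1, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
@settings(max_examples=60, deadline=None)
def test_ic025_below_ic_both_variants(a, b, c, d):
    t = f.ContingencyTable(a, b, c, d)
    for variant in ("shrinkage", "gamma"):
        ic, ic025 = f.bcpnn_ic(t, variant=variant)
        assert ic025 < ic


def test_unknown_variant_rejected():
    with pytest.raises(ValueError):
        f.bcpnn_ic(f.ContingencyTable(1, 1, 1, 1), variant="mgps")


# -------------------------------------------------------------------- flagging
def _sig(n, lo, ic025):
    return SignalResult(
        term="x", level="PT", n_cases=n, ror=lo + 1, ror_low=lo, ror_high=lo + 2,
        ic=ic025 + 1, ic025=ic025, flagged=False,
    )


@pytest.mark.parametrize(
    "n, lo, ic025, expect",
    [
        (81, 1.37, 0.45, True),   # the depression-signal pattern
        (10, 0.99, 0.50, False),
        (2, 1.50, 0.50, False),
        (3, 1.01, 0.01, True),
    ],
)
def test_flag_signal_dual_threshold(n, lo, ic025, expect):
    assert f.flag_signal(_sig(n, lo, ic025)) is expect


# ------------------------------------------------------------------- screening
def test_screen_equals_brute_force(assembled):
    cfg, truth, retained, target_ids, cases, records = assembled
    rec = records.copy()
    rec["is_target"] = rec["primaryid"].isin(target_ids)
    results = f.screen_records(rec)
    assert results, "no terms screened"
    for r in results:
        cells = brute_force_cells(rec, r.term)
        assert (r.table.a, r.table.b, r.table.c, r.table.d) == cells
        ror, lo, hi, _ = f.ror_estimate(r.table)
        assert r.ror == pytest.approx(ror, abs=1e-12)


def test_soc_screen_bounded_by_soc_count(assembled):
    cfg, truth, retained, target_ids, cases, records = assembled
    res = f.screen_all(records, target_ids, level="SOC")
    assert 0 < len(res) <= len(set(cfg.pt_to_soc.values()))
    # cell conservation at SOC level: one record per (report, SOC)
    n_soc_records = records.drop_duplicates(["primaryid", "soc"]).shape[0]
    for r in res:
        assert r.table.n == n_soc_records


def test_results_sorted_by_case_count(assembled):
    cfg, truth, retained, target_ids, cases, records = assembled
    res = f.screen_all(records, target_ids)
    ns = [r.n_cases for r in res]
    assert ns == sorted(ns, reverse=True)


def test_planted_signal_detected(assembled):
    cfg, truth, retained, target_ids, cases, records = assembled
    res = f.screen_all(records, target_ids)
    dep = next(r for r in res if r.term == "Depression")
    assert dep.flagged
    assert dep.ror == pytest.approx(
        truth.expected_ror[("ORKAMBI", "Depression")], rel=0.5
    )


# ----------------------------------------------------------------- sensitivity
def test_restrict_monotherapy_rules(assembled):
    cfg, truth, retained, target_ids, cases, records = assembled
    mono = f.restrict_monotherapy(cases, ("ORKAMBI",))
    assert {c.primaryid for c in mono} == set(truth.monotherapy_primaryids)
    for c in mono:
        assert c.all_drug_names <= {"ORKAMBI"}


def test_restrict_monotherapy_examples():
    from faerspv.faers_io import CaseReport

    def case(names):
        return CaseReport(
            primaryid="1", caseid="1", age_years=None, sex=None, weight_kg=None,
            reporter=None, country=None, year=None, frequency=None, dose=None,
            target_drug_rows=[], all_drug_names=frozenset(names),
            pts=frozenset({"Cough"}), socs=frozenset({"R"}), outcomes=frozenset(),
            indications=frozenset(), earliest_target_start=None, event_date=None,
        )

    kept = f.restrict_monotherapy([case({"ORKAMBI"}), case({"ORKAMBI", "PULMOZYME"})],
                                  ("ORKAMBI",))
    assert len(kept) == 1


def test_comparator_screen_shared_and_specific_signals():
    cfg = f.SimulationConfig(
        n_reports=6000,
        seed=9,
        planted_signals=(
            ("ORKAMBI", "Cough", 6.0),      # shared across all three drugs
            ("KALYDECO", "Cough", 6.0),
            ("SYMDEKO", "Cough", 6.0),
            ("ORKAMBI", "Depression", 6.0),  # target-specific
        ),
    )
    tables, truth = f.generate_tables(cfg)
    retained = f.remove_deleted_cases(
        f.deduplicate(tables.demo), tables.deleted_caseids, tables.demo
    )
    records = f.pt_record_table(tables, retained, cfg.pt_to_soc)
    target = f.select_drug_reports(tables.drug, ("ORKAMBI",)) & retained
    primary = {r.term: r for r in f.screen_all(records, target)}
    assert primary["Cough"].flagged and primary["Depression"].flagged
    for name in ("KALYDECO", "SYMDEKO"):
        comp = {
            r.term: r
            for r in f.comparator_screen(records, tables.drug, (name,), name)
        }
        assert comp["Cough"].flagged
        assert not comp.get("Depression", _sig(0, 0.0, -1.0)).flagged
        assert all(r.analysis_tag == f"comparator:{name}" for r in comp.values())


def test_comparator_identical_to_primary_when_same_drug(assembled):
    cfg, truth, retained, target_ids, cases, records = assembled
    tables, _ = f.generate_tables(cfg)
    primary = f.signal_table(f.screen_all(records, target_ids))
    comp = f.signal_table(
        f.comparator_screen(records, tables.drug, ("ORKAMBI",), "self")
    )
    pd.testing.assert_frame_equal(
        primary.drop(columns="analysis_tag"), comp.drop(columns="analysis_tag")
    )


def test_comparator_absent_gives_empty(assembled):
    cfg, truth, retained, target_ids, cases, records = assembled
    tables, _ = f.generate_tables(cfg)
    assert f.comparator_screen(records, tables.drug, ("NO SUCH DRUG",), "none") == []
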