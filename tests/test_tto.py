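"""Time to onset: interval computation, Weibull fitting and failure
classification, nonparametric comparisons."""

from datetime import date

import numpy as np
import pytest
from scipy import stats

import faerspv as f
from faerspv.faers_io import CaseReport
from faerspv.tto import WeibullFit


def make_case(pid="1", start=None, event=None, pts=("Cough",), socs=("R",), **kw):
    base = dict(
        primaryid=pid, caseid=pid, age_years=None, sex=None, weight_kg=None,
        reporter=None, country=None, year=None, frequency=None, dose=None,
        target_drug_rows=[], all_drug_names=frozenset({"ORKAMBI"}),
        pts=frozenset(pts), socs=frozenset(socs), outcomes=frozenset(),
        indications=frozenset(), earliest_target_start=start, event_date=event,
    )
    base.update(kw)
    return CaseReport(**base)


# ----------------------------------------------------------------------- TTO
def test_compute_tto_calendar_arithmetic():
    # spans the 2016 leap day
    c = make_case(start=date(2015, 8, 1), event=date(2016, 4, 13))
    samples, excl = f.compute_tto([c])
    assert samples[0].days == 256
    assert not excl


def test_compute_tto_exclusion_reasons():
    cases = [
        make_case("1", date(2016, 1, 1), date(2015, 1, 1)),  # event before start
        make_case("2", None, date(2016, 1, 1)),              # missing start
        make_case("3", date(2016, 1, 1), date(2016, 1, 1)),  # same day -> days 0
        make_case("4", date(1980, 1, 1), date(2024, 1, 1)),  # > 25 years
        make_case("5", date(2016, 1, 1), date(2016, 1, 14)),
    ]
    samples, excl = f.compute_tto(cases)
    assert [s.primaryid for s in samples] == ["5"]
    assert excl["non_positive"] == 2
    assert excl["incomplete_dates"] == 1
    assert excl["implausible"] == 1


@pytest.mark.parametrize(
    "days, label",
    [(1, "1-30"), (15, "1-30"), (30, "1-30"), (31, "31-60"),
     (256, "241-270"), (360, "331-360"), (361, ">360"), (5000, ">360")],
)
def test_bin_tto(days, label):
    assert f.bin_tto(days) == label


def test_bin_counts_sum_to_samples():
    cases = [
        make_case(str(i), date(2016, 1, 1),
                  date(2016, 1, 1) + __import__("datetime").timedelta(days=d))
        for i, d in enumerate([5, 40, 200, 400, 800])
    ]
    samples, _ = f.compute_tto(cases)
    table = f.binned_counts(samples)
    assert table["n"].sum() == len(samples) == 5
    assert table.loc[table["interval"] == ">360", "n"].iloc[0] == 2


# -------------------------------------------------------------------- Weibull
def test_weibull_fit_matches_scipy():
    rng = np.random.default_rng(0)
    x = 300 * rng.weibull(1.4, size=800)
    fit = f.weibull_fit(x)
    k, _, lam = stats.weibull_min.fit(x, floc=0)
    assert fit.shape == pytest.approx(k, rel=1e-4)
    assert fit.scale == pytest.approx(lam, rel=1e-4)


def test_weibull_exponential_special_case_coverage():
    hits = 0
    for s in range(20):
        rng = np.random.default_rng(s)
        x = rng.exponential(100, size=2000)
        lo, hi = f.weibull_fit(x).shape_ci
        hits += lo <= 1.0 <= hi
    assert hits >= 18  # >= 90% of seeds


def test_weibull_small_degenerate_inputs():
    with pytest.raises(ValueError):
        f.weibull_fit([5.0] * 12)
    with pytest.raises(ValueError):
        f.weibull_fit([1.0, 2.0, 3.0])  # below minimum n
    with pytest.raises(ValueError):
        f.weibull_fit([1.0] * 9 + [-1.0] + [2.0] * 2)
    # two distinct values only: wide CI, no crash
    fit = f.weibull_fit([1.0] * 5 + [10.0] * 5)
    assert fit.shape > 0 and fit.shape_ci[0] < fit.shape < fit.shape_ci[1]


@pytest.mark.parametrize(
    "shape, ci, expect",
    [(0.79, (0.75, 0.82), "early"), (1.02, (0.9, 1.1), "random"),
     (1.5, (1.2, 1.9), "wearout")],
)
def test_classify_failure(shape, ci, expect):
    fit = WeibullFit(shape=shape, scale=300.0, shape_ci=ci,
                     scale_ci=(250, 350), n=100, log_likelihood=0.0)
    assert f.classify_failure(fit) == expect
    assert fit.failure_class == expect


# ------------------------------------------------------------------ summaries
def test_soc_summary_conventions():
    import datetime as dt

    cases = [
        make_case("1", date(2016, 1, 1), date(2016, 1, 14), socs=("A",)),
    ]
    samples, _ = f.compute_tto(cases)
    df = f.soc_tto_summary(samples)
    assert df.loc[0, ["n", "median", "q1", "q3"]].tolist() == [1, 13.0, 13.0, 13.0]

    cases = [
        make_case(str(i), date(2016, 1, 1),
                  date(2016, 1, 1) + dt.timedelta(days=d), socs=("A", "B"))
        for i, d in enumerate([10, 20, 30, 40])
    ]
    samples, _ = f.compute_tto(cases)
    df = f.soc_tto_summary(samples).set_index("soc")
    # midpoint median; every sample feeds both of its SOCs
    assert df.loc["A", "median"] == 25.0
    assert df.loc["B", "n"] == 4


def test_soc_scale_ordering_preserved_in_medians():
    rng = np.random.default_rng(7)
    samples = []
    for soc, scale in (("fast", 30), ("mid", 120), ("slow", 500)):
        for i, w in enumerate(np.maximum(1, np.ceil(scale * rng.weibull(1.2, 400)))):
            samples.append(
                f.TTOSample(primaryid=f"{soc}{i}", days=int(w),
                            pts=frozenset(), socs=frozenset({soc}))
            )
    med = f.soc_tto_summary(samples).set_index("soc")["median"]
    assert med["fast"] < med["mid"] < med["slow"]


# ---------------------------------------------------------------------- tests
def test_logrank_identical_groups():
    chi2, df, p = f.logrank_test([[1, 2, 3, 4], [1, 2, 3, 4]])
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert (df, p) == (1, pytest.approx(1.0))


def test_logrank_hand_computed_instance():
    chi2, df, p = f.logrank_test([[1, 3], [2, 4]])
    assert chi2 == pytest.approx(0.6154, abs=1e-3)  # (2/3)^2 / (13/18)
    assert df == 1


def test_logrank_three_groups_df():
    chi2, df, p = f.logrank_test([[1, 5, 9], [2, 6, 10], [3, 7, 11]])
    assert df == 2 and 0 <= p <= 1


def test_logrank_empty_group_errors():
    with pytest.raises(ValueError):
        f.logrank_test([[1, 2], []])


def test_wilcoxon_exact_and_tie_paths():
    stat, p = f.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)  # 2 / C(6,3)
    _, p = f.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_wilcoxon_power_grows_with_shift():
    rng = np.random.default_rng(1)
    base = rng.normal(0, 1, 60)
    ps = [f.wilcoxon_rank_sum(base, rng.normal(shift, 1, 60))[1]
          for shift in (0.2, 1.0, 2.5)]
    assert ps[0] > ps[1] > ps[2]


def test_dunn_identical_groups_not_significant():
    g = list(range(1, 21))
    df = f.dunn_pairwise([g, g, g])
    assert (df["p_adj"] > 0.9).all()
    assert (df["p_adj"] >= df["p"] - 1e-12).all()


def test_dunn_one_shifted_group():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 80)
    b = rng.normal(0, 1, 80)
    c = rng.normal(3, 1, 80)
    df = f.dunn_pairwise([a, b, c]).set_index(["group_i", "group_j"])
    assert df.loc[(0, 2), "p_adj"] < 0.001
    assert df.loc[(1, 2), "p_adj"] < 0.001
    assert df.loc[(0, 1), "p_adj"] > 0.05


def test_dunn_small_group_excluded():
    df = f.dunn_pairwise([[1], list(range(10)), list(range(5, 15)),
                          list(range(2, 12))])
    assert set(df["group_i"]) | set(df["group_j"]) == {1, 2, 3}
    with pytest.raises(ValueError):
        f.dunn_pairwise([[1], [2], list(range(10))])
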