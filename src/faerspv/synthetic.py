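"""Synthetic FAERS quarter generator with known ground truth.

Emulates the structure of spontaneous adverse-event reporting data: each
report carries one primary-suspect drug drawn from a catalog, a set of
reaction preferred terms drawn per-PT from a drug-conditional multinomial
reporting model, demographics with realistic missingness, therapy-start /
event-date pairs consistent with Weibull-distributed onset intervals,
injected duplicate case versions (same CASEID, later FDA_DT, higher
PRIMARYID) and deleted-case lists.

Drug-event associations are planted as odds multipliers on the background
PT probability: ``p'/(1-p') = theta * p/(1-p)``.  Because the
disproportionality counting unit downstream is the PT *record*, the exact
expected reporting odds ratio of a planted pair is ``p'/p`` (4.63 for
theta=5 on background 0.02), which :class:`GroundTruth` records; rejection
sampling of empty-PT reports scales both cells of each drug row equally
and leaves that expectation unchanged.

Everything is deterministic under a fixed seed, including the emitted
files (byte-identical).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .faers_io import QuarterTables, normalize_drug_name

TARGET_DRUG = "ORKAMBI"

_DEFAULT_DRUGS: tuple[tuple[str, float], ...] = (
    ("ORKAMBI", 0.10),
    ("KALYDECO", 0.08),
    ("SYMDEKO", 0.08),
) + tuple((f"OTHER DRUG {i:02d}", 0.0925) for i in range(1, 9))

_DEFAULT_PTS: tuple[tuple[str, str, float], ...] = tuple(
    (pt, soc, 0.02)
    for soc, pts in (
        (
            "Infections and infestations",
            (
                "Infective pulmonary exacerbation of cystic fibrosis",
                "Pneumonia",
                "Infection",
                "Sinusitis",
                "Nasopharyngitis",
            ),
        ),
        (
            "Respiratory, thoracic and mediastinal disorders",
            ("Dyspnoea", "Cough", "Haemoptysis", "Respiration abnormal", "Bronchospasm"),
        ),
        (
            "Gastrointestinal disorders",
            ("Nausea", "Vomiting", "Diarrhoea", "Constipation", "Abdominal pain"),
        ),
        (
            "Psychiatric disorders",
            ("Depression", "Suicidal ideation", "Aggression", "Mood altered", "Anxiety"),
        ),
        (
            "Skin and subcutaneous tissue disorders",
            ("Rash", "Pruritus", "Urticaria", "Rash papular", "Dry skin"),
        ),
        (
            "Metabolism and nutrition disorders",
            (
                "Hypoglycaemia",
                "Decreased appetite",
                "Weight decreased",
                "Dehydration",
                "Metabolic acidosis",
            ),
        ),
    )
    for pt in pts
)

_DEFAULT_MISSING = {
    "age": 0.41,
    "sex": 0.076,
    "weight": 0.82,
    "reporter": 0.05,
    "country": 0.02,
    "frequency": 0.273,
    "dose": 0.454,
    "event_dt": 0.25,
    "start_dt": 0.45,
}

_DEFAULT_CONCOMITANTS: tuple[tuple[str, float], ...] = (
    ("PULMOZYME", 0.60),
    ("CREON", 0.37),
    ("SODIUM CHLORIDE", 0.20),
    ("AZITHROMYCIN", 0.18),
    ("CAYSTON", 0.16),
    ("ZENPEP", 0.14),
    ("TOBRAMYCIN", 0.12),
    ("OMEPRAZOLE", 0.11),
    ("PROAIR HFA", 0.105),
    ("VITAMIN D3", 0.105),
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic reporting model.

    Defaults mirror the clinical-characteristics profile of the real
    lumacaftor/ivacaftor report stream (reporter mix, >80% missing weight,
    BID-dominated dosing, ~1.8% fatal outcomes, Weibull(0.79, 407 d) onset,
    ~44% monotherapy).  ``planted_signals`` holds (drug, pt, theta) odds
    multipliers; the null model plants nothing.
    """

    n_reports: int = 2000
    seed: int = 0
    drug_catalog: tuple[tuple[str, float], ...] = _DEFAULT_DRUGS
    pt_catalog: tuple[tuple[str, str, float], ...] = _DEFAULT_PTS
    planted_signals: tuple[tuple[str, str, float], ...] = ()
    duplicate_fraction: float = 0.05
    deleted_fraction: float = 0.01
    missing_rates: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MISSING))
    partial_date_fraction: float = 0.08
    invalid_date_fraction: float = 0.02
    tto_models: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    default_tto: tuple[float, float] = (0.79, 407.0)
    reporting_lag_mean: float = 30.0
    age_groups: tuple[tuple[float, float, float], ...] = (
        (2, 5, 0.10),
        (6, 11, 0.17),
        (12, 17, 0.23),
        (18, 65, 0.50),
    )
    sex_probs: dict[str, float] = field(default_factory=lambda: {"F": 0.52, "M": 0.48})
    weight_lognormal: tuple[float, float] = (math.log(45.0), 0.4)
    reporter_probs: dict[str, float] = field(
        default_factory=lambda: {"CN": 0.455, "OT": 0.23, "PH": 0.207, "MD": 0.108}
    )
    country_probs: dict[str, float] = field(
        default_factory=lambda: {"US": 0.892, "GB": 0.031, "FR": 0.014, "OTHER": 0.063}
    )
    frequency_probs: dict[str, float] = field(
        default_factory=lambda: {"BID": 0.966, "QD": 0.034}
    )
    dose_probs: dict[str, float] = field(
        default_factory=lambda: {
            "200/125": 0.401,
            "400/250": 0.258,
            "100/125": 0.200,
            "150/188": 0.086,
            "OTHER": 0.055,
        }
    )
    indication_probs: dict[str, float] = field(
        default_factory=lambda: {
            "Cystic fibrosis": 0.976,
            "Product used for unknown indication": 0.022,
        }
    )
    fatal_fraction: float = 0.018
    hospitalized_fraction: float = 0.50
    other_serious_fraction: float = 0.088
    monotherapy_fraction: float = 0.436
    concomitant_catalog: tuple[tuple[str, float], ...] = _DEFAULT_CONCOMITANTS
    quarter: str = "23Q1"
    window_start: str = "20150701"
    window_days: int = 3400

    def __post_init__(self) -> None:
        if not self.drug_catalog or not self.pt_catalog:
            raise ValueError("drug and PT catalogs must be non-empty")
        for _, p in self.drug_catalog:
            _check_prob(p, "drug marginal")
        for _, _, p in self.pt_catalog:
            _check_prob(p, "pt background")
        for d, t, theta in self.planted_signals:
            if theta <= 0:
                raise ValueError(f"theta must be > 0 for ({d}, {t})")
        for frac in (
            self.duplicate_fraction,
            self.deleted_fraction,
            self.fatal_fraction,
            self.monotherapy_fraction,
            self.partial_date_fraction,
            self.invalid_date_fraction,
        ):
            _check_prob(frac, "fraction")
        for v in self.missing_rates.values():
            _check_prob(v, "missing rate")
        for shape, scale in list(self.tto_models.values()) + [self.default_tto]:
            if shape <= 0 or scale <= 0:
                raise ValueError("Weibull shape and scale must be positive")

    @property
    def drug_names(self) -> list[str]:
        return [d for d, _ in self.drug_catalog]

    @property
    def pt_names(self) -> list[str]:
        return [p for p, _, _ in self.pt_catalog]

    @property
    def pt_to_soc(self) -> dict[str, str]:
        return {p: s for p, s, _ in self.pt_catalog}


def _check_prob(p: float, what: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{what} must be in [0, 1], got {p}")


@dataclass
class GroundTruth:
    """Exact injected labels and model expectations for a generated dataset."""

    expected_ror: dict[tuple[str, str], float]
    expected_cells: dict[tuple[str, str], tuple[float, float, float, float]]
    onset_days: dict[str, int]
    injected_duplicates: list[tuple[str, str]]  # (superseded pid, retained pid)
    deleted_caseids: frozenset[str]
    deleted_primaryids: frozenset[str]
    n_reports: int          # base reports generated (before duplication)
    n_demo_rows: int        # DEMO rows written (base + duplicate versions)
    n_reports_final: int    # after dedup and deleted-case removal
    n_records: int          # PT records among final reports
    monotherapy_primaryids: frozenset[str]
    tto_shapes: dict[tuple[str, str] | str, float]
    tallies: dict[str, Counter]


def _odds_boost(p: float, theta: float) -> float:
    """Background probability -> planted probability via odds multiplier."""
    return theta * p / (1.0 - p + theta * p)


def _prob_matrix(config: SimulationConfig) -> np.ndarray:
    drugs = {d: i for i, d in enumerate(config.drug_names)}
    pts = {p: j for j, p in enumerate(config.pt_names)}
    P = np.tile(np.array([p for _, _, p in config.pt_catalog]), (len(drugs), 1))
    for d, t, theta in config.planted_signals:
        if d not in drugs or t not in pts:
            raise ValueError(f"planted signal ({d}, {t}) not in catalogs")
        P[drugs[d], pts[t]] = _odds_boost(P[drugs[d], pts[t]], theta)
    return P


def planted_truth(config: SimulationConfig) -> tuple[dict, dict]:
    """Expected record-level 2x2 cell means and ROR for every (drug, pt).

    Expectations condition on each report carrying at least one PT and are
    scaled to the expected number of reports surviving deduplication and
    deleted-case removal; the ROR is the ratio of expected cells.  Under a
    null configuration every pair's expected ROR is exactly 1.
    """
    P = _prob_matrix(config)
    pi = np.array([p for _, p in config.drug_catalog], dtype=float)
    pi = pi / pi.sum()
    q = np.prod(1.0 - P, axis=1)  # P(no PT | drug)
    cond = P / (1.0 - q)[:, None]  # E[records per report for each pt | drug]
    S = cond.sum(axis=1)
    n_del = round(config.deleted_fraction * config.n_reports)
    n_eff = config.n_reports - n_del
    cells: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    rors: dict[tuple[str, str], float] = {}
    for i, drug in enumerate(config.drug_names):
        others = np.arange(len(pi)) != i
        for j, pt in enumerate(config.pt_names):
            a = n_eff * pi[i] * cond[i, j]
            b = n_eff * pi[i] * (S[i] - cond[i, j])
            c = n_eff * float(pi[others] @ cond[others, j])
            d = n_eff * float(pi[others] @ (S[others] - cond[others, j]))
            cells[(drug, pt)] = (a, b, c, d)
            rors[(drug, pt)] = (a * d) / (b * c)
    return cells, rors


def uniform_pt_catalog(
    n_pts: int, background_p: float = 0.02, n_socs: int = 5
) -> tuple[tuple[str, str, float], ...]:
    """A synthetic PT catalog of ``n_pts`` terms spread over ``n_socs``
    organ classes, all at the same background reporting probability."""
    return tuple(
        (f"PT {j:03d}", f"SOC {j % n_socs}", background_p) for j in range(n_pts)
    )


def generate_records(config: SimulationConfig) -> pd.DataFrame:
    """Sample only the drug-event reporting model, in memory.

    Returns a PT-record table (one row per report x distinct PT) with
    columns ``primaryid``, ``pt``, ``soc`` and ``is_target`` (target =
    ORKAMBI).  Demographics, dates, duplicates and files are skipped, so
    this is the path for large simulation studies of the
    disproportionality statistics; the reporting model itself is
    identical to :func:`generate_tables`.
    """
    rng = np.random.default_rng(config.seed)
    P = _prob_matrix(config)
    pi = np.array([p for _, p in config.drug_catalog], dtype=float)
    pi = pi / pi.sum()
    drug_idx = rng.choice(len(pi), size=config.n_reports, p=pi)
    events = _sample_pt_matrix(rng, P, drug_idx)
    ri, rj = np.nonzero(events)
    pts = np.array(config.pt_names, dtype=object)
    socs = np.array([s for _, s, _ in config.pt_catalog], dtype=object)
    target_idx = (
        config.drug_names.index(TARGET_DRUG) if TARGET_DRUG in config.drug_names else -1
    )
    return pd.DataFrame(
        {
            "primaryid": ri.astype(str),
            "pt": pts[rj],
            "soc": socs[rj],
            "is_target": drug_idx[ri] == target_idx,
        }
    )


def _categorical(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return np.array(keys, dtype=object)[rng.choice(len(keys), size=n, p=p)]


def _sample_pt_matrix(
    rng: np.random.Generator, P: np.ndarray, drug_idx: np.ndarray
) -> np.ndarray:
    """Per-report Bernoulli PT draws, resampling rows until non-empty."""
    prob = P[drug_idx]
    events = rng.random(prob.shape) < prob
    empty = ~events.any(axis=1)
    while empty.any():
        redraw = rng.random((int(empty.sum()), P.shape[1])) < prob[empty]
        events[empty] = redraw
        empty_idx = np.flatnonzero(empty)
        still = ~redraw.any(axis=1)
        empty = np.zeros(len(events), dtype=bool)
        empty[empty_idx[still]] = True
    return events


def generate_tables(config: SimulationConfig) -> tuple[QuarterTables, GroundTruth]:
    """Generate one synthetic quarter in memory.

    Returns the parsed-table representation (identical to what
    :func:`faerspv.faers_io.read_quarter` would produce from the written
    files) plus the exact ground truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drugs = config.drug_names
    pts = config.pt_names

    P = _prob_matrix(config)
    pi = np.array([p for _, p in config.drug_catalog], dtype=float)
    pi = pi / pi.sum()
    drug_idx = rng.choice(len(drugs), size=n, p=pi)
    events = _sample_pt_matrix(rng, P, drug_idx)

    pids = np.array([str(10_000_001 + i) for i in range(n)], dtype=object)
    caseids = np.array([str(5_000_001 + i) for i in range(n)], dtype=object)

    # --- onset / dates ---------------------------------------------------
    model_keys = list(config.tto_models)
    M = -np.ones((len(drugs), len(pts)), dtype=int)
    for k, (d, t) in enumerate(model_keys):
        M[drugs.index(d), pts.index(t)] = k
    shapes = np.array(
        [config.tto_models[k][0] for k in model_keys] + [config.default_tto[0]]
    )
    scales = np.array(
        [config.tto_models[k][1] for k in model_keys] + [config.default_tto[1]]
    )
    per_report_model = np.full(n, len(model_keys))  # default
    if model_keys:
        mid = np.where(events, M[drug_idx], -1)
        has = (mid >= 0).any(axis=1)
        first = np.argmax(mid >= 0, axis=1)
        per_report_model[has] = mid[has, first[has]]
    onset = np.maximum(
        1, np.ceil(scales[per_report_model] * rng.weibull(shapes[per_report_model]))
    ).astype(int)

    w0 = date(
        int(config.window_start[:4]), int(config.window_start[4:6]), int(config.window_start[6:8])
    )
    start_off = rng.integers(0, config.window_days, size=n)
    lag = rng.geometric(1.0 / config.reporting_lag_mean, size=n)
    start_dates = [w0 + timedelta(days=int(o)) for o in start_off]
    event_dates = [s + timedelta(days=int(d)) for s, d in zip(start_dates, onset)]
    fda_dates = [e + timedelta(days=int(l)) for e, l in zip(event_dates, lag)]

    # --- demographics ----------------------------------------------------
    ag = config.age_groups
    g_idx = rng.choice(len(ag), size=n, p=np.array([g[2] for g in ag]) / sum(g[2] for g in ag))
    lo = np.array([g[0] for g in ag])[g_idx]
    hi = np.array([g[1] for g in ag])[g_idx]
    ages = np.floor(lo + rng.random(n) * (hi + 1 - lo)).astype(int)
    sexes = _categorical(rng, config.sex_probs, n)
    mu, sig = config.weight_lognormal
    weights = np.round(np.exp(rng.normal(mu, sig, size=n)), 1)
    reporters = _categorical(rng, config.reporter_probs, n)
    countries = _categorical(rng, config.country_probs, n)
    freqs = _categorical(rng, config.frequency_probs, n)
    doses = _categorical(rng, config.dose_probs, n)
    ind_probs = dict(config.indication_probs)
    ind_missing = max(0.0, 1.0 - sum(ind_probs.values()))
    ind_probs[""] = ind_missing
    indications = _categorical(rng, ind_probs, n)

    miss = {
        f: rng.random(n) < config.missing_rates.get(f, 0.0)
        for f in ("age", "sex", "weight", "reporter", "country", "frequency", "dose",
                  "event_dt", "start_dt")
    }
    date_mode = rng.random(n)  # shared draw: partial / invalid date corruption
    partial = date_mode < config.partial_date_fraction
    invalid = (date_mode >= config.partial_date_fraction) & (
        date_mode < config.partial_date_fraction + config.invalid_date_fraction
    )

    fatal = rng.random(n) < config.fatal_fraction
    hosp = rng.random(n) < config.hospitalized_fraction
    other_ser = rng.random(n) < config.other_serious_fraction

    mono = rng.random(n) < config.monotherapy_fraction
    is_target = np.array([drugs[i] == TARGET_DRUG for i in drug_idx])
    conc_names = [c for c, _ in config.concomitant_catalog]
    conc_p = np.array([p for _, p in config.concomitant_catalog])
    conc_mat = np.zeros((n, len(conc_names)), dtype=bool)
    not_mono = ~mono
    if not_mono.any():
        k = int(not_mono.sum())
        draws = rng.random((k, len(conc_names))) < conc_p
        empty = ~draws.any(axis=1)
        while empty.any():
            redraw = rng.random((int(empty.sum()), len(conc_names))) < conc_p
            draws[empty] = redraw
            e_idx = np.flatnonzero(empty)
            still = ~redraw.any(axis=1)
            empty = np.zeros(k, dtype=bool)
            empty[e_idx[still]] = True
        conc_mat[not_mono] = draws

    # --- duplicates / deletions ------------------------------------------
    n_dup = round(config.duplicate_fraction * n)
    n_del = round(config.deleted_fraction * n)
    perm = rng.permutation(n)
    dup_rows = np.sort(perm[:n_dup])
    del_rows = np.sort(perm[n_dup : n_dup + n_del])
    dup_pids = {int(i): str(20_000_001 + k) for k, i in enumerate(dup_rows)}
    dup_extra_lag = {int(i): int(l) for i, l in zip(dup_rows, rng.integers(1, 91, n_dup))}
    deleted_caseids = frozenset(caseids[del_rows])
    deleted_pids = set(pids[del_rows]) | {
        dup_pids[int(i)] for i in dup_rows if i in set(del_rows)
    }

    # --- assemble string tables -------------------------------------------
    def dstr(d: date) -> str:
        return f"{d.year:04d}{d.month:02d}{d.day:02d}"

    def corrupt(s: str, i: int) -> str:
        if partial[i]:
            return s[:6]
        if invalid[i]:
            return s[:4] + "13"  # impossible month -> invalid
        return s

    demo_rows, drug_rows, reac_rows, indi_rows, ther_rows, outc_rows = (
        [] for _ in range(6)
    )
    record_idx = np.nonzero(events)

    def emit_report(i: int, pid: str, fda: date) -> None:
        age_v, age_u = "", ""
        if not miss["age"][i]:
            if ages[i] < 2:
                age_v, age_u = str(int(ages[i] * 12)), "MON"
            else:
                age_v, age_u = str(int(ages[i])), "YR"
        ev = "" if miss["event_dt"][i] else corrupt(dstr(event_dates[i]), i)
        demo_rows.append(
            (
                pid,
                str(caseids[i]),
                dstr(fda),
                ev,
                age_v,
                age_u,
                "" if miss["sex"][i] else str(sexes[i]),
                "" if miss["weight"][i] else str(weights[i]),
                "" if miss["weight"][i] else "KG",
                "" if miss["reporter"][i] else str(reporters[i]),
                "" if miss["country"][i] else str(countries[i]),
            )
        )
        drug_rows.append(
            (
                pid,
                "1",
                "PS",
                drugs[drug_idx[i]],
                "" if miss["dose"][i] else str(doses[i]),
                "" if miss["frequency"][i] else str(freqs[i]),
            )
        )
        for k, c in enumerate(conc_names):
            if conc_mat[i, k]:
                drug_rows.append((pid, str(k + 2), "C", c, "", ""))
        st = "" if miss["start_dt"][i] else corrupt(dstr(start_dates[i]), i)
        ther_rows.append((pid, "1", st, ""))
        if indications[i]:
            indi_rows.append((pid, "1", str(indications[i])))
        if fatal[i]:
            outc_rows.append((pid, "DE"))
        if hosp[i]:
            outc_rows.append((pid, "HO"))
        if other_ser[i]:
            outc_rows.append((pid, "OT"))

    pt_arr = np.array(pts, dtype=object)
    for i in range(n):
        emit_report(i, str(pids[i]), fda_dates[i])
    for ri, rj in zip(*record_idx):
        reac_rows.append((str(pids[ri]), str(pt_arr[rj])))
    # duplicate versions: identical content, later FDA_DT, higher PRIMARYID
    for i in dup_rows:
        i = int(i)
        newpid = dup_pids[i]
        emit_report(i, newpid, fda_dates[i] + timedelta(days=dup_extra_lag[i]))
        for rj in np.flatnonzero(events[i]):
            reac_rows.append((newpid, str(pt_arr[rj])))

    cols = {
        "demo": [
            "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod", "sex",
            "wt", "wt_cod", "occp_cod", "reporter_country",
        ],
        "drug": ["primaryid", "drug_seq", "role_cod", "drugname", "dose_amt", "dose_freq"],
        "reac": ["primaryid", "pt"],
        "indi": ["primaryid", "indi_drug_seq", "indi_pt"],
        "ther": ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"],
        "outc": ["primaryid", "outc_cod"],
    }
    raw = {
        "demo": pd.DataFrame(demo_rows, columns=cols["demo"]),
        "drug": pd.DataFrame(drug_rows, columns=cols["drug"]),
        "reac": pd.DataFrame(reac_rows, columns=cols["reac"]),
        "indi": pd.DataFrame(indi_rows, columns=cols["indi"]),
        "ther": pd.DataFrame(ther_rows, columns=cols["ther"]),
        "outc": pd.DataFrame(outc_rows, columns=cols["outc"]),
    }

    # canonical (parsed) view, as read_quarter would deliver
    from . import faers_io as fio

    tables = QuarterTables(
        quarter=config.quarter,
        deleted_caseids=deleted_caseids,
        **{
            name: fio._canonicalize(df.replace("", pd.NA), name)
            for name, df in raw.items()
        },
    )
    tables.parse_issues["raw"] = raw  # kept for byte-identical file writing

    # --- ground truth -----------------------------------------------------
    cells, rors = planted_truth(config)
    final_mask = np.ones(n, dtype=bool)
    final_mask[del_rows] = False
    n_records = int(events[final_mask].sum())
    tallies = {
        "sex": Counter(
            str(sexes[i]) if not miss["sex"][i] else "missing"
            for i in range(n) if final_mask[i]
        ),
        "reporter": Counter(
            str(reporters[i]) if not miss["reporter"][i] else "missing"
            for i in range(n) if final_mask[i]
        ),
        "weight_missing": Counter(
            "missing" if miss["weight"][i] else "known"
            for i in range(n) if final_mask[i]
        ),
        "drug": Counter(drugs[drug_idx[i]] for i in range(n) if final_mask[i]),
    }
    shapes_truth: dict = {k: v[0] for k, v in config.tto_models.items()}
    shapes_truth["default"] = config.default_tto[0]
    truth = GroundTruth(
        expected_ror=rors,
        expected_cells=cells,
        onset_days={str(pids[i]): int(onset[i]) for i in range(n)},
        injected_duplicates=[(str(pids[int(i)]), dup_pids[int(i)]) for i in dup_rows],
        deleted_caseids=deleted_caseids,
        deleted_primaryids=frozenset(str(p) for p in deleted_pids),
        n_reports=n,
        n_demo_rows=n + n_dup,
        n_reports_final=n - n_del,
        n_records=n_records,
        # after dedup the surviving pid of a duplicated report is the
        # injected later version
        monotherapy_primaryids=frozenset(
            dup_pids.get(i, str(pids[i]))
            for i in range(n)
            if mono[i] and final_mask[i] and is_target[i]
        ),
        tto_shapes=shapes_truth,
        tallies=tallies,
    )
    return tables, truth


def generate_dataset(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Path, GroundTruth]:
    """Write one synthetic quarter as FAERS-format "$"-delimited files.

    Emits DEMO/DRUG/REAC/INDI/THER/OUTC ``<tag>.txt`` plus a
    ``DELETED<tag>.txt`` caseid list when deletions were injected, and a
    ``pt_soc_map.tsv`` for the catalog.  Byte-identical under a fixed seed.
    """
    tables, truth = generate_tables(config)
    raw: dict[str, pd.DataFrame] = tables.parse_issues["raw"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = tables.quarter
    for name, df in raw.items():
        path = out / f"{name.upper()}{tag}.txt"
        lines = ["$".join(df.columns)]
        lines += ["$".join(map(str, row)) for row in df.itertuples(index=False)]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    if truth.deleted_caseids:
        (out / f"DELETED{tag}.txt").write_text(
            "\n".join(sorted(truth.deleted_caseids)) + "\n", encoding="utf-8"
        )
    soc_lines = ["pt\tsoc"] + [f"{p}\t{s}" for p, s, _ in config.pt_catalog]
    (out / "pt_soc_map.tsv").write_text("\n".join(soc_lines) + "\n", encoding="utf-8")
    truth_path = out / "ground_truth.json"
    truth_path.write_text(_truth_json(truth), encoding="utf-8")
    return out, truth


def _truth_json(truth: GroundTruth) -> str:
    d = asdict(truth)
    d["expected_ror"] = {f"{k[0]}|{k[1]}": v for k, v in truth.expected_ror.items()}
    d["expected_cells"] = {f"{k[0]}|{k[1]}": v for k, v in truth.expected_cells.items()}
    d["deleted_caseids"] = sorted(truth.deleted_caseids)
    d["deleted_primaryids"] = sorted(truth.deleted_primaryids)
    d["monotherapy_primaryids"] = sorted(truth.monotherapy_primaryids)
    d["tto_shapes"] = {
        ("|".join(k) if isinstance(k, tuple) else k): v for k, v in truth.tto_shapes.items()
    }
    d["tallies"] = {k: dict(v) for k, v in truth.tallies.items()}
    return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# dedicated covariate-driven outcome generator (logistic-recovery scenario)


REGRESSION_DEFAULT_COEFS: dict[str, float] = {
    "intercept": -2.442,               # ~8% baseline outcome prevalence
    "sex_male": math.log(0.224),       # strong protective sex effect
}

_REG_MARGINALS = {
    "sex_male": 0.487,
    "age_under18": 0.518,
    "reporter_consumer": 0.394,
    "country_other": 0.097,
    "frequency_qd": 0.018,
    "monotherapy": 0.270,
}


def simulate_regression_cases(
    n: int = 3440,
    coefs: Mapping[str, float] | None = None,
    seed: int = 0,
    outcome_pt: str = "Depression",
) -> list:
    """Complete-case reports with a planted logistic model for one outcome PT.

    Covariate marginals mirror the complete-report subset of the real
    study (≈49% male, ≈52% under 18, ≈39% consumer-reported, ≈2% QD).
    ``coefs`` are log-odds on indicator covariates named as in
    ``REGRESSION_DEFAULT_COEFS``; unlisted covariates have zero effect.
    """
    from .faers_io import CaseReport

    coefs = dict(REGRESSION_DEFAULT_COEFS if coefs is None else coefs)
    rng = np.random.default_rng(seed)
    X = {k: (rng.random(n) < p) for k, p in _REG_MARGINALS.items()}
    eta = np.full(n, coefs.get("intercept", 0.0))
    for k, v in coefs.items():
        if k != "intercept":
            eta = eta + v * X[k].astype(float)
    p = 1.0 / (1.0 + np.exp(-eta))
    y = rng.random(n) < p
    cases = []
    for i in range(n):
        pts = {outcome_pt} if y[i] else {"Cough"}
        drugs = frozenset(
            {TARGET_DRUG} if X["monotherapy"][i] else {TARGET_DRUG, "PULMOZYME"}
        )
        cases.append(
            CaseReport(
                primaryid=str(30_000_001 + i),
                caseid=str(30_000_001 + i),
                age_years=10.0 if X["age_under18"][i] else 30.0,
                sex="M" if X["sex_male"][i] else "F",
                weight_kg=None,
                reporter="CN" if X["reporter_consumer"][i] else "MD",
                country="OTHER" if X["country_other"][i] else "US",
                year=2020,
                frequency="QD" if X["frequency_qd"][i] else "BID",
                dose=None,
                target_drug_rows=[],
                all_drug_names=drugs,
                pts=frozenset(pts),
                socs=frozenset({"Psychiatric disorders" if y[i] else "Respiratory"}),
                outcomes=frozenset(),
                indications=frozenset({"Cystic fibrosis"}),
                earliest_target_start=None,
                event_date=None,
            )
        )
    return cases


def config_from_json(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a JSON key-value file."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    for key in ("drug_catalog", "pt_catalog", "planted_signals", "age_groups",
                "concomitant_catalog"):
        if key in data:
            data[key] = tuple(tuple(x) for x in data[key])
    if "tto_models" in data:
        data["tto_models"] = {
            tuple(k.split("|")): tuple(v) for k, v in data["tto_models"].items()
        }
    if "default_tto" in data:
        data["default_tto"] = tuple(data["default_tto"])
    if "weight_lognormal" in data:
        data["weight_lognormal"] = tuple(data["weight_lognormal"])
    return SimulationConfig(**data)
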