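"""Disproportionality signal detection: ROR and BCPNN information component.

Every statistic is computed on a 2x2 contingency table of PT *records*
(one row per report x distinct preferred term):

====================  ==================  ======================
                      target event        other events
====================  ==================  ======================
target drug           a                   b
all other drugs       c                   d
====================  ==================  ======================

The reporting odds ratio is ``(a*d)/(b*c)`` with a Wald 95% CI on the log
scale.  The Bayesian confidence propagation neural network information
component is the shrunk log2 observed/expected ratio
``IC = log2((a+0.5)/(E+0.5))`` with ``E = (a+b)(a+c)/N``; its lower 2.5%
credibility bound uses the standard shrinkage approximation
``IC025 = IC - 3.3*(a+0.5)^-1/2 - 2*(a+0.5)^-3/2``.  A gamma-variance
variant (delta-method on the posterior, Bate-style priors) is selectable.

A term is flagged as a positive signal only when the case count, the ROR
CI lower bound and IC025 all clear their thresholds simultaneously
(defaults: n>=3, ROR025>1, IC025>0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .faers_io import CaseReport, normalize_synonyms

Z95 = 1.959963984540054


@dataclass(frozen=True)
class ContingencyTable:
    """a/b/c/d record counts underlying every disproportionality statistic."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass
class SignalResult:
    """Per-term disproportionality estimates with dual-threshold flag."""

    term: str
    level: str  # "PT" | "SOC"
    n_cases: int  # = a
    ror: float
    ror_low: float
    ror_high: float
    ic: float
    ic025: float
    flagged: bool
    analysis_tag: str = "primary"
    corrected: bool = False
    table: ContingencyTable | None = None


def build_contingency(
    pt_records: pd.DataFrame,
    drug_predicate: Callable[[pd.DataFrame], pd.Series] | pd.Series,
    event_predicate: Callable[[pd.DataFrame], pd.Series] | pd.Series,
) -> ContingencyTable:
    """2x2 over a PT-record table (one row per report x distinct PT).

    The predicates mark target-drug records and target-event records; the
    four cells partition all records.
    """
    if len(pt_records) == 0:
        raise ValueError("empty PT-record table")
    dmask = drug_predicate(pt_records) if callable(drug_predicate) else drug_predicate
    emask = event_predicate(pt_records) if callable(event_predicate) else event_predicate
    dmask = np.asarray(dmask, dtype=bool)
    emask = np.asarray(emask, dtype=bool)
    a = int((dmask & emask).sum())
    b = int((dmask & ~emask).sum())
    c = int((~dmask & emask).sum())
    d = int((~dmask & ~emask).sum())
    return ContingencyTable(a, b, c, d)


def ror_estimate(
    t: ContingencyTable, haldane: bool = True
) -> tuple[float, float, float, bool]:
    """ROR with Wald 95% CI; Haldane +0.5 on all cells when any cell is 0.

    Returns ``(ror, low, high, corrected)``.  With the correction disabled
    a zero cell yields NaNs (undefined-signal marker), never an exception.
    """
    corrected = False
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if t.has_zero_cell:
        if not haldane:
            return math.nan, math.nan, math.nan, False
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    low = math.exp(math.log(ror) - Z95 * se)
    high = math.exp(math.log(ror) + Z95 * se)
    return ror, low, high, corrected


def bcpnn_ic(t: ContingencyTable, variant: str = "shrinkage") -> tuple[float, float]:
    """Information component and its lower 2.5% credibility bound.

    ``variant="shrinkage"`` (default) uses the closed-form credible-interval
    approximation; ``variant="gamma"`` uses the delta-method posterior
    variance with symmetric unit priors.
    """
    a, n = t.a, t.n
    e = (t.a + t.b) * (t.a + t.c) / n
    ic = math.log2((a + 0.5) / (e + 0.5))
    if variant == "shrinkage":
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
        return ic, ic025
    if variant == "gamma":
        a1 = b1 = g11 = 1.0
        alpha = beta = 2.0
        n1 = t.a + t.b
        nc1 = t.a + t.c
        gamma = g11 * (n + alpha) * (n + beta) / ((n1 + a1) * (nc1 + b1))
        var = (1.0 / math.log(2.0)) ** 2 * (
            (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
            + (n - n1 + alpha - a1) / ((n1 + a1) * (1 + n + alpha))
            + (n - nc1 + beta - b1) / ((nc1 + b1) * (1 + n + beta))
        )
        return ic, ic - Z95 * math.sqrt(var)
    raise ValueError(f"unknown BCPNN variant: {variant!r}")


def flag_signal(r: SignalResult, min_cases: int = 3) -> bool:
    """Dual-threshold positivity: n>=min_cases, ROR025>1 and IC025>0."""
    return bool(
        r.n_cases >= min_cases
        and not math.isnan(r.ror_low)
        and r.ror_low > 1.0
        and r.ic025 > 0.0
    )


def screen_records(
    records: pd.DataFrame,
    level: str = "PT",
    analysis_tag: str = "primary",
    min_cases: int = 3,
    bcpnn_variant: str = "shrinkage",
) -> list[SignalResult]:
    """Screen every term of a database-wide record table.

    ``records`` must hold one row per (report, distinct term) with columns
    ``primaryid``, ``pt`` and/or ``soc``, and boolean ``is_target``.  At
    SOC level a report contributes once per distinct (report, SOC) pair.
    One result per term with a >= 1, sorted by case count descending.
    """
    col = "pt" if level == "PT" else "soc"
    if col not in records.columns:
        raise ValueError(f"record table lacks a {col!r} column")
    sub = records[["primaryid", col, "is_target"]].drop_duplicates(
        ["primaryid", col]
    )
    n_total = len(sub)
    target = sub["is_target"].to_numpy(dtype=bool)
    n_target = int(target.sum())
    counts = (
        sub.groupby([col, "is_target"], sort=False, observed=True)
        .size()
        .unstack(fill_value=0)
    )
    a_col = counts[True] if True in counts.columns else pd.Series(0, index=counts.index)
    c_col = counts[False] if False in counts.columns else pd.Series(0, index=counts.index)
    results: list[SignalResult] = []
    for term in counts.index:
        a = int(a_col.get(term, 0))
        if a < 1:
            continue
        c = int(c_col.get(term, 0))
        t = ContingencyTable(a, n_target - a, c, n_total - n_target - c)
        ror, lo, hi, corr = ror_estimate(t)
        ic, ic025 = bcpnn_ic(t, variant=bcpnn_variant)
        r = SignalResult(
            term=str(term),
            level=level,
            n_cases=a,
            ror=ror,
            ror_low=lo,
            ror_high=hi,
            ic=ic,
            ic025=ic025,
            flagged=False,
            analysis_tag=analysis_tag,
            corrected=corr,
            table=t,
        )
        r.flagged = flag_signal(r, min_cases)
        results.append(r)
    results.sort(key=lambda r: (-r.n_cases, r.term))
    return results


def screen_all(
    record_table: pd.DataFrame,
    target_ids: Iterable[str],
    level: str = "PT",
    analysis_tag: str = "primary",
    min_cases: int = 3,
    bcpnn_variant: str = "shrinkage",
) -> list[SignalResult]:
    """Convenience wrapper: mark target reports in a (primaryid, pt, soc)
    record table and screen at the requested level."""
    targets = {str(p) for p in target_ids}
    rec = record_table.copy()
    rec["is_target"] = rec["primaryid"].astype(str).isin(targets)
    return screen_records(rec, level=level, analysis_tag=analysis_tag,
                          min_cases=min_cases, bcpnn_variant=bcpnn_variant)


def restrict_monotherapy(
    case_reports: Sequence[CaseReport], synonyms: Iterable[str]
) -> list[CaseReport]:
    """Keep target-drug reports whose drug rows name only target synonyms."""
    syn = normalize_synonyms(synonyms)
    return [c for c in case_reports if c.all_drug_names <= syn]


def comparator_screen(
    record_table: pd.DataFrame,
    drug_df: pd.DataFrame,
    comparator_synonyms: Iterable[str],
    comparator_name: str,
    level: str = "PT",
    min_cases: int = 3,
    role: str = "PS",
) -> list[SignalResult]:
    """Re-run the screen with a comparator drug as the target.

    Returns an empty list (with a warning in the log) when the comparator
    is absent from the data.
    """
    from . import faers_io
    import logging

    ids = faers_io.select_drug_reports(drug_df, comparator_synonyms, role=role)
    ids &= set(record_table["primaryid"].astype(str))
    if not ids:
        logging.getLogger(__name__).warning(
            "comparator %s absent from data; empty screen", comparator_name
        )
        return []
    return screen_all(
        record_table,
        ids,
        level=level,
        analysis_tag=f"comparator:{comparator_name}",
        min_cases=min_cases,
    )


def signal_table(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Diffable signal table: fixed column order, 4-decimal rounding."""
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "level": [r.level for r in results],
            "n": [r.n_cases for r in results],
            "ror": [round(r.ror, 4) for r in results],
            "ror_low": [round(r.ror_low, 4) for r in results],
            "ror_high": [round(r.ror_high, 4) for r in results],
            "ic": [round(r.ic, 4) for r in results],
            "ic025": [round(r.ic025, 4) for r in results],
            "flagged": [r.flagged for r in results],
            "analysis_tag": [r.analysis_tag for r in results],
        }
    )
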