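"""Clinical priority scoring and signal-origin classification.

Each positive signal is scored 0-2 on four criteria — reporting rate,
magnitude of the ROR CI lower bound, reported case fatality rate, and
clinical relevance (designated / important medical event lists) — and the
total (0-8) maps to a priority category: low 0-2, medium 3-5, high 6-8.

Band edges published for the middle bands overlap their neighbours
("1-10%", "2-5", "25-50%"); they are resolved upper-inclusive for the
middle band, so exactly 10% reporting rate scores 1, ROR025 of exactly 5
scores 1, and a 50% fatality rate scores 1.

Signal origin partitions flagged terms into *expected* (on the drug
label), *disease-expected* (also flagged for every same-indication
comparator drug) and *unexpected* (neither).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

CATEGORY_BANDS = ((0, 2, "low"), (3, 5, "medium"), (6, 8, "high"))


@dataclass(frozen=True)
class PriorityScore:
    term: str
    points_rate: int
    points_ror: int
    points_cfr: int
    points_relevance: int
    reporting_rate: float
    ror_low: float
    cfr: float
    relevance: str  # "DME" | "IME" | "none"

    @property
    def total(self) -> int:
        return self.points_rate + self.points_ror + self.points_cfr + self.points_relevance

    @property
    def category(self) -> str:
        for lo, hi, name in CATEGORY_BANDS:
            if lo <= self.total <= hi:
                return name
        raise AssertionError("total outside 0-8")


@dataclass(frozen=True)
class OriginClass:
    term: str
    origin: str  # "expected" | "disease_expected" | "unexpected"
    evidence: str


def band_rate(rate: float) -> int:
    """Reporting rate (cases / total records): >10% -> 2, 1-10% -> 1, <1% -> 0."""
    if rate > 0.10:
        return 2
    if rate >= 0.01:
        return 1
    return 0


def band_ror_low(ror_low: float) -> int:
    """ROR 95% CI lower bound: >5 -> 2, 2-5 -> 1, below 2 -> 0."""
    if ror_low > 5.0:
        return 2
    if ror_low >= 2.0:
        return 1
    return 0


def band_cfr(cfr: float) -> int:
    """Case fatality rate: >50% -> 2, 25-50% -> 1, <25% -> 0."""
    if cfr > 0.50:
        return 2
    if cfr >= 0.25:
        return 1
    return 0


def band_relevance(relevance: str) -> int:
    return {"DME": 2, "IME": 1}.get(relevance, 0)


def score_priority(
    term: str,
    n_cases: int,
    total_records: int,
    ror_low: float,
    deaths: int,
    relevance: str = "none",
) -> PriorityScore:
    """Score one flagged signal on the four-criterion framework."""
    if n_cases <= 0:
        raise ValueError("nothing to score: n_cases must be positive")
    if total_records <= 0:
        raise ValueError("total_records must be positive")
    if deaths > n_cases:
        raise ValueError("deaths cannot exceed n_cases")
    rate = n_cases / total_records
    cfr = deaths / n_cases
    return PriorityScore(
        term=term,
        points_rate=band_rate(rate),
        points_ror=band_ror_low(ror_low),
        points_cfr=band_cfr(cfr),
        points_relevance=band_relevance(relevance),
        reporting_rate=rate,
        ror_low=ror_low,
        cfr=cfr,
        relevance=relevance if relevance in ("DME", "IME") else "none",
    )


def classify_signal_origin(
    term: str,
    label_terms: Iterable[str],
    comparator_flags: Mapping[str, bool],
) -> OriginClass:
    """Classify one flagged term.

    expected if on the drug label; else disease-expected if flagged in
    *every* comparator screen (a missing comparator result counts as not
    flagged); else unexpected.
    """
    labels = set(label_terms)
    if term in labels:
        return OriginClass(term, "expected", "drug label")
    if comparator_flags and all(bool(v) for v in comparator_flags.values()):
        names = ", ".join(sorted(comparator_flags))
        return OriginClass(term, "disease_expected", f"flagged for all comparators ({names})")
    return OriginClass(term, "unexpected", "absent from label; not flagged for all comparators")


def priority_table(
    scores: Iterable[PriorityScore],
    origins: Mapping[str, OriginClass] | None = None,
) -> pd.DataFrame:
    """Priority TSV layout: term, four point columns, total, category, origin."""
    scores = list(scores)
    origins = origins or {}
    return pd.DataFrame(
        {
            "term": [s.term for s in scores],
            "points_rate": [s.points_rate for s in scores],
            "points_ror": [s.points_ror for s in scores],
            "points_cfr": [s.points_cfr for s in scores],
            "points_relevance": [s.points_relevance for s in scores],
            "total": [s.total for s in scores],
            "category": [s.category for s in scores],
            "origin": [
                origins[s.term].origin if s.term in origins else "" for s in scores
            ],
        }
    )
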