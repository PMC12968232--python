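"""Time-to-onset (TTO) analysis: onset intervals, Weibull failure typing,
per-SOC summaries and nonparametric subgroup comparisons.

TTO is the interval in days between the earliest valid therapy start date
of the target drug and the report's event date.  Reports with partial or
missing dates, non-positive intervals or intervals beyond an
implausibility cap (25 years) are excluded, with per-reason counts.

Onset distributions are modelled as Weibull; the maximum-likelihood shape
parameter classifies the hazard: a 95% CI entirely below 1 is *early
failure* (risk concentrated at the start of therapy), a CI containing 1
*random failure* (constant hazard), a CI above 1 *wear-out failure*
(risk growing with treatment duration).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import optimize, stats

from .faers_io import CaseReport

IMPLAUSIBLE_DAYS = 9125  # 25 years

Z95 = 1.959963984540054


@dataclass(frozen=True)
class TTOSample:
    primaryid: str
    days: int
    pts: frozenset[str]
    socs: frozenset[str]
    strata: dict = field(default_factory=dict, hash=False, compare=False)


def compute_tto(
    case_reports: Sequence[CaseReport],
    max_days: int = IMPLAUSIBLE_DAYS,
) -> tuple[list[TTOSample], Counter]:
    """Onset samples plus exclusion counts keyed by reason.

    One sample per report (days = event date − earliest target-drug
    therapy start); only full 8-digit dates qualify.
    """
    samples: list[TTOSample] = []
    excluded: Counter = Counter()
    for c in case_reports:
        if c.earliest_target_start is None or c.event_date is None:
            excluded["incomplete_dates"] += 1
            continue
        days = (c.event_date - c.earliest_target_start).days
        if days <= 0:
            excluded["non_positive"] += 1
            continue
        if days > max_days:
            excluded["implausible"] += 1
            continue
        samples.append(
            TTOSample(
                primaryid=c.primaryid,
                days=days,
                pts=c.pts,
                socs=c.socs,
                strata={
                    "sex": c.sex,
                    "age_group": age_group(c.age_years),
                    "weight_group": weight_group(c.weight_kg),
                    "frequency": c.frequency,
                    "dose": c.dose,
                    "fatal": c.fatal,
                },
            )
        )
    return samples, excluded


def age_group(age_years: float | None) -> str | None:
    if age_years is None:
        return None
    for lo, hi, label in (
        (0, 2, "<2"), (2, 6, "2-5"), (6, 12, "6-11"),
        (12, 18, "12-17"), (18, 66, "18-65"),
    ):
        if lo <= age_years < hi:
            return label
    return ">65"


def weight_group(weight_kg: float | None) -> str | None:
    if weight_kg is None:
        return None
    if weight_kg < 50:
        return "<50"
    if weight_kg <= 100:
        return "50-100"
    return ">100"


def bin_tto(days: int) -> str:
    """30-day onset bins "1-30" ... "331-360", then ">360"."""
    if days < 1:
        raise ValueError("days must be >= 1")
    if days > 360:
        return ">360"
    hi = 30 * math.ceil(days / 30)
    return f"{hi - 29}-{hi}"


BIN_LABELS = tuple(f"{30 * k - 29}-{30 * k}" for k in range(1, 13)) + (">360",)


def binned_counts(samples: Iterable[TTOSample]) -> pd.DataFrame:
    """Butterfly-plot table: interval, n, percent (ordered bins)."""
    days = [s.days for s in samples]
    counts = Counter(bin_tto(d) for d in days)
    total = len(days)
    return pd.DataFrame(
        {
            "interval": BIN_LABELS,
            "n": [counts.get(b, 0) for b in BIN_LABELS],
            "percent": [
                round(100.0 * counts.get(b, 0) / total, 2) if total else 0.0
                for b in BIN_LABELS
            ],
        }
    )


# ---------------------------------------------------------------------------
# Weibull maximum likelihood


@dataclass
class WeibullFit:
    shape: float
    scale: float
    shape_ci: tuple[float, float]
    scale_ci: tuple[float, float]
    n: int
    log_likelihood: float

    @property
    def failure_class(self) -> str:
        return classify_failure(self)


def weibull_fit(samples: Sequence[float]) -> WeibullFit:
    """Maximum-likelihood Weibull fit with log-scale Wald CIs.

    The shape solves the profile-likelihood equation
    ``sum(x^k ln x)/sum(x^k) − 1/k − mean(ln x) = 0`` (bracketed root
    find); the scale follows in closed form.  CIs come from the observed
    information evaluated on the (log shape, log scale) parametrization,
    exponentiated back.
    """
    x = np.asarray(list(samples), dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    if np.any(x <= 0):
        raise ValueError("Weibull support is positive")
    if np.unique(x).size < 2:
        raise ValueError("degenerate sample: all values identical")
    lx = np.log(x)
    mean_lx = lx.mean()

    def profile(k: float) -> float:
        w = np.exp(k * (lx - lx.max()))  # stabilized x^k
        return float((w * lx).sum() / w.sum() - 1.0 / k - mean_lx)

    lo, hi = 1e-3, 1.0
    while profile(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError(
                f"Weibull shape solve failed to bracket a root; "
                f"profile({hi / 2:.0f}) = {profile(hi / 2.0):.3g}"
            )
    k = float(optimize.brentq(profile, lo, hi, xtol=1e-12))
    lam = float((np.exp(k * (lx - lx.max())).mean()) ** (1.0 / k) * np.exp(lx.max()))

    n = len(x)
    ll = float(
        n * math.log(k) - n * k * math.log(lam) + (k - 1) * lx.sum() - ((x / lam) ** k).sum()
    )

    # observed information on (log k, log lambda) by central differences
    def negll(theta: np.ndarray) -> float:
        kk, ll_ = math.exp(theta[0]), math.exp(theta[1])
        z = (x / ll_) ** kk
        return -(n * math.log(kk) - n * kk * math.log(ll_) + (kk - 1) * lx.sum() - z.sum())

    theta_hat = np.array([math.log(k), math.log(lam)])
    h = 1e-4
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            H[i, j] = (
                negll(theta_hat + ei + ej)
                - negll(theta_hat + ei - ej)
                - negll(theta_hat - ei + ej)
                + negll(theta_hat - ei - ej)
            ) / (4 * h * h)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    shape_ci = (k * math.exp(-Z95 * se[0]), k * math.exp(Z95 * se[0]))
    scale_ci = (lam * math.exp(-Z95 * se[1]), lam * math.exp(Z95 * se[1]))
    return WeibullFit(
        shape=k, scale=lam, shape_ci=shape_ci, scale_ci=scale_ci,
        n=n, log_likelihood=ll,
    )


def classify_failure(fit: WeibullFit) -> str:
    """early if the shape CI is below 1; wearout if above; else random."""
    lo, hi = fit.shape_ci
    if hi < 1.0:
        return "early"
    if lo > 1.0:
        return "wearout"
    return "random"


# ---------------------------------------------------------------------------
# summaries and tests


def soc_tto_summary(samples: Iterable[TTOSample]) -> pd.DataFrame:
    """Per-SOC n, median and quartiles; a sample contributes to every SOC
    its PTs map to.  SOCs without samples are omitted."""
    by_soc: dict[str, list[int]] = {}
    for s in samples:
        for soc in s.socs:
            by_soc.setdefault(soc, []).append(s.days)
    rows = []
    for soc in sorted(by_soc):
        d = np.array(by_soc[soc], dtype=float)
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        rows.append({"soc": soc, "n": len(d), "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows, columns=["soc", "n", "median", "q1", "q3"])


def logrank_test(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """k-group log-rank test on fully observed event times.

    Spontaneous reports are all events (no censoring model), so this
    compares cumulative-incidence curves directly.  Returns (chi2, df, p).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if len(g) == 0:
            raise ValueError(f"group {i} is empty")
    durations = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    labels = np.concatenate(
        [np.full(len(g), i) for i, g in enumerate(groups)]
    )
    res = multivariate_logrank_test(durations, labels, np.ones_like(durations))
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided rank-sum test.

    Exact null distribution when min(n) <= 8 and there are no ties;
    otherwise the normal approximation with tie and continuity
    corrections.  Returns (rank-sum U statistic of x, p).
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(xa) == 0 or len(ya) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(len(xa), len(ya)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        xa, ya, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(1.0, res.pvalue))


def dunn_pairwise(groups: Sequence[Sequence[float]]) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with tie correction and
    Benjamini-Hochberg adjustment across the pairs.

    Groups with fewer than 2 observations are excluded (warning).
    Returns a table with columns group_i, group_j, z, p, p_adj.
    """
    import logging

    from .stratified import benjamini_hochberg

    arrs = []
    keep_idx = []
    for i, g in enumerate(groups):
        a = np.asarray(g, dtype=float)
        if len(a) < 2:
            logging.getLogger(__name__).warning(
                "dunn_pairwise: group %d has n=%d < 2; excluded", i, len(a)
            )
            continue
        arrs.append(a)
        keep_idx.append(i)
    if len(arrs) < 3:
        raise ValueError("need at least three usable groups")
    pooled = np.concatenate(arrs)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(a) for a in arrs]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[offsets[i]: offsets[i + 1]].mean() for i in range(len(arrs))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (N - 1)))
    base_var = N * (N + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append(
                {"group_i": keep_idx[i], "group_j": keep_idx[j], "z": z, "p": min(1.0, p)}
            )
    df = pd.DataFrame(rows)
    df["p_adj"] = benjamini_hochberg(df["p"].tolist())
    return df


def tto_sample_table(samples: Sequence[TTOSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "primaryid": [s.primaryid for s in samples],
            "days": [s.days for s in samples],
            "pts": ["|".join(sorted(s.pts)) for s in samples],
            "socs": ["|".join(sorted(s.socs)) for s in samples],
            "sex": [s.strata.get("sex") for s in samples],
            "age_group": [s.strata.get("age_group") for s in samples],
            "weight_group": [s.strata.get("weight_group") for s in samples],
            "frequency": [s.strata.get("frequency") for s in samples],
            "dose": [s.strata.get("dose") for s in samples],
            "fatal": [s.strata.get("fatal") for s in samples],
        }
    )
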