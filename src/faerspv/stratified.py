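"""Stratified (modified-ROR) subgroup screens and logistic risk modelling.

The modified ROR compares reporting of a term between two strata of the
*target-drug* reports (e.g. males vs females): a/b are the term's records
and all other records in group 1, c/d the same in group 2.  Inference
combines the Wald CI of the subgroup ROR with a chi-square test (no
continuity correction by default) and Benjamini-Hochberg adjustment
across the terms of one screen: the CI lower bound >1 with adjusted
p < alpha flags group 1, an upper bound <1 flags group 2.

Logistic regression identifies independent risk factors for reporting a
chosen outcome PT: complete-case analysis, univariate screens at
p < alpha_enter, then a multivariate fit on the survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import Logit
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .faers_io import CaseReport
from .signals import ContingencyTable, ror_estimate

log = logging.getLogger(__name__)


@dataclass
class SubgroupSignal:
    term: str
    stratum_variable: str
    group1: str
    group2: str
    a: int
    b: int
    c: int
    d: int
    ror: float
    ror_low: float
    ror_high: float
    chi2: float
    p: float
    p_adj: float = float("nan")
    direction: str = "none"  # "group1" | "group2" | "none"
    corrected: bool = False


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment; empty in, empty out; capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def flag_direction(
    ror_low: float, ror_high: float, p_adj: float, alpha: float = 0.05
) -> str:
    """Direction rule: CI low >1 & p_adj<alpha -> group1; CI high <1 -> group2."""
    if np.isnan(ror_low) or np.isnan(p_adj):
        return "none"
    if ror_low > 1.0 and p_adj < alpha:
        return "group1"
    if ror_high < 1.0 and p_adj < alpha:
        return "group2"
    return "none"


def subgroup_screen(
    pt_records: pd.DataFrame,
    stratum_variable: str,
    group1: str,
    group2: str,
    min_cases: int = 3,
    alpha: float = 0.05,
    yates: bool = False,
) -> list[SubgroupSignal]:
    """Modified-ROR screen of every term across two strata.

    ``pt_records`` holds one row per (report, distinct PT) of the target
    drug with a ``pt`` column and the stratum column; records with a
    missing stratum are excluded (counted in the log).  Terms with
    a + c < min_cases are skipped.  Adjustment is across the terms of this
    screen.
    """
    if stratum_variable not in pt_records.columns:
        raise ValueError(f"no stratum column {stratum_variable!r}")
    rec = pt_records[["primaryid", "pt", stratum_variable]].drop_duplicates(
        ["primaryid", "pt"]
    )
    known = rec[stratum_variable].isin([group1, group2])
    n_missing = int((~known).sum())
    if n_missing:
        log.info(
            "subgroup_screen(%s): excluded %d records outside {%s, %s}",
            stratum_variable, n_missing, group1, group2,
        )
    rec = rec[known]
    in1 = rec[stratum_variable] == group1
    n1 = int(in1.sum())
    n2 = len(rec) - n1
    counts = rec.groupby(["pt", stratum_variable], observed=True).size().unstack(fill_value=0)
    out: list[SubgroupSignal] = []
    for term in counts.index:
        a = int(counts.loc[term].get(group1, 0))
        c = int(counts.loc[term].get(group2, 0))
        if a + c < min_cases:
            continue
        b, d = n1 - a, n2 - c
        t = ContingencyTable(a, b, c, d)
        ror, lo, hi, corr = ror_estimate(t)
        chi2, p = _chi2_test(a, b, c, d, yates)
        out.append(
            SubgroupSignal(
                term=str(term), stratum_variable=stratum_variable,
                group1=group1, group2=group2,
                a=a, b=b, c=c, d=d,
                ror=ror, ror_low=lo, ror_high=hi,
                chi2=chi2, p=p, corrected=corr,
            )
        )
    padj = benjamini_hochberg([s.p for s in out])
    for s, q in zip(out, padj):
        s.p_adj = float(q)
        s.direction = flag_direction(s.ror_low, s.ror_high, s.p_adj, alpha)
    out.sort(key=lambda s: (s.p_adj, s.term))
    return out


def _chi2_test(a: int, b: int, c: int, d: int, yates: bool) -> tuple[float, float]:
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


def volcano_table(signals: Sequence[SubgroupSignal]) -> pd.DataFrame:
    """Volcano-plot-ready TSV layout."""
    return pd.DataFrame(
        {
            "term": [s.term for s in signals],
            "stratum_variable": [s.stratum_variable for s in signals],
            "group1": [s.group1 for s in signals],
            "group2": [s.group2 for s in signals],
            "a": [s.a for s in signals],
            "b": [s.b for s in signals],
            "c": [s.c for s in signals],
            "d": [s.d for s in signals],
            "log2_ror": [np.log2(s.ror) if s.ror > 0 else np.nan for s in signals],
            "ror": [round(s.ror, 4) for s in signals],
            "ror_low": [round(s.ror_low, 4) for s in signals],
            "ror_high": [round(s.ror_high, 4) for s in signals],
            "p": [s.p for s in signals],
            "p_adj": [s.p_adj for s in signals],
            "direction": [s.direction for s in signals],
        }
    )


# ---------------------------------------------------------------------------
# logistic regression


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: coefficients diverge."""


@dataclass
class LogisticFit:
    names: list[str]
    coefficients: np.ndarray
    std_errors: np.ndarray
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    converged: bool
    n: int

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "coef": self.coefficients,
                "odds_ratio": self.odds_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            }
        )


_Z = 1.959963984540054
_DIVERGENCE = 15.0  # |log-odds| beyond this flags separation


def fit_logistic(X: pd.DataFrame | np.ndarray, y: Sequence[int]) -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald 95% CIs.

    ``X`` must already contain the intercept column.  Non-convergence
    within 50 Newton iterations and (quasi-)complete separation raise,
    with diagnostics, rather than returning silently absurd estimates.
    """
    Xdf = pd.DataFrame(X)
    yarr = np.asarray(y, dtype=float)
    if len(Xdf) != len(yarr):
        raise ValueError("X and y lengths differ")
    if len(Xdf) < Xdf.shape[1]:
        raise ValueError("fewer observations than parameters")
    if yarr.min() == yarr.max():
        raise ValueError("degenerate outcome: all observations identical")
    model = Logit(yarr, Xdf.astype(float))
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence reported via exceptions
            res = model.fit(disp=0, maxiter=50, method="newton")
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"separation detected: {exc}") from exc
    coefs = np.asarray(res.params, dtype=float)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(
            f"logistic fit did not converge in 50 iterations; "
            f"last coefficients {({c: round(float(v), 2) for c, v in zip(Xdf.columns, coefs)})}"
        )
    if np.max(np.abs(coefs)) > _DIVERGENCE:
        raise SeparationError(
            f"diverging coefficients (max |coef| = {np.abs(coefs).max():.1f}); "
            "the design is separated"
        )
    se = np.asarray(res.bse, dtype=float)
    return LogisticFit(
        names=[str(c) for c in Xdf.columns],
        coefficients=coefs,
        std_errors=se,
        odds_ratios=np.exp(coefs),
        ci_low=np.exp(coefs - _Z * se),
        ci_high=np.exp(coefs + _Z * se),
        p_values=np.asarray(res.pvalues, dtype=float),
        log_likelihood=float(res.llf),
        converged=True,
        n=len(yarr),
    )


#: covariate name -> (extractor, indicator label); reference levels mirror
#: the real study's regression design (female, health-professional, US,
#: BID, 18-65, non-monotherapy references).
@dataclass
class RegressionDesign:
    outcome_pt: str = "Depression"
    target_synonyms: tuple[str, ...] = ("ORKAMBI",)
    adult_range: tuple[float, float] = (18.0, 65.0)


def _covariate_frame(
    cases: Sequence[CaseReport], design: RegressionDesign
) -> pd.DataFrame:
    syn = design.target_synonyms
    rows = []
    for c in cases:
        rows.append(
            {
                "primaryid": c.primaryid,
                "outcome": int(design.outcome_pt in c.pts),
                "age_under18": (
                    np.nan if c.age_years is None else int(c.age_years < 18)
                ),
                "sex_male": {"M": 1, "F": 0}.get(c.sex, np.nan),
                "reporter_consumer": (
                    np.nan if c.reporter is None else int(c.reporter == "CN")
                ),
                "country_other": (
                    np.nan if c.country is None else int(c.country != "US")
                ),
                "frequency_qd": (
                    np.nan if c.frequency is None else int(c.frequency == "QD")
                ),
                "monotherapy": int(c.is_monotherapy(syn)),
            }
        )
    return pd.DataFrame(rows)


def regression_workflow(
    case_reports: Sequence[CaseReport],
    outcome_pt: str,
    covariates: Sequence[str] = (
        "age_under18", "sex_male", "reporter_consumer",
        "country_other", "frequency_qd", "monotherapy",
    ),
    alpha_enter: float = 0.05,
    target_synonyms: Iterable[str] = ("ORKAMBI",),
) -> tuple[pd.DataFrame, LogisticFit | None]:
    """Univariate screens then a multivariate model for one outcome PT.

    Outcome = 1 when the report contains ``outcome_pt``.  Complete-case:
    reports missing any requested covariate are dropped (count logged).
    Covariates with a single level after filtering are dropped with a
    warning.  Returns the univariate table and the multivariate fit (None
    when nothing passes the univariate screen).
    """
    design = RegressionDesign(outcome_pt=outcome_pt,
                              target_synonyms=tuple(target_synonyms))
    df = _covariate_frame(case_reports, design)
    if df["outcome"].sum() == 0:
        raise ValueError(f"outcome PT {outcome_pt!r} absent from the data")
    before = len(df)
    df = df.dropna(subset=list(covariates)).reset_index(drop=True)
    if before - len(df):
        log.info("regression_workflow: dropped %d incomplete reports", before - len(df))
    usable = []
    for cov in covariates:
        if df[cov].nunique() < 2:
            log.warning("covariate %s has a single level after filtering; dropped", cov)
            continue
        usable.append(cov)
    uni_rows = []
    passed = []
    for cov in usable:
        X = pd.DataFrame({"intercept": 1.0, cov: df[cov].astype(float)})
        try:
            fit = fit_logistic(X, df["outcome"])
        except (SeparationError, RuntimeError, ValueError) as exc:
            log.warning("univariate fit for %s failed: %s", cov, exc)
            uni_rows.append({"term": cov, "n": len(df), "error": str(exc)})
            continue
        i = fit.names.index(cov)
        uni_rows.append(
            {
                "term": cov,
                "n": len(df),
                "odds_ratio": fit.odds_ratios[i],
                "ci_low": fit.ci_low[i],
                "ci_high": fit.ci_high[i],
                "p": fit.p_values[i],
            }
        )
        if fit.p_values[i] < alpha_enter:
            passed.append(cov)
    univariate = pd.DataFrame(uni_rows)
    if not passed:
        log.info("no covariate passed the univariate screen; multivariate skipped")
        return univariate, None
    X = pd.concat(
        [pd.Series(1.0, index=df.index, name="intercept")]
        + [df[c].astype(float) for c in passed],
        axis=1,
    )
    multi = fit_logistic(X, df["outcome"])
    return univariate, multi
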