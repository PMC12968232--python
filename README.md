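# faerspv

Pharmacovigilance signal detection on FAERS spontaneous adverse-event
reports, built for post-marketing safety studies of a single drug (the
bundled defaults follow a study of the CFTR-modulator combination
lumacaftor/ivacaftor, Orkambi, in cystic fibrosis).  It is a library
first — `import faerspv` — with a thin `faers-pv` CLI for the end-to-end
pipeline, and a synthetic-FAERS generator with known ground truth so that
every stage is testable without downloading the real database.

## What it computes

**Ingestion.** FAERS quarterly `$`-delimited tables (DEMO, DRUG, REAC,
INDI, THER, OUTC) are parsed, deduplicated by the FDA-recommended rule
(keep the most recent `FDA_DT` per `CASEID`, ties broken by the highest
`PRIMARYID`), stripped of deleted cases, and assembled into per-report
case records for a target drug identified by an exact-match synonym list
(primary-suspect role only).

**Disproportionality.** For every preferred term (PT) or system organ
class (SOC), a 2×2 table of PT *records* (report × distinct term) is
formed — a: target drug & term, b: target drug & other terms, c/d the
same for all other drugs — and two statistics are computed:

- reporting odds ratio, ROR = ad/bc, with Wald 95% CI
  exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)); Haldane +0.5 on all cells when
  one is zero;
- BCPNN information component, IC = log2((a+½)/(E+½)) with
  E = (a+b)(a+c)/N, and its lower credibility bound
  IC025 = IC − 3.3(a+½)^−1/2 − 2(a+½)^−3/2.

A term is a positive signal only when n ≥ 3 **and** ROR CI lower bound
> 1 **and** IC025 > 0.  Sensitivity re-analyses: monotherapy-only
reports, and same-indication comparator drugs (ivacaftor, tezacaftor/
ivacaftor by default).

**Prioritization.** Each flagged signal scores 0–2 points on reporting
rate, ROR CI lower bound, case-fatality rate, and DME/IME clinical
relevance; totals 0–2 / 3–5 / 6–8 map to low / medium / high priority.
Signal origin is classified as *expected* (on the drug label),
*disease-expected* (flagged for every comparator) or *unexpected*.

**Stratified analysis.** A modified ROR compares each term between two
strata of the target drug's reports (sex, weight, dosing frequency,
fatality), with chi-square tests and Benjamini–Hochberg adjustment;
univariate → multivariate logistic regression identifies independent
risk factors for reporting a chosen outcome PT (default: depression).

**Time to onset.** TTO = event date − earliest target-drug therapy
start (full dates only, 1 day ≤ TTO ≤ 25 y).  Onsets are binned
(30-day intervals plus “>360”), summarized per SOC (median, IQR) and
fitted by maximum-likelihood Weibull; the shape parameter β classifies
the hazard: CI < 1 early failure, CI ∋ 1 random, CI > 1 wear-out.
Subgroups are compared with log-rank, Wilcoxon rank-sum and Dunn tests.

## Worked example

```sh
python examples/simulate_and_screen.py
```

```
reports after dedup + deleted-case removal: 4950
target-drug reports: 500; PT records in database: 6517
expected ROR for the planted pair: 4.630

term                      n     ROR  ROR low   IC025  flagged
Depression               86    4.56     3.48    1.26  True
Metabolic acidosis       28    1.46     0.97   -0.18  False
...
```

A θ=5 odds multiplier was planted for (ORKAMBI, Depression) on a 2%
background; the record-level expected ROR is p′/p = 4.63, the screen
estimates 4.56, and only the planted term passes the dual threshold —
every other term stays below at least one of the two bounds.  The other
`examples/` scripts walk through priority scoring, the subgroup volcano
screen, the depression regression, the time-to-onset analysis, and the
full pipeline (`faers-pv run-all --out out/ --seed 0`), whose manifest
records the monotone filter chain raw → deduplicated → deleted-removed
→ target-selected.

Real FAERS quarters are analysed the same way with
`RunConfig(input_mode="faers", faers_dir=..., quarters=[...],
pt_soc_path=...)`; a user-supplied PT→SOC mapping TSV is required
(MedDRA is licensed and not bundled), as are label/DME/IME term lists
for prioritization.

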