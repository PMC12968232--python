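# Methods

## The data model

FAERS is a spontaneous reporting system: each safety report carries one
or more suspect/concomitant drug rows, a set of MedDRA preferred terms
(PTs), demographics with heavy missingness, outcome codes and therapy
dates.  Reports arrive in versions; the deduplication rule keeps, per
`CASEID`, the row with the latest `FDA_DT` and breaks ties by the
highest `PRIMARYID`.  An unparseable `FDA_DT` sorts as oldest, so a
versioned case never survives on a corrupt date alone.  From 2019Q4
onward quarters ship "deleted case" lists; those caseids are removed
after deduplication.

The counting unit for every disproportionality statistic is the **PT
record** — one row per (report, distinct PT).  A report with two PTs
contributes two records; duplicate PTs within one report collapse to
one.  This distinction (reports vs records) is forced by the data:
report-level and record-level denominators differ by the mean number of
PTs per report, and all 2×2 cells here partition the records.

Drug identification is exact matching of normalized names (uppercase,
punctuation runs collapsed) against a synonym list — never substring —
so a bare "IVACAFTOR" synonym cannot accidentally capture combination
products.  Only rows with the primary-suspect (PS) role select a report.

## Disproportionality statistics

ROR = ad/bc with the Wald CI on the log scale.  When any cell is zero
the Haldane +0.5 correction is applied to all four cells and the result
is marked `corrected`; with the correction disabled a zero-a table
yields NaN (an undefined-signal marker), never an exception.

The BCPNN information component uses the closed-form shrinkage
estimator IC = log2((a+½)/(E+½)), E = (a+b)(a+c)/N, with
IC025 = IC − 3.3(a+½)^−1/2 − 2(a+½)^−3/2.  This is the default because
it has no free prior hyperparameters; a delta-method variant with
symmetric unit priors (`variant="gamma"`) is selectable.  The shrinkage
makes IC conservative for small a and *non-monotone* in a when the a
cell dominates both margins; the monotonicity property is therefore
asserted only in the realistic regime (a small relative to b and c).

Thresholds — n ≥ 3, ROR CI lower bound > 1, IC025 > 0, both met
simultaneously — follow standard pharmacovigilance practice and are
config-overridable.  Under the null reporting model the joint flag rate
among eligible terms measures well below 5% (the IC025 shrinkage
dominates), which the acceptance suite verifies over 200 simulations.

## Priority scoring and origin

The four criteria (reporting rate, ROR CI lower bound, case-fatality
rate, DME/IME relevance) score 0–2 each.  The published band edges
overlap at 1%/10%, 2/5 and 25%/50%; they are resolved upper-inclusive
for the middle band (e.g. a rate of exactly 10% scores 1), giving a
deterministic, exhaustively testable banding.  Label, DME and IME term
lists are user-supplied; no licensed list content ships with the
package.  Origin classification: a flagged term on the label is
*expected*; otherwise, if every same-indication comparator drug also
flags it, it is *disease-expected* (an indication effect, not a drug
effect); otherwise *unexpected*.  A missing comparator result counts as
not flagged.

## Stratified screens and regression

The modified ROR reuses the same 2×2 estimator on two strata of the
target drug's records (so the subgroup ROR is bit-identical to
`ror_estimate` on the subgroup table); inference combines the Wald CI
with a chi-square test without continuity correction (Yates optional)
and Benjamini–Hochberg adjustment *within each stratum-variable screen*
(the multiplicity family is per screen, not global — a documented
choice).  Direction: CI lower bound > 1 with adjusted p < α flags group
1, upper bound < 1 flags group 2.

Logistic regression is a complete-case workflow: reports missing any
requested covariate are dropped and counted; covariates reduced to a
single level are removed with a warning; univariate fits at p < 0.05
gate entry to the multivariate model.  Fits are maximum likelihood
(Newton) with Wald CIs; non-convergence within 50 iterations and
(quasi-)complete separation raise explicit errors with the diverging
coefficients — separation is reported, not resolved (no Firth penalty).
Reference levels are female, health-professional reporter, United
States, BID dosing, 18–65 years, non-monotherapy.

## Time to onset

TTO = event date − earliest valid full therapy-start date of the target
drug, per report.  Partial (YYYYMM / YYYY) or missing dates, intervals
≤ 0 (the Weibull support is positive, so same-day onset is excluded)
and intervals above 9,125 days (25 years, the implausibility cap — the
rule itself is a documented package choice) are excluded with
per-reason counts.

The Weibull fit solves the one-dimensional profile-likelihood equation
for the shape by bracketed root finding, recovers the scale in closed
form, and takes Wald CIs from the observed information on the (log
shape, log scale) parametrization, exponentiated back — positive bounds
by construction.  Failure typing is a total function of the shape CI:
upper < 1 early, lower > 1 wear-out, else random.  Cross-checks against
an independent general-purpose optimizer agree to 4 significant digits;
at n = 1,592 (the study-sized scenario) the shape estimator's bias on
integer-day data is below 0.01 and CI coverage sits in the low 90s.

Log-rank tests treat every report as an observed event (spontaneous
reports carry no censoring time), matching the cumulative-incidence
usage; the Wilcoxon rank-sum test uses the exact null distribution when
min(n) ≤ 8 without ties, otherwise the normal approximation with tie
and continuity corrections.  Dunn's pairwise test is rank-based with
tie correction and BH adjustment across pairs.

## The synthetic generator

The generator emulates the structure the analysis assumes: one
primary-suspect drug per report (multinomial over a catalog), per-PT
Bernoulli events conditional on the drug, demographics with the
missingness profile of the real report stream (>80% missing weight,
~41% missing age, ~27% missing frequency), therapy-start/event/receipt
dates consistent with a sampled onset (default Weibull shape 0.79,
scale 407 d, i.e. median ≈ 256 d), geometric reporting lag (mean 30 d),
injected duplicate case versions (same caseid, later `FDA_DT`, higher
`PRIMARYID`, identical content) and deleted-case lists.  Partial and
invalid date strings corrupt a configurable fraction of rows.  Files
are byte-identical under a fixed seed.

Associations are planted as odds multipliers on the background PT
probability: p′/(1−p′) = θ·p/(1−p).  Because the counting unit is the
record, the exact expected ROR of a planted pair is p′/p (4.63 for θ=5
on p=0.02), which `GroundTruth` stores alongside expected cell means;
rejection-sampling of empty-PT reports rescales both cells of each drug
row by the same factor and leaves this expectation unchanged.  Planting
one PT also deflates the same drug's other terms slightly (masking), so
the "unplanted pairs have expected ROR 1" property holds exactly only
in the null configuration — truth values are always computed
numerically from the full probability matrix.

What the generator does **not** model: drug co-prescription correlation
beyond independent concomitant draws, PT–PT correlation within a
report, covariate-dependent reporting probabilities (except in the
dedicated regression scenario below), secular trends, or real MedDRA
vocabulary.  Passing tests therefore demonstrate correctness of the
statistical machinery under a known model, not real-world performance.

The regression scenario (`simulate_regression_cases`) is separate: it
plants a logistic model for one outcome PT on report covariates at the
study's complete-case size (n = 3,440), by default only a male
protective effect (log-odds ln 0.224) over an 8% female baseline
prevalence — high enough that the rare male cell keeps enough events
for stable maximum-likelihood estimation across replicates, which is
what the recovery tests measure.

## Pipeline and determinism

`run_analysis` executes ingest → dedup → select → screen → prioritize
→ stratify → regress → TTO → describe, writes every stage's table as
TSV, and records a manifest with the monotone filter chain and all
exclusion counters.  Any stage failure aborts with the stage name.  All
randomness flows from one seed; wall-clock timestamps are recorded only
when `record_timestamps` is set, so default reruns are byte-identical.
If the configured regression outcome PT is absent from the assembled
cases the regression stage is recorded as skipped in the manifest notes
rather than aborting the run (the outcome's presence depends on the
data, not on a configuration error).  The bundled synthetic study uses
4,000 reports — large enough for every stage to have non-trivial input,
small enough to run in seconds.

Indication filtering (e.g. restricting to cystic fibrosis reports) is a
config switch, off by default, since signal detection on the full
stream is the primary analysis and the restriction is a sensitivity
choice.

## Known limitations

- No legacy (pre-2014) FAERS layout, no download client, no RPSR table.
- SOC-level statistics are computed on records (one per report × SOC),
  not unique reports; both conventions exist in the literature.
- The TTO unit is one sample per report (the per-record alternative is
  available by expanding samples over PTs manually).
- No interval censoring or parametric survival regression.
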