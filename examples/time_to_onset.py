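"""Time-to-onset analysis: onset intervals, Weibull failure typing, 30-day
bins, per-SOC medians and subgroup comparisons."""

import faerspv as f

cfg = f.default_synthetic_config(seed=3, n_reports=8000)
tables, truth = f.generate_tables(cfg)
retained = f.remove_deleted_cases(
    f.deduplicate(tables.demo), tables.deleted_caseids, tables.demo
)
target = f.select_drug_reports(tables.drug, ("ORKAMBI",)) & retained
cases = f.assemble_cases(tables, target, cfg.pt_to_soc, ("ORKAMBI",))

samples, excluded = f.compute_tto(cases)
print(f"valid onset samples: {len(samples)}; excluded by reason: {dict(excluded)}")

fit = f.weibull_fit([s.days for s in samples])
lo, hi = fit.shape_ci
print(f"Weibull shape {fit.shape:.3f} (95% CI {lo:.3f}-{hi:.3f}), "
      f"scale {fit.scale:.0f} d -> {fit.failure_class} failure")
print("(shape < 1 with the CI below 1: the event hazard falls with time on")
print(" therapy, i.e. most onsets cluster early -- the generating shape is 0.79)")
print()
bins = f.binned_counts(samples)
print(bins[bins["n"] > 0].to_string(index=False))
print()
groups = {}
for s in samples:
    g = s.strata.get("sex")
    if g:
        groups.setdefault(g, []).append(s.days)
chi2, df, p = f.logrank_test(list(groups.values()))
_, wp = f.wilcoxon_rank_sum(*list(groups.values())[:2])
print(f"sex comparison: log-rank chi2 {chi2:.3f} (df {df}, p {p:.3f}); "
      f"Wilcoxon p {wp:.3f}")
print("no sex effect is planted, so both tests should be non-significant.")
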