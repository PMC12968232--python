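"""Score flagged signals on the four-criterion clinical priority
framework and classify their origin (expected / disease-expected /
unexpected) against label terms and comparator screens."""

import faerspv as f

cfg = f.default_synthetic_config(seed=11, n_reports=6000)
tables, truth = f.generate_tables(cfg)
retained = f.remove_deleted_cases(
    f.deduplicate(tables.demo), tables.deleted_caseids, tables.demo
)
records = f.pt_record_table(tables, retained, cfg.pt_to_soc)
target = f.select_drug_reports(tables.drug, ("ORKAMBI",)) & retained
cases = f.assemble_cases(tables, target, cfg.pt_to_soc, ("ORKAMBI",))

primary = f.screen_all(records, target)
flagged = [r for r in primary if r.flagged]
comp_flags = {}
for name in ("KALYDECO", "SYMDEKO"):
    res = f.comparator_screen(records, tables.drug, (name,), name)
    comp_flags[name] = {r.term for r in res if r.flagged}

label_terms = {"Infective pulmonary exacerbation of cystic fibrosis", "Dyspnoea"}
ime_terms = {"Depression", "Suicidal ideation"}
total_records = sum(c.n_records for c in cases)
deaths = {}
for c in cases:
    if c.fatal:
        for pt in c.pts:
            deaths[pt] = deaths.get(pt, 0) + 1

print(f"{'term':<22}{'pts':>4}  category  origin")
for r in flagged:
    rel = "IME" if r.term in ime_terms else "none"
    s = f.score_priority(r.term, r.n_cases, total_records, r.ror_low,
                         deaths.get(r.term, 0), rel)
    o = f.classify_signal_origin(
        r.term, label_terms,
        {k: r.term in v for k, v in comp_flags.items()},
    )
    print(f"{r.term:<22}{s.total:>4}  {s.category:<8}  {o.origin}")
print()
print("Points: reporting rate, ROR CI lower bound, case fatality rate and")
print("DME/IME relevance, each 0-2; totals 0-2/3-5/6-8 map to low/medium/high.")
print("Origin: on the label -> expected; flagged for every comparator CF drug")
print("-> disease-expected; otherwise unexpected (a candidate new risk).")
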