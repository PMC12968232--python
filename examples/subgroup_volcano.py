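"""Sex-stratified modified-ROR screen of target-drug PT records.

The modified ROR compares a term's reporting odds between two strata of
the target drug's own reports; BH-adjusted chi-square p-values plus the
CI position assign the risk direction."""

import pandas as pd

import faerspv as f

rng_rows = []
import numpy as np

rng = np.random.default_rng(5)
pid = 0
for i in range(2000):
    sex = "F" if rng.random() < 0.5 else "M"
    p_enriched = 0.22 if sex == "F" else 0.06  # planted female-enriched term
    term = "Chest discomfort" if rng.random() < p_enriched else f"Background {rng.integers(12)}"
    pid += 1
    rng_rows.append({"primaryid": str(pid), "pt": term, "sex": sex})
records = pd.DataFrame(rng_rows)

results = f.subgroup_screen(records, "sex", "M", "F")
print(f"{'term':<18}{'a':>5}{'b':>6}{'c':>5}{'d':>6}{'ROR':>7}{'p.adj':>10}  direction")
for s in results[:5]:
    print(f"{s.term:<18}{s.a:>5}{s.b:>6}{s.c:>5}{s.d:>6}{s.ror:>7.2f}"
          f"{s.p_adj:>10.2e}  {s.direction}")
print()
print("direction=group2 means the female stratum carries the signal: the ROR")
print("CI upper bound is below 1 with adjusted p < 0.05 (male is group 1).")
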