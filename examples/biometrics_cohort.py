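"""Biometric indices and maturity grouping on a small simulated cohort.

Generates a 20-fish cohort (14 immature, 6 pubertal), computes condition
factors, assigns maturity groups from GSI, and applies the histology
filters used to characterise the cohort.
"""

from testispec import (assign_maturity_group, compute_cf, filter_cohort,
                       has_observation, stage_above)
from testispec.simulate import generate_cohort

records, meta = generate_cohort(seed=1)

print("fish  weight(g)  length(cm)  CF    GSI(%)  group")
for r in records[:5]:
    cf = compute_cf(r.body_weight, r.fork_length)
    print(f"{r.fish_id}  {r.body_weight:8.1f}  {r.fork_length:9.2f}  "
          f"{cf:4.2f}  {r.gsi:6.3f}  {assign_maturity_group(r.gsi)}")
print(f"... ({len(records)} fish total)\n")

advanced, n_adv = filter_cohort(records, stage_above("SPA"))
oocytes, n_ooc = filter_cohort(records, has_observation("oocytes"))
groups = [assign_maturity_group(r.gsi) for r in records]

print(f"fish with germ cells beyond spermatogonia A: {n_adv}")
print(f"fish with oocyte observations:               {n_ooc}")
print(f"immature / pubertal split:                   "
      f"{groups.count('immature')} / {groups.count('pubertal')}")
print("\nAdvanced histology coincides with the pubertal GSI group; oocytes "
      "appear only in immature testes (an intersex-like state).")
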