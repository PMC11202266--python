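"""Serum steroid panel statistics against testis size (GSI).

Generates a hormone panel whose androgen-like analytes are calibrated to a
true Pearson correlation of 0.83 with GSI, then recovers per-analyte
correlations, pubertal/immature fold changes, and t-test p-values.
"""

import pandas as pd

from testispec import (assign_maturity_group, correlate_with_index,
                       group_difference_test, group_fold)
from testispec.simulate import ANDROGEN_ANALYTES, generate_hormones

panel, truth = generate_hormones(seed=3)
gsi = truth.samples["gsi"]
groups = gsi.map(assign_maturity_group)

r, mean_r, sd_r = correlate_with_index(panel, gsi,
                                       summary_analytes=ANDROGEN_ANALYTES)
fold = group_fold(panel, groups)
p = group_difference_test(panel, groups)

table = pd.DataFrame({"pearson_r": r, "fold": fold, "p_value": p}).round(3)
print(table.to_string())
print(f"\nmean r across the five androgen-like analytes: "
      f"{mean_r:.2f} (SD {sd_r:.2f})")
print("Androgens track testis growth (high r, large pubertal fold); the "
      "cortisol-like analytes do not (r near 0, fold near 1).")
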