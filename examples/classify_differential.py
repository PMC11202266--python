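"""HSA/LSA classification on a simulated two-compartment testis transcriptome.

Simulates expression where the germinative compartment grows from ~30 % to
~80 % of the tissue, classifies genes by log2 expression ratio and t-test,
and shows how compartment growth alone (zero regulation for most genes)
produces apparent differential "specific activity".
"""

import pandas as pd

from testispec import differential_activity
from testispec.simulate import SimulationConfig, generate_testis_matrix

cfg = SimulationConfig(n_genes=2000)
matrix, truth = generate_testis_matrix(cfg, seed=2)
groups = pd.Series(truth.samples["group"].to_numpy(),
                   index=truth.samples.index)

results = differential_activity(matrix, groups)
print(results["class"].value_counts().to_string())

summary = results.join(truth.genes["category"]).groupby("category")
print("\nmean log2-ER by planted gene category:")
print(summary["log2_er"].mean().round(2).to_string())
print("\nGerminative-exclusive genes rise ~log2(0.8/0.3) = 1.4 and "
      "interstitial-exclusive genes fall ~log2(0.2/0.7) = -1.8 purely "
      "through compartment growth; shared genes stay flat unless a "
      "regulation multiplier was planted.")
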