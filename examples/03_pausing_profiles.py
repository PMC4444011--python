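"""Promoter-proximal pausing indices and treatment redistribution.

Simulates Pol II ChIP coverage for a cohort with planted paused/repressed,
stimulated and unaffected genes, then classifies each gene from the
control-vs-treated change in promoter (first 500 bp) and gene-body
occupancy.
"""

import pandas as pd

from pausewave import PausingSimParams, simulate_chip_coverage, tiling_genes
from pausewave.pausing import pausing_table

params = PausingSimParams(n_paused=100, n_stimulated=100, n_null=300, seed=3)
genes = tiling_genes(params.n_genes)
tracks, truth = simulate_chip_coverage(params, genes)

table = pausing_table(tracks["control"], tracks["treated"], genes,
                      span=5000, bin=25, promoter_window=500)

print("called classes:", table["class"].value_counts().to_dict())
print()
merged = table.join(truth, rsuffix="_true")
print(pd.crosstab(merged["class_true"], merged["class"],
                  rownames=["planted"], colnames=["called"]))
paused = merged[merged["class_true"] == "paused_repressed"]
print()
print(f"median pausing index, paused genes:  "
      f"control {paused['pi_control'].median():.2f} -> "
      f"treated {paused['pi_treated'].median():.2f}")
print()
print("A promoter gain (>= 1.5x) without a body gain is the signature of")
print("polymerases accumulating promoter-proximally on repressed genes;")
print("a joint promoter+body gain marks transcriptional stimulation.")
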