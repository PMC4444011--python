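"""Call reactive genes with the low-expression-corrected fold change.

Simulates a three-condition count matrix (mock, CDK9-inhibited "drb",
hnRNP A1/A2-depleted "sia") with planted responders, builds the corrected
fold-change table for the drb-vs-mock contrast and calls reactive genes at
the 2-fold threshold (|corrected log2 FC| >= 1).
"""

from pausewave import (
    CountSimParams,
    build_expression_table,
    call_reactive_genes,
    simulate_counts,
    synthetic_gene_models,
)

cm, truth = simulate_counts(CountSimParams(n_genes=5000, seed=1))
genes = synthetic_gene_models(cm.gene_ids, seed=1)

table = build_expression_table(cm, genes, treated="drb", mock="mock")
hits = call_reactive_genes(table, threshold=1.0)

print(f"genes analyzed:        {len(table)}")
print(f"reactive at 2-fold:    {len(hits)} "
      f"({(hits['direction'] == 'up').sum()} up, "
      f"{(hits['direction'] == 'down').sum()} down)")
planted = truth["group"].isin(["shared", "drb_only"])
print(f"planted responders:    {planted.sum()}")
strong = planted & (truth["l2fc_drb"].abs() >= 1.5)
recalled = truth[strong].index.isin(hits.index).mean()
print(f"recall of strong (|l2fc|>=1.5) planted effects: {recalled:.2f}")
print()
print("The corrected statistic adds gamma^-exp to |log2 FC|, so weakly")
print("expressed genes can clear the threshold; calls therefore include")
print("low-expression genes whose fold change alone would fall short.")
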