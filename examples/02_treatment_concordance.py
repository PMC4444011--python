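"""Treatment-concordance overlap of two reactive gene sets.

Both treatments act through the same elongation-factor axis, so their
reactive sets should overlap far beyond chance and their fold changes
should correlate on the shared genes.  The simulator plants that structure
(correlated effects on shared responders); this script measures it back
with the Venn partition, a one-sided Fisher exact test and Pearson R^2.
"""

from pausewave import (
    CountSimParams,
    build_expression_table,
    concordance,
    expressed_universe,
    simulate_counts,
    synthetic_gene_models,
)

params = CountSimParams(seed=11)  # 10k genes, shared_corr = 0.83
cm, truth = simulate_counts(params)
genes = synthetic_gene_models(cm.gene_ids, seed=11)

table_sia = build_expression_table(cm, genes, "sia", "mock")
table_drb = build_expression_table(cm, genes, "drb", "mock")
universe = expressed_universe(cm, genes)

res = concordance(table_sia, table_drb, universe, threshold=1.0)

print(f"universe (expressed genes):  {res.universe_size}")
print(f"reactive in siA1/A2 only:    {res.a_only}")
print(f"reactive in DRB only:        {res.b_only}")
print(f"reactive in both:            {res.both}")
print(f"overlap fraction |AnB|/|A|:  {res.overlap_fraction:.3f}")
print(f"Fisher exact p (greater):    {res.fisher_p:.3g}")
print(f"Pearson R^2 on shared set:   {res.pearson_r2:.3f}")
print()
print("An overlap fraction above 0.5 with a vanishing p-value reproduces")
print("the planted common-defect regime; R^2 tracks the planted effect")
print("correlation (0.83^2 ~ 0.69); only genes with a raw 2-fold change")
print("enter the correlation, mirroring how the concordance map is drawn.")
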