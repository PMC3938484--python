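"""Permutation-test differential expression on a spiked synthetic study.

Generates a two-condition study (3 vs 3 replicates) with 10 genes shifted
4-fold among 490 nulls, runs the pooled-null permutation t-test with BH
q-values, applies the q < 0.05 and |log2 FC| >= 1 screen, and compares the
calls with the ground truth. Also shows the packaged C8-challenge reference
table's extreme genes.
"""

from acidstress import expression, synth

study, truth = synth.gen_de_study(n_genes=500, n_spiked=10, seed=123)
results = expression.de_analysis(study, n_perm=2000, seed=123)
hits = expression.call_significant(results)

spiked = set(truth.params["spiked_genes"])
print(f"significant genes: {len(hits)}")
print(f"true spikes recovered: {len(spiked & set(hits.index))} / {len(spiked)}")
print(f"false calls: {len(set(hits.index) - spiked)}")
print("\ntop calls (signed linear ratio):")
print(hits[["log2_fc", "ratio", "p", "q"]].head(5).round(4))

table = expression.load_reference_table()
(top_gene, top_ratio), (bottom_gene, bottom_ratio) = expression.table_extremes(table)
print(f"\nC8 reference table extremes: {top_gene} {top_ratio:+.1f} "
      f"(acid-resistance decarboxylase), {bottom_gene} {bottom_ratio:+.1f} "
      f"(outer-membrane porin)")
print(
    "\nReading: the screen recovers the spiked genes with essentially no "
    "false calls (with only 3 replicates per group the weakest spikes can "
    "sit at the q = 0.05 boundary); in the real challenge data the same "
    "screen tops out at the glutamate-dependent acid resistance system."
)
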