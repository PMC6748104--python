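"""Spectral-count differential proteomics with study-set filters and GSEA.

A membrane-proteome-style comparison is simulated: 800 proteins measured as
spectral counts in 2 conditions x 2 biological x 2 technical replicates,
with 40 proteins shifted up 3 log2 units in the case condition.  Replicate
averages give log2 fold changes, a two-sided Welch t-test gives p-values,
and two nested sets follow: the stringent study set (log2FC >= 1,
p < 0.05) and the GSEA list (p < 0.05, ranked by log2FC) tested against a
gene set containing the truly shifted proteins.
"""

from screenforge import (
    build_study_sets,
    differential_proteins,
    preranked_gsea,
    simulate_spectral_counts,
)

counts, design, truth = simulate_spectral_counts(
    n_proteins=800, n_diff=40, effect_lfc=3.0, mean_count=50,
    dispersion=0.1, seed=5,
)
results = differential_proteins(counts, design)
study, ranked = build_study_sets(results)

shifted = set(truth.loc[truth["is_shifted"], "protein_id"])
print(f"study set (log2FC >= 1, p < 0.05): {len(study)} proteins, "
      f"{len(set(study['protein_id']) & shifted)} truly shifted")
print(f"GSEA list (p < 0.05): {len(ranked)} proteins")

gene_sets = {
    "TRULY_SHIFTED": shifted,
    "RANDOM_DECOY": set(truth["protein_id"].iloc[400:430]),
}
gsea = preranked_gsea(ranked, gene_sets, n_perm=1000, seed=5)
print("\npreranked GSEA against the two sets:")
print(gsea.to_string(index=False))
print("\nThe planted set concentrates at the top of the ranked list")
print("(enrichment score near 1, small permutation p); the decoy does not.")
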