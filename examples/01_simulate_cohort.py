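"""Generate a synthetic IBD biopsy cohort and inspect its structure.

Builds ~165 genotyped individuals contributing ~280 biopsies (repeated
measures, ~40% inflamed), genotypes in Hardy-Weinberg proportions, log2
expression with location/inflammation confounder components and planted
effects, plus 28 cell-type enrichment scores.  Prints the cohort shape and
the ground-truth table used by recovery tests.
"""

from inflaqtl.simulate import simulate_dataset

bundle = simulate_dataset(n_individuals=165, n_genes=200, n_variants=600,
                          n_main=5, n_gxe=3, n_de=5, seed=1)

s = bundle.samples
print(f"samples: {len(s)} from {s['individual_id'].nunique()} individuals")
print(f"inflamed fraction: {s['inflamed'].mean():.2f}")
both = s.groupby("individual_id")["inflamed"].nunique()
print(f"individuals with both an inflamed and a non-inflamed biopsy: {(both == 2).sum()}")
print(f"genotypes: {bundle.genotypes.dosage.shape[0]} samples x "
      f"{bundle.genotypes.dosage.shape[1]} variants, "
      f"MAF range {bundle.genotypes.variants['maf'].min():.2f}-"
      f"{bundle.genotypes.variants['maf'].max():.2f}")
print(f"expression: {bundle.expression.values.shape[0]} genes (log2 scale)")
print(f"cell-type scores: {bundle.celltype_scores.shape[1]} cell types in [0, 1]")
print("\nplanted ground truth (what recovery tests try to find):")
print(bundle.truth.to_string(index=False))
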