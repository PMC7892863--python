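"""Downstream statistics: colocalization, replication, heterogeneity, cohort table.

These operate on summary statistics rather than raw data: Wakefield
approximate Bayes factors enumerate five colocalization hypotheses for an
eQTL signal and a disease GWAS signal in one region; replication is the
percent of eQTL pairs with the same effect direction in an external
dataset; Cochran's Q tests whether effect sizes disagree across studies;
and the cohort table comparisons are chi-square / rank-sum tests.
"""

import numpy as np
import pandas as pd

from inflaqtl.downstream import (cochran_q, cohort_compare, coloc_abf,
                                 replication_rate)

# --- colocalization: one strong variant shared by eQTL and GWAS signals
idx = [f"v{i}" for i in range(100)]
beta = np.zeros(100)
beta[12] = 0.8  # z = 8 at this variant in both traits
eqtl = pd.DataFrame({"beta": beta, "se": np.full(100, 0.1)}, index=idx)
gwas = pd.DataFrame({"beta": 0.9 * beta, "se": np.full(100, 0.1)}, index=idx)
r = coloc_abf(eqtl, gwas)
print("colocalization posteriors (H0..H4):", np.round(r.pp, 4))
print(f"PP4 = {r.pp4:.3f} -> colocalized: {r.colocalized} "
      "(one shared causal variant when PP4 > 0.5)")

null = pd.DataFrame({"beta": np.zeros(100), "se": np.full(100, 1e9)}, index=idx)
print(f"flat region: PP0 = {coloc_abf(null, null).pp[0]:.4f} "
      "(prior arithmetic alone)")

# --- replication: direction concordance from overlap counts
internal = pd.DataFrame({"variant_id": [f"v{i}" for i in range(1113)],
                         "gene_id": "g", "beta": 1.0})
external = internal.copy()
external["beta"] = np.where(np.arange(1113) < 28, -1.0, 1.0)
out = replication_rate(internal, external)
print(f"\nreplication: {out['n_concordant']}/{out['n_overlapping']} same direction "
      f"= {out['percent']}%")

# --- heterogeneity: opposite effects across two studies
het = cochran_q([0.5, -0.5], [0.1, 0.1])
print(f"heterogeneity of opposite effects: Q = {het.Q:.0f}, p = {het.p:.2e} "
      f"-> heterogeneous: {het.heterogeneous}")

# --- cohort table: biopsy location by inflammation status
rows = []
for inflamed, loc, cnt in [(1, "colon", 81), (1, "ileum", 31),
                           (0, "colon", 110), (0, "ileum", 58)]:
    rows += [{"inflamed": inflamed, "location": loc}] * cnt
tab = cohort_compare(pd.DataFrame(rows), "location")
print(f"\ncohort location-by-inflammation chi-square: p = {tab['p']:.2f} "
      "(no significant imbalance)")
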