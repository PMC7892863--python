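"""Genotype x cell-type-enrichment interaction models.

For each inflammation-dependent top eQTL pair and each of the 28 reference
cell types, fits expression ~ intercept + PCs + dosage + score +
dosage:score + kinship random effect, asking whether the eQTL effect scales
with the enrichment of that cell type in the biopsy.  FDR is applied
per coefficient, pooled across all pair x cell-type tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, PCSet
from .genotype import GenotypeMatrix, mean_impute
from .lmm import bh_fdr, fit_lmm_rotated
from .scans import _spectral
from .simulate import CELL_TYPES

log = logging.getLogger(__name__)

__all__ = ["validate_celltype_names", "celltype_interaction_scan", "summarize_celltype_counts"]


def validate_celltype_names(scores: pd.DataFrame) -> list[str]:
    """Warn about score columns that are not among the 28 reference cell types."""
    unknown = [c for c in scores.columns if c not in CELL_TYPES]
    if unknown:
        log.warning("unrecognized cell-type names: %s", unknown)
    return unknown


def celltype_interaction_scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    K,
    pcs: PCSet,
    scores: pd.DataFrame,
    top_pairs: pd.DataFrame,
    alpha: float = 0.05,
    fdr_universe: str = "pooled",
) -> pd.DataFrame:
    """Interaction of eSNP dosage with continuous cell-type enrichment.

    ``top_pairs`` needs gene_id/variant_id columns (the inflammation-
    dependent top eQTLs).  Returns one record per pair x cell type with
    per-coefficient p and q values; constant score columns are skipped with
    a reason.  ``fdr_universe='per_celltype'`` adjusts within each cell type
    instead of pooling all tests.
    """
    if top_pairs.empty:
        return pd.DataFrame()
    sk = _spectral(K)
    samples = expr.values.columns
    n = len(samples)
    scores = scores.loc[samples]
    dosage = mean_impute(geno.dosage.loc[samples])
    pc_mat = pcs.selected().loc[samples].to_numpy(float)
    Bt = sk.rotate(np.column_stack([np.ones(n), pc_mat]))
    Yt = sk.rotate(expr.values.to_numpy(float).T).T
    gene_pos = {g: i for i, g in enumerate(expr.values.index)}

    const_cols = [c for c in scores.columns if scores[c].nunique() < 2]
    if const_cols:
        log.info("skipping constant cell-type score column(s): %s", const_cols)
    score_cols = [c for c in scores.columns if c not in const_cols]
    St = sk.rotate(scores[score_cols].to_numpy(float))

    rows, skipped = [], [{"cell_type": c, "reason": "constant score"} for c in const_cols]
    for gene_id, variant_id in top_pairs[["gene_id", "variant_id"]].itertuples(index=False):
        dos = dosage[variant_id].to_numpy(float)
        gt = sk.rotate(dos)
        gi = gene_pos[gene_id]
        for ci, cell in enumerate(score_cols):
            sc = scores[cell].to_numpy(float)
            Xt = np.column_stack([Bt, gt, St[:, ci], sk.rotate(dos * sc)])
            try:
                fit = fit_lmm_rotated(Yt[gi], Xt, sk.d)
            except ValueError:
                skipped.append({"gene_id": gene_id, "variant_id": variant_id,
                                "cell_type": cell, "reason": "collinear"})
                continue
            rows.append({
                "gene_id": gene_id, "variant_id": variant_id, "cell_type": cell,
                "beta_genotype": fit.beta[-3], "p_genotype": fit.p[-3],
                "beta_score": fit.beta[-2], "p_score": fit.p[-2],
                "beta_interaction": fit.beta[-1], "se_interaction": fit.se[-1],
                "p_interaction": fit.p[-1],
            })
    rec = pd.DataFrame(rows)
    if rec.empty:
        rec.attrs["skipped"] = skipped
        return rec
    for coef in ("genotype", "score", "interaction"):
        if fdr_universe == "per_celltype":
            rec[f"q_{coef}"] = rec.groupby("cell_type")[f"p_{coef}"].transform(
                lambda s: bh_fdr(s.to_numpy())
            )
        else:
            rec[f"q_{coef}"] = bh_fdr(rec[f"p_{coef}"].to_numpy())
    rec["significant_interaction"] = rec["q_interaction"] < alpha
    rec.attrs["skipped"] = skipped
    return rec


def summarize_celltype_counts(
    records: pd.DataFrame, alpha: float = 0.05, min_count_displayed: int = 3
) -> pd.DataFrame:
    """Per-gene count of cell types with a significant dosage x score interaction.

    ``displayed`` marks genes whose count exceeds ``min_count_displayed``
    (the plotting filter for the per-gene interaction-count figure).
    """
    if records.empty:
        return pd.DataFrame(columns=["gene_id", "n_celltypes", "displayed"])
    sig = records[records["q_interaction"] < alpha]
    counts = (
        sig.groupby("gene_id")["cell_type"].nunique().rename("n_celltypes").reset_index()
    )
    counts["displayed"] = counts["n_celltypes"] > min_count_displayed
    return counts
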