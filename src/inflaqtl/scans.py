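"""Association scans: differential expression, cis-eQTL and GxE interaction mapping.

All scans share one engine: the kinship matrix is eigendecomposed once, every
response and covariate is rotated into that basis, and each gene(-variant)
model is a REML mixed-model fit (`lmm.fit_lmm_rotated`).  Multiple testing is
controlled with Benjamini-Hochberg FDR pooled over all tests of a scan; the
inflammation-interaction scan additionally adjusts the genotype, environment
and interaction coefficients separately across the per-gene top pairs, which
is what the interaction-only / genotype-and-interaction classification reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, PCSet
from .genotype import GenotypeMatrix, KinshipMatrix, mean_impute
from .lmm import SpectralKinship, bh_fdr, fit_lmm_rotated

log = logging.getLogger(__name__)

__all__ = [
    "differential_expression",
    "enumerate_cis_pairs",
    "cis_eqtl_scan",
    "interaction_scan",
    "InteractionResult",
    "classify_top_egenes",
    "permutation_calibration",
]

_CONTRASTS = ("inflammation", "diagnosis", "location")


def aligned_pc(pcs: PCSet, values) -> int | None:
    """1-based index of the selected PC most (rank-)correlated with ``values``.

    This is how the scans decide which PC to drop from the covariates so a
    contrast is not regressed away: the component capturing biopsy location
    is excluded when testing location/diagnosis, and the component capturing
    inflammation is excluded when testing inflammation (in the motivating
    cohort these are the first and second PCs respectively).
    """
    from scipy.stats import spearmanr

    v = np.asarray(values, dtype=float)
    k = pcs.n_selected or pcs.scores.shape[1]
    best, best_r = None, 0.0
    for i in range(1, k + 1):
        r = abs(float(spearmanr(pcs.scores[f"PC{i}"], v).statistic))
        if np.isfinite(r) and r > best_r:
            best, best_r = i, r
    return best


def _spectral(K) -> SpectralKinship:
    if isinstance(K, SpectralKinship):
        return K
    if isinstance(K, KinshipMatrix):
        return SpectralKinship(K.to_numpy(), sample_ids=K.sample_ids)
    return SpectralKinship(np.asarray(K))


def _contrast_vector(samples: pd.DataFrame, contrast: str) -> np.ndarray:
    if contrast == "inflammation":
        v = samples["inflamed"].to_numpy(float)
    elif contrast == "diagnosis":
        # IBD-unclassified grouped with UC; CD coded 1
        v = (samples["diagnosis"] == "CD").to_numpy(float)
    elif contrast == "location":
        v = (samples["location"] == "ileum").to_numpy(float)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    if np.unique(v).size < 2:
        raise ValueError(f"contrast {contrast!r} is constant across samples")
    return v


def differential_expression(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    K,
    contrast: str,
    pcs: PCSet,
    fdr_max: float = 0.001,
    abs_beta_min: float = 1.5,
) -> pd.DataFrame:
    """Mixed-model differential expression for one binary contrast.

    Per gene: expression ~ intercept + selected PCs + contrast + kinship
    random effect.  The PC most aligned with the contrast (see
    :func:`aligned_pc`) is excluded from the covariates so the contrast
    itself is not regressed away.  Genes are flagged when q < ``fdr_max``
    and |beta| > ``abs_beta_min``.
    """
    if contrast not in _CONTRASTS:
        raise ValueError(f"contrast must be one of {sorted(_CONTRASTS)}")
    v = _contrast_vector(samples, contrast)
    sk = _spectral(K)
    n = len(samples)
    drop = aligned_pc(pcs, pd.Series(v, index=samples.index).loc[pcs.scores.index].to_numpy())
    exclude = [drop] if drop else []
    pc_mat = pcs.selected(exclude=exclude).loc[samples.index].to_numpy(float)
    X = np.column_stack([np.ones(n), pc_mat, v])
    Xt = sk.rotate(X)
    Yt = sk.rotate(expr.values.to_numpy(float).T).T  # genes x n, rotated
    rows = []
    for gi, gid in enumerate(expr.values.index):
        fit = fit_lmm_rotated(Yt[gi], Xt, sk.d)
        rows.append({"gene_id": gid, "variant_id": "", "contrast": contrast,
                     "beta": fit.beta[-1], "se": fit.se[-1], "t": fit.wald_t[-1],
                     "p": fit.p[-1], "variance_ratio": fit.variance_ratio})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["flagged"] = (out["q"] < fdr_max) & (out["beta"].abs() > abs_beta_min)
    return out


def enumerate_cis_pairs(
    genes: pd.DataFrame, variants: pd.DataFrame, window: int = 500_000
) -> pd.DataFrame:
    """All gene-variant pairs with the variant within ``window`` bp of the gene center.

    Gene coordinates are 0-based half-open; the center floor((start+end)/2)
    is converted to a 1-based position and compared with the 1-based variant
    position; the boundary is inclusive.
    """
    if (genes["end"] <= genes["start"]).any():
        bad = genes.index[genes["end"] <= genes["start"]].tolist()
        raise ValueError(f"genes with end <= start: {bad[:5]}")
    centers = ((genes["start"] + genes["end"]) // 2 + 1).astype(int)
    out = []
    for chrom in genes["chrom"].unique():
        vmask = (variants["chrom"] == chrom).to_numpy()
        vids = variants.index.to_numpy()[vmask]
        pos = variants["pos"].to_numpy(int)[vmask]
        for gid in genes.index[genes["chrom"] == chrom]:
            c = int(centers[gid])
            hit = np.abs(pos - c) <= window
            for vid, p in zip(vids[hit], pos[hit]):
                out.append({"gene_id": gid, "variant_id": vid, "chrom": chrom,
                            "pos": int(p), "distance": int(abs(int(p) - c))})
    return pd.DataFrame(out, columns=["gene_id", "variant_id", "chrom", "pos", "distance"])


def _prep_scan(expr, geno, K, pcs, pairs, exclude_pcs=None):
    """Shared rotation bookkeeping for the pair scans."""
    sk = _spectral(K)
    samples = expr.values.columns
    n = len(samples)
    dosage = mean_impute(geno.dosage.loc[samples])
    pc_mat = pcs.selected(exclude=exclude_pcs).loc[samples].to_numpy(float)
    base = np.column_stack([np.ones(n), pc_mat])
    Bt = sk.rotate(base)
    Yt = sk.rotate(expr.values.to_numpy(float).T).T
    Gt = sk.rotate(dosage.to_numpy(float))
    gene_pos = {g: i for i, g in enumerate(expr.values.index)}
    var_pos = {v: j for j, v in enumerate(dosage.columns)}
    return sk, dosage, Bt, Yt, Gt, gene_pos, var_pos


def cis_eqtl_scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    K,
    pcs: PCSet,
    pairs: pd.DataFrame,
    fdr_max: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Main-effect cis-eQTL scan over the supplied gene-variant pairs.

    Per pair: expression ~ intercept + all selected PCs + dosage + kinship
    random effect; BH FDR pooled across all tested pairs.  Returns
    (records, top table) where the top table holds, per eGene (any pair
    q < ``fdr_max``), its most significant eSNP with ties broken by smaller
    distance to the gene center then lexicographic variant id.
    """
    if pairs.empty:
        raise ValueError("no cis pairs to test")
    sk, dosage, Bt, Yt, Gt, gene_pos, var_pos = _prep_scan(expr, geno, K, pcs, pairs)
    rows, n_skipped = [], 0
    for gene_id, variant_id, dist in pairs[["gene_id", "variant_id", "distance"]].itertuples(index=False):
        gi, vj = gene_pos[gene_id], var_pos[variant_id]
        if dosage.iloc[:, vj].nunique() < 2:
            n_skipped += 1
            continue
        Xt = np.column_stack([Bt, Gt[:, vj]])
        fit = fit_lmm_rotated(Yt[gi], Xt, sk.d)
        rows.append({"gene_id": gene_id, "variant_id": variant_id, "distance": dist,
                     "beta": fit.beta[-1], "se": fit.se[-1], "t": fit.wald_t[-1],
                     "p": fit.p[-1], "variance_ratio": fit.variance_ratio})
    if n_skipped:
        log.info("cis scan skipped %d monomorphic pair(s)", n_skipped)
    rec = pd.DataFrame(rows)
    rec["q"] = bh_fdr(rec["p"].to_numpy())
    sig = rec[rec["q"] < fdr_max]
    top = (
        sig.sort_values(["gene_id", "p", "distance", "variant_id"])
        .groupby("gene_id", sort=True)
        .head(1)
        .reset_index(drop=True)
    )
    rec.attrs["n_skipped_monomorphic"] = n_skipped
    return rec, top


@dataclass
class InteractionResult:
    """Stage-1 pair records and stage-2 per-eGene top pairs with separate FDRs."""

    records: pd.DataFrame      # all pairs: p_genotype/p_env/p_interaction, q_interaction
    top: pd.DataFrame          # one row per significant eGene, q_* recomputed
    p_threshold: float         # largest stage-1 p_interaction passing q < alpha
    alpha: float


def interaction_scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    K,
    pcs: PCSet,
    env: np.ndarray | pd.Series,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
    exclude_pcs: list[int] | None = None,
    top_fdr_universe: str = "top",
) -> InteractionResult:
    """Genotype x environment interaction scan over cis pairs.

    Stage 1 fits, per pair, expression ~ intercept + PCs + dosage + env +
    dosage:env + kinship random effect, and adjusts the interaction p-values
    with BH across all pairs.  Stage 2 keeps the most significant pair per
    eGene with stage-1 q < ``alpha`` and recomputes BH separately for the
    genotype, environment and interaction coefficients across those top pairs
    (set ``top_fdr_universe='stage1'`` to adjust across all significant pairs
    instead).  ``env`` must align with the expression sample order; the PC
    capturing the environment should be excluded via ``exclude_pcs``.
    """
    env = np.asarray(env, dtype=float).ravel()
    if np.unique(env).size < 2:
        raise ValueError("environment variable is constant")
    if len(env) != expr.values.shape[1]:
        raise ValueError("env length does not match the number of samples")
    if exclude_pcs is None:
        drop = aligned_pc(pcs, pd.Series(env, index=expr.values.columns)
                          .loc[pcs.scores.index].to_numpy())
        exclude_pcs = [drop] if drop else []
    sk, dosage, Bt, Yt, Gt, gene_pos, var_pos = _prep_scan(
        expr, geno, K, pcs, pairs, exclude_pcs=exclude_pcs
    )
    env_t = sk.rotate(env)
    GEt = sk.rotate(dosage.to_numpy(float) * env[:, None])
    rows, skipped = [], []
    for gene_id, variant_id, dist in pairs[["gene_id", "variant_id", "distance"]].itertuples(index=False):
        gi, vj = gene_pos[gene_id], var_pos[variant_id]
        if dosage.iloc[:, vj].nunique() < 2:
            skipped.append((gene_id, variant_id, "monomorphic"))
            continue
        Xt = np.column_stack([Bt, Gt[:, vj], env_t, GEt[:, vj]])
        try:
            fit = fit_lmm_rotated(Yt[gi], Xt, sk.d)
        except ValueError:
            skipped.append((gene_id, variant_id, "collinear"))
            continue
        rows.append({
            "gene_id": gene_id, "variant_id": variant_id, "distance": dist,
            "beta_genotype": fit.beta[-3], "se_genotype": fit.se[-3], "p_genotype": fit.p[-3],
            "beta_env": fit.beta[-2], "se_env": fit.se[-2], "p_env": fit.p[-2],
            "beta_interaction": fit.beta[-1], "se_interaction": fit.se[-1],
            "p_interaction": fit.p[-1], "variance_ratio": fit.variance_ratio,
        })
    rec = pd.DataFrame(rows)
    if rec.empty:
        raise ValueError("no testable pairs in interaction scan")
    rec["q_interaction"] = bh_fdr(rec["p_interaction"].to_numpy())
    sig = rec[rec["q_interaction"] < alpha]
    p_threshold = float(sig["p_interaction"].max()) if len(sig) else float("nan")
    top = (
        sig.sort_values(["gene_id", "p_interaction", "distance", "variant_id"])
        .groupby("gene_id", sort=True)
        .head(1)
        .copy()
    )
    universe = sig if top_fdr_universe == "stage1" else top
    for coef in ("genotype", "env", "interaction"):
        q = pd.Series(bh_fdr(universe[f"p_{coef}"].to_numpy()), index=universe.index)
        top[f"q_{coef}"] = q.reindex(top.index).to_numpy()
    top = top.reset_index(drop=True)
    rec.attrs["skipped"] = skipped
    if skipped:
        log.info("interaction scan skipped %d pair(s)", len(skipped))
    return InteractionResult(records=rec, top=top, p_threshold=p_threshold, alpha=alpha)


def classify_top_egenes(top: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Label per-eGene top pairs by what drives them.

    interaction_only: q_interaction < alpha and q_genotype > alpha (the eQTL
    appears only in the interacting context); genotype_and_interaction:
    q_interaction < alpha and q_genotype <= alpha; otherwise not_significant.
    """
    for col in ("q_genotype", "q_interaction"):
        if col not in top.columns:
            raise ValueError(f"missing per-coefficient FDR column {col!r}")
    out = top.copy()
    qi, qg = out["q_interaction"], out["q_genotype"]
    label = np.where(
        qi < alpha,
        np.where(qg > alpha, "interaction_only", "genotype_and_interaction"),
        "not_significant",
    )
    out["class_label"] = label
    return out


def permutation_calibration(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    K,
    pcs: PCSet,
    env: np.ndarray | pd.Series,
    pairs: pd.DataFrame,
    real: InteractionResult,
    n_perm: int = 10,
    seed: int = 0,
    exclude_pcs: list[int] | None = None,
    preserve_individuals: pd.Series | None = None,
) -> dict:
    """Empirical check that the interaction FDR threshold is not driven by chance.

    The environment labels are permuted across samples ``n_perm`` times
    (optionally permuting whole individuals via ``preserve_individuals``);
    each permutation reruns the stage-1 interaction scan and counts pairs
    with p_interaction below the real scan's significance p threshold.  The
    threshold is judged adequate when the mean permuted count is below
    alpha x the real significant-pair count.
    """
    n_real = int((real.records["q_interaction"] < real.alpha).sum())
    report = {"n_real_significant": n_real, "n_perm": n_perm,
              "p_threshold": real.p_threshold, "per_permutation_hits": [],
              "mean_permuted_hits": np.nan, "adequate": None}
    if n_real == 0 or not np.isfinite(real.p_threshold):
        log.warning("no significant interaction pairs; calibration adequacy undefined")
        return report
    rng = np.random.default_rng(seed)
    env = np.asarray(env, dtype=float).ravel()
    if exclude_pcs is None:
        # permuted scans must use the same covariates as the real scan
        drop = aligned_pc(pcs, pd.Series(env, index=expr.values.columns)
                          .loc[pcs.scores.index].to_numpy())
        exclude_pcs = [drop] if drop else []
    for _ in range(n_perm):
        if preserve_individuals is not None:
            codes, uniq = pd.factorize(preserve_individuals)
            perm_env = env.copy()
            perm = rng.permutation(len(uniq))
            # permute individual labels, then broadcast back to samples
            first = pd.Series(env).groupby(codes).first().to_numpy()
            perm_env = first[perm][codes]
        else:
            perm_env = env[rng.permutation(env.size)]
        if np.unique(perm_env).size < 2:
            report["per_permutation_hits"].append(0)
            continue
        res = interaction_scan(expr, geno, K, pcs, perm_env, pairs,
                               alpha=real.alpha, exclude_pcs=exclude_pcs)
        hits = int((res.records["p_interaction"] <= real.p_threshold).sum())
        report["per_permutation_hits"].append(hits)
    report["mean_permuted_hits"] = float(np.mean(report["per_permutation_hits"]))
    report["adequate"] = bool(report["mean_permuted_hits"] < real.alpha * n_real)
    return report
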