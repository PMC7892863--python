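"""Downstream statistics: colocalization, replication, heterogeneity, co-expression.

Colocalization follows the approximate-Bayes-factor framework: per-variant
Wakefield log-ABFs for each trait are combined over the five-hypothesis
enumeration (no association / trait-1 only / trait-2 only / two distinct
causal variants / one shared causal variant), and a region is called
colocalized when the shared-variant posterior PP4 exceeds 0.5.  Replication
against an external eQTL dataset is direction-concordance of effect signs
after allele harmonization; heterogeneity across studies is Cochran's
fixed-effect Q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .expression import ExpressionMatrix, PCSet
from .lmm import bh_fdr

log = logging.getLogger(__name__)

__all__ = [
    "ColocResult",
    "HeterogeneityResult",
    "wakefield_log_abf",
    "coloc_abf",
    "replication_rate",
    "cochran_q",
    "coexpression_scan",
    "cohort_compare",
]


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp: np.ndarray  # (pp0, pp1, pp2, pp3, pp4)
    n_snps: int
    priors: tuple  # (p1, p2, p12)

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def colocalized(self) -> bool:
        return self.pp4 > 0.5


@dataclass
class HeterogeneityResult:
    """Cochran's Q fixed-effect heterogeneity test."""

    Q: float
    df: int
    p: float
    beta_fixed: float = field(default=np.nan)

    @property
    def heterogeneous(self) -> bool:
        return self.p < 0.05


def wakefield_log_abf(beta, se, prior_sd: float = 0.15) -> np.ndarray:
    """Per-variant Wakefield approximate log Bayes factors.

    log ABF = 0.5 log(1 - r) + 0.5 r z^2 with z = beta/se and
    r = prior_sd^2 / (prior_sd^2 + se^2).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    z = beta / se
    r = prior_sd**2 / (prior_sd**2 + se**2)
    return 0.5 * np.log(1.0 - r) + 0.5 * r * z * z


def _se_from_p_maf_n(p, maf, n) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct (beta, se) scale from p-value, MAF and sample size.

    z is recovered from the two-sided p; se is approximated from the
    phenotypic-variance identity se ~ 1/sqrt(2 maf (1-maf) (n + z^2)).
    """
    p = np.asarray(p, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    z = stats.norm.isf(np.clip(p / 2.0, 1e-300, 1.0))
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * (n + z * z))
    return z * se, se


def coloc_abf(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.15,
) -> ColocResult:
    """Five-hypothesis colocalization of two association signals in a region.

    Each stats frame is indexed by variant id and needs either (beta, se) or
    (p, maf, n) columns; variants are inner-joined on id.  Returns the
    normalized posterior over H0..H4 under per-variant priors p1/p2/p12.
    """
    shared = stats1.index.intersection(stats2.index)
    if len(shared) < 2:
        raise ValueError("colocalization needs at least 2 shared variants")
    l1 = _trait_log_abf(stats1.loc[shared], prior_sd1)
    l2 = _trait_log_abf(stats2.loc[shared], prior_sd2)
    m = len(shared)
    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    # H3 sums ABF1_i * ABF2_j over ordered pairs i != j:
    # log(sum_i ABF1_i * sum_j ABF2_j - sum_i ABF1_i ABF2_i)
    tot = lsum1 + lsum2
    lh3_body = tot + np.log1p(-np.exp(np.clip(lsum12 - tot, None, -1e-12)))
    lh = np.array([
        0.0,
        np.log(p1) + lsum1,
        np.log(p2) + lsum2,
        np.log(p1) + np.log(p2) + lh3_body,
        np.log(p12) + lsum12,
    ])
    pp = np.exp(lh - logsumexp(lh))
    return ColocResult(pp=pp, n_snps=m, priors=(p1, p2, p12))


def _trait_log_abf(df: pd.DataFrame, prior_sd: float) -> np.ndarray:
    if {"beta", "se"} <= set(df.columns):
        return wakefield_log_abf(df["beta"], df["se"], prior_sd)
    if {"p", "maf", "n"} <= set(df.columns):
        beta, se = _se_from_p_maf_n(df["p"], df["maf"], df["n"])
        return wakefield_log_abf(beta, se, prior_sd)
    raise ValueError("summary statistics need (beta, se) or (p, maf, n) columns")


def replication_rate(
    internal: pd.DataFrame,
    external: pd.DataFrame,
    match_on: tuple[str, str] = ("variant_id", "gene_id"),
) -> dict:
    """Direction-concordance replication of eQTL pairs in an external dataset.

    Both frames need the match columns and ``beta``; when both carry
    effect_allele/other_allele the external effect is harmonized (sign
    flipped for swapped alleles, mismatched allele pairs dropped and
    counted).  percent = 100 * n_concordant / n_overlapping, two decimals.
    """
    cols = list(match_on)
    merged = internal.merge(external, on=cols, suffixes=("_int", "_ext"))
    n_dropped = 0
    if {"effect_allele_int", "other_allele_int", "effect_allele_ext", "other_allele_ext"} <= set(merged.columns):
        same = (merged["effect_allele_int"] == merged["effect_allele_ext"]) & (
            merged["other_allele_int"] == merged["other_allele_ext"]
        )
        swapped = (merged["effect_allele_int"] == merged["other_allele_ext"]) & (
            merged["other_allele_int"] == merged["effect_allele_ext"]
        )
        n_dropped = int((~(same | swapped)).sum())
        merged = merged[same | swapped].copy()
        merged.loc[swapped[same | swapped], "beta_ext"] *= -1.0
    n_overlap = len(merged)
    if n_overlap == 0:
        log.warning("no overlapping significant pairs; replication percent undefined")
        return {"n_overlapping": 0, "n_concordant": 0, "percent": np.nan,
                "n_dropped_allele_mismatch": n_dropped}
    concordant = np.sign(merged["beta_int"]) == np.sign(merged["beta_ext"])
    n_conc = int(concordant.sum())
    return {
        "n_overlapping": n_overlap,
        "n_concordant": n_conc,
        "percent": round(100.0 * n_conc / n_overlap, 2),
        "n_dropped_allele_mismatch": n_dropped,
    }


def cochran_q(betas, ses) -> HeterogeneityResult:
    """Fixed-effect heterogeneity: Q = sum w (beta - beta_FE)^2, w = 1/se^2.

    p from chi-square with k-1 degrees of freedom.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size < 2:
        raise ValueError("heterogeneity needs at least 2 studies")
    if (ses <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta_fe = float(np.sum(w * betas) / np.sum(w))
    Q = float(np.sum(w * (betas - beta_fe) ** 2))
    df = betas.size - 1
    return HeterogeneityResult(Q=Q, df=df, p=float(stats.chi2.sf(Q, df)), beta_fixed=beta_fe)


def coexpression_scan(
    expr: ExpressionMatrix,
    target_gene: str,
    pcs: PCSet,
    r_min: float = 0.5,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Genes co-expressed with a target after removing PC-captured structure.

    All genes are residualized on the selected PCs (ordinary least squares);
    the target's residuals are Spearman-correlated with every other gene's,
    BH-adjusted across genes, and pairs with |r| > ``r_min`` and
    q < ``fdr_max`` are flagged.  The target itself is excluded.
    """
    if target_gene not in expr.values.index:
        raise ValueError(f"target gene {target_gene!r} not in expression matrix")
    Y = expr.values.to_numpy(float).T  # samples x genes
    P = pcs.selected().loc[expr.values.columns].to_numpy(float)
    X = np.column_stack([np.ones(len(Y)), P])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ coef
    genes = list(expr.values.index)
    ti = genes.index(target_gene)
    tr = R[:, ti]
    keep, rs, ps = [], [], []
    for j, g in enumerate(genes):
        if j == ti:
            continue
        col = R[:, j]
        if np.allclose(col, col[0]):
            log.info("skipping constant residual vector for gene %s", g)
            continue
        r, p = stats.spearmanr(tr, col)
        keep.append(g)
        rs.append(r)
        ps.append(p)
    out = pd.DataFrame({"gene_id": keep, "target": target_gene, "r": rs, "p": ps})
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["coexpressed"] = (out["r"].abs() > r_min) & (out["q"] < fdr_max)
    return out


def cohort_compare(samples: pd.DataFrame, variable: str, grouping: str = "inflamed") -> dict:
    """Group comparison for one cohort-table variable.

    Categorical variables: Pearson chi-square on the contingency table, with
    Yates continuity correction iff the table is 2x2.  Continuous variables:
    two-sided Wilcoxon rank-sum with normal approximation, tie correction and
    continuity correction.
    """
    g = samples[grouping]
    if g.nunique() != 2:
        raise ValueError(f"grouping {grouping!r} must be binary")
    x = samples[variable]
    if x.nunique() < 2:
        raise ValueError(f"variable {variable!r} is constant")
    if pd.api.types.is_numeric_dtype(x) and x.nunique() > 5:
        lo, hi = sorted(g.unique())
        res = stats.mannwhitneyu(x[g == lo], x[g == hi], alternative="two-sided",
                                 method="asymptotic")
        return {"test": "wilcoxon", "statistic": float(res.statistic),
                "df": None, "p": float(res.pvalue)}
    table = pd.crosstab(g, x)
    if (table.to_numpy() < 5).any():
        log.warning("contingency table for %s has expected/observed cells < 5", variable)
    is_2x2 = table.shape == (2, 2)
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=is_2x2)
    return {"test": "chi2", "statistic": float(chi2), "df": int(dof), "p": float(p)}
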