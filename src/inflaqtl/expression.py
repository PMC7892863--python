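"""Expression normalization and principal-component confounder handling.

Raw counts are normalized between samples with trimmed-mean-of-M-values (TMM)
scaling factors and converted to log2 counts-per-million.  PCA on the
normalized matrix provides confounder covariates for every downstream model;
the number of components to keep is chosen at the inflection (elbow) of the
scree curve, and samples far out on the leading components are flagged as
outliers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PCSet",
    "tmm_factors",
    "tmm_log_normalize",
    "pca_and_outliers",
    "select_num_pcs",
    "pc_covariate_association",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with gene coordinates.

    ``values``: DataFrame (index = gene ids, columns = sample ids).
    ``genes``: DataFrame indexed by gene id with chrom, start, end
    (0-based half-open).  ``is_log`` records whether values are raw counts
    or normalized log2 units.
    """

    values: pd.DataFrame
    genes: pd.DataFrame
    is_log: bool = False

    def __post_init__(self):
        if self.genes is not None and not self.values.index.equals(self.genes.index):
            self.genes = self.genes.loc[self.values.index]
        if not self.is_log and (self.values.to_numpy() < 0).any():
            raise ValueError("raw counts must be nonnegative")
        if self.genes is not None and {"start", "end"} <= set(self.genes.columns):
            if (self.genes["end"] <= self.genes["start"]).any():
                bad = self.genes.index[self.genes["end"] <= self.genes["start"]].tolist()
                raise ValueError(f"genes with end <= start: {bad[:5]}")

    @property
    def sample_ids(self):
        return list(self.values.columns)

    @property
    def gene_ids(self):
        return list(self.values.index)


@dataclass
class PCSet:
    """Principal-component scores with their explained-variance curve."""

    scores: pd.DataFrame  # samples x components, columns PC1..PCk
    variance_explained: np.ndarray
    n_selected: int = 0

    def selected(self, exclude: list[int] | None = None) -> pd.DataFrame:
        """Scores of the first ``n_selected`` PCs, minus 1-based ``exclude``."""
        keep = [i for i in range(1, self.n_selected + 1) if not (exclude and i in exclude)]
        return self.scores[[f"PC{i}" for i in keep]]


def tmm_factors(
    counts: np.ndarray,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, one per sample (column).

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean.  For each sample, log ratios M against the reference
    are trimmed by ``logratio_trim`` (two-sided) and absolute intensities A
    by ``sum_trim``; the factor is 2 to the (inverse-variance) weighted mean
    of the surviving M values.  Factors are rescaled to geometric mean 1.
    Genes with a zero count in either member of a pair are excluded from the
    pair's factor estimation.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError(f"samples with zero total counts at columns {np.where(lib == 0)[0].tolist()}")
    with np.errstate(divide="ignore", invalid="ignore"):
        uq = np.array([np.quantile(counts[:, j][counts[:, j] > 0] / lib[j], 0.75) if (counts[:, j] > 0).any() else 0.0
                       for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(counts.shape[1])
    xr, Nr = counts[:, ref], lib[ref]
    for j in range(counts.shape[1]):
        x, N = counts[:, j], lib[j]
        use = (x > 0) & (xr > 0)
        if use.sum() < 2 or j == ref:
            continue
        fx, fr = x[use] / N, xr[use] / Nr
        M = np.log2(fx / fr)
        A = 0.5 * np.log2(fx * fr)
        if np.allclose(M, M[0], atol=1e-10):
            factors[j] = 2.0 ** M[0]
            continue
        n = M.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
        rank_m = stats.rankdata(M, method="average")
        rank_a = stats.rankdata(A, method="average")
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            continue
        if weighted:
            w = 1.0 / ((N - x[use]) / (N * x[use]) + (Nr - xr[use]) / (Nr * xr[use]))
        else:
            w = np.ones(n)
        factors[j] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def tmm_log_normalize(counts: ExpressionMatrix, pseudocount: float = 0.5) -> ExpressionMatrix:
    """TMM-normalize raw counts and return log2 counts-per-million.

    output = log2(count / (library_size * factor) * 1e6 + pseudocount).
    All-zero genes take the value log2(pseudocount) in every sample.
    """
    if counts.is_log:
        raise ValueError("expression is already normalized")
    vals = counts.values.to_numpy(dtype=float)
    lib = vals.sum(axis=0)
    if (lib == 0).any():
        bad = [counts.values.columns[j] for j in np.where(lib == 0)[0]]
        raise ValueError(f"samples with zero total counts: {bad}")
    factors = tmm_factors(vals)
    cpm = vals / (lib * factors)[None, :] * 1e6
    out = np.log2(cpm + pseudocount)
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns),
        genes=counts.genes,
        is_log=True,
    )


def _pca(values: pd.DataFrame, n_components: int | None = None):
    """PCA across samples of gene-centered log expression."""
    from sklearn.decomposition import PCA

    X = values.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    k = min(X.shape) - 1 if n_components is None else n_components
    k = max(1, min(k, min(X.shape)))
    pca = PCA(n_components=k, svd_solver="full", random_state=0)
    scores = pca.fit_transform(X)
    cols = [f"PC{i}" for i in range(1, k + 1)]
    return (
        pd.DataFrame(scores, index=values.columns, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )


def pca_and_outliers(
    expr: ExpressionMatrix, outlier_sd: float = 4.0, n_components: int | None = None
) -> tuple[PCSet, list[str]]:
    """PCA on normalized expression with leading-component outlier removal.

    Samples whose PC1 or PC2 score exceeds ``outlier_sd`` standard deviations
    of that component are flagged; PCA is recomputed on the remaining samples
    and the returned scores/variances refer to the cleaned data.
    """
    if not expr.is_log:
        raise ValueError("expression must be normalized before PCA")
    if expr.values.shape[1] < 3:
        raise ValueError("PCA requires at least 3 samples")
    scores, var = _pca(expr.values, n_components)
    outliers: list[str] = []
    for pc in ("PC1", "PC2"):
        if pc in scores:
            s = scores[pc]
            flag = np.abs(s) > outlier_sd * s.std(ddof=1)
            outliers.extend(scores.index[flag])
    outliers = sorted(set(outliers))
    if outliers:
        log.info("removed %d expression outlier sample(s): %s", len(outliers), outliers)
        kept = expr.values.drop(columns=outliers)
        scores, var = _pca(kept, n_components)
    return PCSet(scores=scores, variance_explained=var), outliers


def select_num_pcs(pcs: PCSet, max_pcs: int = 18, default: int = 10) -> int:
    """Number of PCs to keep: the inflection (elbow) of the scree curve.

    The elbow is the index i (1-based, i <= max_pcs) maximizing the relative
    second difference (v_i - 2 v_{i+1} + v_{i+2}) / v_i of the explained
    variance curve v; ties go to the smallest index.  A flat curve (all
    second differences zero) falls back to ``default`` with a warning.
    """
    v = np.asarray(pcs.variance_explained, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 components to locate an inflection")
    m = min(max_pcs, v.size - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = (v[:m] - 2.0 * v[1 : m + 1] + v[2 : m + 2]) / v[:m]
    d2 = np.where(np.isfinite(d2), d2, 0.0)
    if np.allclose(d2, 0.0, atol=1e-15):
        warnings.warn("flat scree curve; falling back to default PC count")
        return min(default, v.size)
    return int(np.argmax(d2)) + 1


def pc_covariate_association(pcs: PCSet, covariates: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each selected PC with each (numeric) covariate.

    Returns one row per (component, covariate) with r, r^2 and the two-sided
    p-value; constant covariates yield a flagged row with NaN statistics.
    """
    n_pc = pcs.n_selected or pcs.scores.shape[1]
    rows = []
    cov = covariates.loc[pcs.scores.index]
    for i in range(1, n_pc + 1):
        s = pcs.scores[f"PC{i}"].to_numpy()
        for name in cov.columns:
            x = pd.to_numeric(cov[name], errors="coerce").to_numpy(dtype=float)
            ok = ~np.isnan(x)
            if np.unique(x[ok]).size < 2:
                rows.append({"component": i, "covariate": name, "r": np.nan,
                             "r2": np.nan, "p": np.nan, "constant": True})
                continue
            r, p = stats.spearmanr(s[ok], x[ok])
            rows.append({"component": i, "covariate": name, "r": r, "r2": r * r,
                         "p": p, "constant": False})
    return pd.DataFrame(rows)
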