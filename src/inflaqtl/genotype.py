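"""Genotype containers, variant QC, and identity-by-state kinship.

Dosages are additive minor-allele counts in {0, 1, 2} (float, NaN = missing),
stored samples x variants.  QC thresholds default to the conventions used for
post-imputation best-guess genotypes: call rate >= 0.99, MAF >= 5%, and a
Hardy-Weinberg chi-square p-value >= 1e-6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "annotate_variants",
    "hwe_chi2",
    "variant_qc",
    "ibs_kinship",
    "mean_impute",
]


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage matrix plus per-variant metadata.

    ``dosage``: DataFrame (index = sample ids, columns = variant ids), entries
    in {0, 1, 2} or NaN.  ``variants``: DataFrame indexed by variant id with
    columns chrom, pos (1-based), ref, alt, maf, call_rate, hwe_p.
    """

    dosage: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self):
        if not self.dosage.columns.equals(self.variants.index):
            self.variants = self.variants.loc[self.dosage.columns]
        if not all(dt.kind == "f" for dt in self.dosage.dtypes):
            self.dosage = self.dosage.astype(float)
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def sample_ids(self):
        return list(self.dosage.index)

    @property
    def variant_ids(self):
        return list(self.dosage.columns)


@dataclass
class KinshipMatrix:
    """Symmetric sample x sample genetic similarity in [0, 1], diagonal 1."""

    values: pd.DataFrame

    @property
    def sample_ids(self):
        return list(self.values.index)

    def to_numpy(self):
        return self.values.to_numpy(dtype=float)


def hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-square).

    Compares observed genotype counts with the proportions expected at the
    sample allele frequency.  Monomorphic input returns 1 by convention.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be nonnegative")
    n = counts.sum()
    if n == 0:
        raise ValueError("at least one genotype count must be positive")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def annotate_variants(dosage: pd.DataFrame, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Compute per-variant MAF, call rate, and HWE p from a dosage frame.

    MAF and HWE use non-missing dosages only; call rate is the non-missing
    fraction.  Positional metadata (chrom/pos/ref/alt) is carried over from
    ``meta`` when provided.
    """
    vals = dosage.to_numpy(dtype=float)
    missing = np.isnan(vals)
    n_obs = (~missing).sum(axis=0).astype(float)
    call_rate = n_obs / vals.shape[0]
    with np.errstate(invalid="ignore"):
        af = np.nansum(vals, axis=0) / (2 * np.maximum(n_obs, 1))
    maf = np.minimum(af, 1 - af)
    hwe = np.ones(vals.shape[1])
    for j in range(vals.shape[1]):
        col = vals[~missing[:, j], j]
        if col.size == 0:
            continue
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        hwe[j] = hwe_chi2(n2, n1, n0)
    out = pd.DataFrame(
        {"maf": maf, "call_rate": call_rate, "hwe_p": hwe}, index=dosage.columns
    )
    if meta is not None:
        for col in ("chrom", "pos", "ref", "alt"):
            if col in meta.columns:
                out[col] = meta[col].reindex(dosage.columns)
    return out


def variant_qc(
    g: GenotypeMatrix,
    call_rate_min: float = 0.99,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, dict]:
    """Filter variants on call rate, MAF and HWE; return matrix + QC report.

    A variant is retained iff call_rate >= call_rate_min, MAF >= maf_min and
    hwe_p >= hwe_p_min.  The report counts removals per criterion (a variant
    failing several criteria is counted under each).
    """
    for name, v in (("call_rate_min", call_rate_min), ("maf_min", maf_min), ("hwe_p_min", hwe_p_min)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    v = g.variants
    fail_cr = v["call_rate"] < call_rate_min
    fail_maf = v["maf"] < maf_min
    fail_hwe = v["hwe_p"] < hwe_p_min
    keep = ~(fail_cr | fail_maf | fail_hwe)
    report = {
        "n_input": int(len(v)),
        "n_removed_call_rate": int(fail_cr.sum()),
        "n_removed_maf": int(fail_maf.sum()),
        "n_removed_hwe": int(fail_hwe.sum()),
        "n_retained": int(keep.sum()),
        "thresholds": {
            "call_rate_min": call_rate_min,
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
        },
    }
    if report["n_retained"] == 0:
        log.warning("variant QC removed every variant")
    kept = g.dosage.loc[:, keep.to_numpy()]
    return GenotypeMatrix(dosage=kept, variants=v.loc[keep.to_numpy()]), report


def ibs_kinship(g: GenotypeMatrix | pd.DataFrame, psd_floor: float = 1e-8) -> KinshipMatrix:
    """Identity-by-state similarity between samples.

    similarity(i, j) = 1 - sum_m |g_im - g_jm| / (2 * M_ij) over the M_ij
    variants non-missing in both samples.  Samples carrying identical dosage
    vectors (e.g. two biopsies of one individual) get similarity exactly 1.
    If the smallest eigenvalue falls below -1e-8 the matrix is ridged (and
    rescaled back to unit diagonal) so that it is positive semidefinite.
    """
    dosage = g.dosage if isinstance(g, GenotypeMatrix) else g
    vals = dosage.to_numpy(dtype=float)
    n = vals.shape[0]
    valid = ~np.isnan(vals)
    if not valid.any(axis=1).all():
        bad = dosage.index[~valid.any(axis=1)].tolist()
        raise ValueError(f"samples with all-missing genotypes: {bad}")
    # |a-b| over {0,1,2} decomposes onto genotype-class indicator products
    ind = [((vals == k) & valid).astype(float) for k in (0.0, 1.0, 2.0)]
    a0, a1, a2 = ind
    dist = (
        a0 @ a1.T + a1 @ a0.T + a1 @ a2.T + a2 @ a1.T + 2.0 * (a0 @ a2.T + a2 @ a0.T)
    )
    overlap = valid.astype(float) @ valid.astype(float).T
    if (overlap == 0).any():
        i, j = np.argwhere(overlap == 0)[0]
        raise ValueError(
            f"samples {dosage.index[i]!r} and {dosage.index[j]!r} share no non-missing variants"
        )
    sim = 1.0 - dist / (2.0 * overlap)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    w = np.linalg.eigvalsh(sim)
    if w[0] < -psd_floor:
        ridge = psd_floor - w[0]
        log.info("IBS kinship ridged by %.3g to restore positive semidefiniteness", ridge)
        sim = (sim + ridge * np.eye(n)) / (1.0 + ridge)
    return KinshipMatrix(values=pd.DataFrame(sim, index=dosage.index, columns=dosage.index))


def mean_impute(dosage: pd.DataFrame) -> pd.DataFrame:
    """Replace missing dosages by the per-variant mean (for LMM designs)."""
    vals = dosage.to_numpy(dtype=float).copy()
    means = np.nanmean(vals, axis=0)
    idx = np.where(np.isnan(vals))
    vals[idx] = np.take(means, idx[1])
    return pd.DataFrame(vals, index=dosage.index, columns=dosage.columns)
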