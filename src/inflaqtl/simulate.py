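"""Synthetic cohorts with the structure the eQTL analysis assumes.

The generator emulates an IBD biopsy study: ~165 genotyped individuals
contributing ~280 intestinal biopsy samples (some individuals sampled both
inflamed and non-inflamed), biallelic dosages in Hardy-Weinberg proportions
with MAF >= 5%, log-scale expression carrying latent confounder components
(biopsy location on the leading component, inflammation on the second),
per-individual random intercepts that the kinship random effect must absorb,
planted cis-eQTL / interaction / differential-expression effects recorded in
a ground-truth table, and 28 cell-type enrichment scores in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genotype import GenotypeMatrix, annotate_variants

log = logging.getLogger(__name__)

__all__ = [
    "CELL_TYPES",
    "DEFAULT_INFLAMMATION_SHIFTS",
    "simulate_cohort",
    "genome_layout",
    "simulate_genotypes",
    "expand_to_samples",
    "plant_effects",
    "simulate_expression",
    "simulate_celltype_scores",
    "simulate_dataset",
    "Bundle",
]

#: The 28 reference cell types scored in intestinal mucosa.
CELL_TYPES = [
    "cDC", "pDC", "M1 Macrophages", "M2 Macrophages", "NK cells",
    "CD4+ naive T cells", "CD4+ Tcm", "CD4+ Tem", "CD8+ naive T cells",
    "CD8+ Tcm", "CD8+ Tem", "Tgd cells", "Th1 cells", "Th2 cells", "Tregs",
    "NKT cells", "naive B cells", "Plasma cells", "Memory B cells",
    "Class-switched memory B cells", "Basophils", "Mast cells",
    "Neutrophils", "Eosinophils", "Endothelial cells", "Epithelial cells",
    "Fibroblasts", "Smooth muscle cells",
]

#: Default mean score shifts in inflamed tissue: innate/adaptive effector
#: populations enriched when inflamed, M2 macrophages and basophils depleted.
DEFAULT_INFLAMMATION_SHIFTS = {
    "M1 Macrophages": 0.20,
    "Plasma cells": 0.15,
    "Neutrophils": 0.15,
    "Th2 cells": 0.10,
    "Tregs": 0.10,
    "M2 Macrophages": -0.10,
    "Basophils": -0.05,
}

_MEDS = ["mesalazines", "steroids", "thiopurines", "anti_tnf"]
_CIS_WINDOW = 500_000


def simulate_cohort(
    n_individuals: int = 165,
    samples_per_individual: float | int | dict = 1.7,
    inflamed_fraction: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample table with repeated biopsies per individual.

    ``samples_per_individual`` may be an int (exact count), a float in
    [1, 2] (expected count; each individual contributes a second sample with
    probability expectation - 1), or a dict {count: probability}.
    Inflammation status is drawn per sample, so individuals with two samples
    frequently contribute one inflamed and one non-inflamed biopsy.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    if not 0.0 < inflamed_fraction < 1.0:
        raise ValueError("inflamed_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if isinstance(samples_per_individual, dict):
        counts = rng.choice(
            list(samples_per_individual), size=n_individuals,
            p=list(samples_per_individual.values()),
        ).astype(int)
    elif isinstance(samples_per_individual, (int, np.integer)) or float(samples_per_individual).is_integer():
        k = int(samples_per_individual)
        if k < 1:
            raise ValueError("samples_per_individual must be positive")
        counts = np.full(n_individuals, k)
    else:
        e = float(samples_per_individual)
        if not 1.0 <= e <= 2.0:
            raise ValueError("fractional samples_per_individual must lie in [1, 2]")
        counts = 1 + (rng.random(n_individuals) < (e - 1.0)).astype(int)

    width = len(str(n_individuals))
    rows = []
    k_sample = 0
    for i in range(n_individuals):
        ind = f"I{i + 1:0{width}d}"
        diagnosis = rng.choice(["CD", "UC", "IBDU"], p=[0.62, 0.28, 0.10])
        sex = rng.choice(["F", "M"], p=[0.61, 0.39])
        meds = {m: int(rng.random() < p) for m, p in zip(_MEDS, (0.30, 0.20, 0.27, 0.20))}
        age0 = max(16.0, rng.normal(42.0, 15.0))
        for _ in range(counts[i]):
            k_sample += 1
            rows.append({
                "sample_id": f"S{k_sample:04d}",
                "individual_id": ind,
                "inflamed": int(rng.random() < inflamed_fraction),
                "location": rng.choice(["colon", "ileum"], p=[0.68, 0.32]),
                "diagnosis": diagnosis,
                "sex": sex,
                "age": round(age0, 1),
                **meds,
            })
    return pd.DataFrame(rows).set_index("sample_id")


def genome_layout(
    n_genes: int,
    n_variants: int,
    n_chrom: int = 10,
    gene_spacing: int = 1_000_000,
    gene_length: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene annotation (0-based half-open) and variant positions (1-based).

    Genes are spaced ``gene_spacing`` bp apart across ``n_chrom`` chromosomes;
    variants are assigned round-robin to genes and placed uniformly within
    +/- 400 kb of the gene center so every variant is cis to its host gene.
    """
    rng = np.random.default_rng(seed)
    per_chrom = int(np.ceil(n_genes / n_chrom))
    genes = []
    for g in range(n_genes):
        chrom = str(g // per_chrom + 1)
        idx = g % per_chrom
        start = 500_000 + idx * gene_spacing
        genes.append({"gene_id": f"G{g + 1:05d}", "chrom": chrom,
                      "start": start, "end": start + gene_length})
    genes = pd.DataFrame(genes).set_index("gene_id")
    centers = ((genes["start"] + genes["end"]) // 2 + 1).to_numpy()
    variants = []
    for v in range(n_variants):
        g = v % n_genes
        pos = int(centers[g] + rng.integers(-400_000, 400_001))
        variants.append({"variant_id": f"rs{v + 1:06d}", "chrom": genes["chrom"].iloc[g],
                         "pos": max(1, pos)})
    variants = pd.DataFrame(variants, columns=["variant_id", "chrom", "pos"])
    variants = variants.set_index("variant_id")
    variants["ref"] = "A"
    variants["alt"] = "G"
    return genes, variants


def simulate_genotypes(
    n_individuals: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    variants_meta: pd.DataFrame | None = None,
    individual_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Individual-level dosages under Hardy-Weinberg proportions.

    Each variant draws a MAF uniformly from ``maf_range`` and dosages as
    Binomial(2, MAF).  Returns an individual-indexed GenotypeMatrix; use
    :func:`expand_to_samples` to replicate rows over repeated biopsies.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a nonempty interval within (0, 0.5]")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_variants)
    dos = rng.binomial(2, mafs[None, :], size=(n_individuals, n_variants)).astype(float)
    if individual_ids is None:
        width = len(str(n_individuals))
        individual_ids = [f"I{i + 1:0{width}d}" for i in range(n_individuals)]
    if variants_meta is None:
        vids = [f"rs{j + 1:06d}" for j in range(n_variants)]
        variants_meta = pd.DataFrame(
            {"chrom": "1", "pos": 10_000 * (np.arange(n_variants) + 1),
             "ref": "A", "alt": "G"},
            index=pd.Index(vids, name="variant_id"),
        )
    dosage = pd.DataFrame(dos, index=individual_ids, columns=variants_meta.index)
    meta = annotate_variants(dosage, variants_meta)
    return GenotypeMatrix(dosage=dosage, variants=meta)


def expand_to_samples(g: GenotypeMatrix, samples: pd.DataFrame) -> GenotypeMatrix:
    """Replicate individual-level genotype rows to one row per sample."""
    missing = set(samples["individual_id"]) - set(g.dosage.index)
    if missing:
        raise ValueError(f"individuals without genotypes: {sorted(missing)[:5]}")
    dosage = g.dosage.loc[samples["individual_id"]].set_axis(samples.index)
    return GenotypeMatrix(dosage=dosage, variants=g.variants.copy())


def plant_effects(
    genes: pd.DataFrame,
    variants_meta: pd.DataFrame,
    n_main: int = 0,
    n_gxe: int = 0,
    n_de: int = 0,
    main_beta: float = 0.8,
    gxe_beta: float = 1.0,
    de_beta: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pick random genes and cis variants for the requested planted effects.

    Returns a truth table with columns gene_id, variant_id, effect_class,
    effect_size, context.  Distinct genes are used for each effect.
    """
    rng = np.random.default_rng(seed)
    centers = (genes["start"] + genes["end"]) // 2 + 1
    cis: dict[str, list[str]] = {}
    for vid, row in variants_meta.iterrows():
        near = genes.index[(genes["chrom"] == row["chrom"])
                           & (np.abs(centers - row["pos"]) <= _CIS_WINDOW)]
        for gid in near:
            cis.setdefault(gid, []).append(vid)
    eligible = [gid for gid in genes.index if cis.get(gid)]
    need = n_main + n_gxe + n_de
    if need > len(genes):
        raise ValueError("not enough genes for the requested planted effects")
    chosen = list(rng.choice(genes.index.to_numpy(), size=need, replace=False))
    rows = []
    for cls, cnt, beta, ctx in (
        ("main_eqtl", n_main, main_beta, ""),
        ("gxe_inflammation", n_gxe, gxe_beta, "inflamed"),
        ("de_shift", n_de, de_beta, "inflamed"),
    ):
        for _ in range(cnt):
            gid = chosen.pop()
            if cls == "de_shift":
                vid = ""
            else:
                if not cis.get(gid):  # re-draw among eligible genes
                    gid = eligible[int(rng.integers(len(eligible)))]
                vid = cis[gid][int(rng.integers(len(cis[gid])))]
            rows.append({"gene_id": gid, "variant_id": vid, "effect_class": cls,
                         "effect_size": float(beta), "context": ctx})
    return pd.DataFrame(rows, columns=["gene_id", "variant_id", "effect_class",
                                       "effect_size", "context"])


def _validate_truth(truth: pd.DataFrame, genes: pd.DataFrame,
                    variants_meta: pd.DataFrame) -> None:
    centers = (genes["start"] + genes["end"]) // 2 + 1
    for _, row in truth.iterrows():
        if row["gene_id"] not in genes.index:
            raise ValueError(f"planted effect on unknown gene {row['gene_id']!r}")
        if not np.isfinite(row["effect_size"]):
            raise ValueError("planted effect sizes must be finite")
        vid = row["variant_id"]
        if not vid:
            continue
        if vid not in variants_meta.index:
            raise ValueError(f"planted effect on unknown variant {vid!r}")
        v = variants_meta.loc[vid]
        if (v["chrom"] != genes.loc[row["gene_id"], "chrom"]
                or abs(v["pos"] - centers[row["gene_id"]]) > _CIS_WINDOW):
            raise ValueError(
                f"planted variant {vid!r} is outside the cis window of {row['gene_id']!r}"
            )


def simulate_expression(
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    planted: pd.DataFrame | list | None,
    n_genes: int,
    genes_meta: pd.DataFrame | None = None,
    n_confounder_components: int = 4,
    confounder_sds: tuple = (0.9, 0.7, 0.35, 0.25),
    noise_sd: float = 0.8,
    individual_random_sd: float = 0.8,
    celltype_scores: pd.DataFrame | None = None,
    seed: int = 0,
):
    """Log2-scale expression with confounders, kinship structure, and planted effects.

    expression = baseline + confounder components + planted effects
    + per-individual random intercept (sd ``individual_random_sd``)
    + N(0, ``noise_sd``) noise.  The first confounder component's sample
    scores follow biopsy location and the second follows inflammation status,
    so a scree/PC analysis of the output reproduces the location-on-PC1,
    inflammation-on-PC2 structure.  Returns (ExpressionMatrix, truth table).

    ``genotypes`` must be sample-level (rows = sample ids).  Effects of class
    ``gxe_celltype`` require ``celltype_scores`` (samples x cell types) and a
    context naming the cell type.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if individual_random_sd < 0:
        raise ValueError("individual_random_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    sample_ids = samples.index
    n = len(sample_ids)
    if genes_meta is None:
        genes_meta, _ = genome_layout(n_genes, 0, seed=seed)
    genes_meta = genes_meta.iloc[:n_genes]

    if planted is None:
        truth = pd.DataFrame(columns=["gene_id", "variant_id", "effect_class",
                                      "effect_size", "context"])
    elif isinstance(planted, pd.DataFrame):
        truth = planted.copy()
    else:
        truth = pd.DataFrame(planted)
    if len(truth):
        _validate_truth(truth, genes_meta, genotypes.variants)

    baseline = rng.normal(5.0, 2.0, size=n_genes)
    expr = np.tile(baseline[:, None], (1, n))

    # Latent confounder components: rank-one gene-loading x sample-score
    # terms.  The location and inflammation components use sparse loadings
    # (a strong response in a minority of genes, as in real tissue), and
    # genes carrying planted inflammation-context effects are kept free of
    # the inflammation component so the truth table's effect sizes are exact.
    k = n_confounder_components
    sds = list(confounder_sds) + [0.2] * max(0, k - len(confounder_sds))
    density = 0.15
    scores = np.zeros((k, n))
    if k >= 1:
        loc = (samples["location"] == "ileum").to_numpy(float)
        scores[0] = (loc - loc.mean()) / max(loc.std(), 1e-9) + rng.normal(0, 0.35, n)
    if k >= 2:
        inf = samples["inflamed"].to_numpy(float)
        scores[1] = (inf - inf.mean()) / max(inf.std(), 1e-9) + rng.normal(0, 0.35, n)
    for j in range(2, k):
        scores[j] = rng.standard_normal(n)
    protected = set()
    if len(truth):
        protected = set(truth.loc[truth["context"] == "inflamed", "gene_id"])
    protected_idx = [i for i, gid in enumerate(genes_meta.index) if gid in protected]
    for j in range(k):
        if j < 2:
            loadings = np.zeros(n_genes)
            n_strong = max(2, int(round(density * n_genes)))
            strong = rng.choice(n_genes, size=min(n_strong, n_genes), replace=False)
            loadings[strong] = rng.normal(0.0, sds[j] / np.sqrt(density), size=strong.size)
            if j == 1:
                loadings[protected_idx] = 0.0
        else:
            loadings = rng.normal(0.0, sds[j], size=n_genes)
        expr += loadings[:, None] * scores[j][None, :]

    # per-individual random intercept, independent across genes
    ind_codes, ind_idx = pd.factorize(samples["individual_id"])
    a = rng.normal(0.0, individual_random_sd, size=(n_genes, len(ind_idx)))
    expr += a[:, ind_codes]

    gene_pos = {g: i for i, g in enumerate(genes_meta.index)}
    inf_vec = samples["inflamed"].to_numpy(float)
    for _, row in truth.iterrows():
        gi = gene_pos[row["gene_id"]]
        beta = float(row["effect_size"])
        cls = row["effect_class"]
        if cls == "de_shift":
            expr[gi] += beta * inf_vec
        elif cls == "main_eqtl":
            expr[gi] += beta * genotypes.dosage[row["variant_id"]].to_numpy(float)
        elif cls == "gxe_inflammation":
            dos = genotypes.dosage[row["variant_id"]].to_numpy(float)
            expr[gi] += beta * dos * inf_vec
        elif cls == "gxe_celltype":
            if celltype_scores is None:
                raise ValueError("gxe_celltype effects require celltype_scores")
            dos = genotypes.dosage[row["variant_id"]].to_numpy(float)
            sc = celltype_scores.loc[sample_ids, row["context"]].to_numpy(float)
            expr[gi] += beta * dos * sc
        else:
            raise ValueError(f"unknown effect class {cls!r}")

    expr += rng.normal(0.0, noise_sd, size=expr.shape)
    em = pd.DataFrame(expr, index=genes_meta.index, columns=sample_ids)
    return ExpressionMatrix(values=em, genes=genes_meta, is_log=True), truth


def simulate_celltype_scores(
    samples: pd.DataFrame,
    n_celltypes: int = 28,
    inflammation_shift: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-type enrichment scores in [0, 1], shifted in inflamed samples.

    Baseline scores are Beta(2, 5); named cell types are shifted by
    ``inflammation_shift`` (defaults to the package's inflamed-mucosa
    pattern) in inflamed samples.  Values leaving [0, 1] are clipped and the
    clipping is logged.
    """
    if n_celltypes < 1:
        raise ValueError("n_celltypes must be >= 1")
    rng = np.random.default_rng(seed)
    names = CELL_TYPES[:n_celltypes] if n_celltypes <= len(CELL_TYPES) else (
        CELL_TYPES + [f"cell_type_{i}" for i in range(len(CELL_TYPES), n_celltypes)]
    )
    if inflammation_shift is None:
        inflammation_shift = {k: v for k, v in DEFAULT_INFLAMMATION_SHIFTS.items() if k in names}
    n = len(samples)
    scores = rng.beta(2.0, 5.0, size=(n, len(names)))
    inf = samples["inflamed"].to_numpy(float)
    for name, shift in inflammation_shift.items():
        if name not in names:
            raise ValueError(f"unknown cell type {name!r}")
        scores[:, names.index(name)] += shift * inf
    n_clip = int(((scores < 0) | (scores > 1)).sum())
    if n_clip:
        log.info("clipped %d cell-type scores to [0, 1]", n_clip)
    scores = np.clip(scores, 0.0, 1.0)
    return pd.DataFrame(scores, index=samples.index, columns=names)


@dataclass
class Bundle:
    """One simulated dataset: everything the pipeline reads, plus the truth."""

    samples: pd.DataFrame
    genotypes: GenotypeMatrix  # sample-level
    genotypes_individual: GenotypeMatrix
    expression: "object"  # ExpressionMatrix (log2)
    celltype_scores: pd.DataFrame
    genes: pd.DataFrame
    truth: pd.DataFrame


def simulate_dataset(
    n_individuals: int = 165,
    samples_per_individual: float | int | dict = 1.7,
    inflamed_fraction: float = 0.4,
    n_genes: int = 200,
    n_variants: int = 600,
    n_main: int = 10,
    n_gxe: int = 5,
    n_de: int = 10,
    maf_range: tuple[float, float] = (0.05, 0.5),
    noise_sd: float = 0.8,
    individual_random_sd: float = 0.8,
    seed: int = 0,
    **expr_kwargs,
) -> Bundle:
    """End-to-end simulation: cohort, genotypes, expression, scores, truth."""
    samples = simulate_cohort(n_individuals, samples_per_individual, inflamed_fraction, seed)
    genes, vmeta = genome_layout(n_genes, n_variants, seed=seed + 1)
    g_ind = simulate_genotypes(n_individuals, n_variants, maf_range, seed + 2,
                               variants_meta=vmeta)
    g_smp = expand_to_samples(g_ind, samples)
    truth_spec = plant_effects(genes, vmeta, n_main=n_main, n_gxe=n_gxe, n_de=n_de,
                               seed=seed + 3)
    scores = simulate_celltype_scores(samples, seed=seed + 4)
    expr, truth = simulate_expression(
        g_smp, samples, truth_spec, n_genes, genes_meta=genes,
        noise_sd=noise_sd, individual_random_sd=individual_random_sd,
        celltype_scores=scores, seed=seed + 5, **expr_kwargs,
    )
    return Bundle(samples=samples, genotypes=g_smp, genotypes_individual=g_ind,
                  expression=expr, celltype_scores=scores, genes=genes, truth=truth)
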