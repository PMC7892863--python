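"""Configuration, input reconciliation, and the end-to-end pipeline driver.

`run_pipeline` executes the stages in analysis order — variant QC, IBS
kinship, (optional) TMM normalization, PCA with outlier removal and PC
selection, differential expression, cis-eQTL scan, inflammation-interaction
scan with classification, permutation calibration, cell-type interaction
scan, and co-expression around the interaction eGenes — writing one
metadata-headed TSV per stage.  Reruns with the same config and seed are
bit-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iomod
from .celltype import celltype_interaction_scan, summarize_celltype_counts, validate_celltype_names
from .downstream import coexpression_scan
from .expression import (ExpressionMatrix, pca_and_outliers, select_num_pcs,
                         pc_covariate_association, tmm_log_normalize)
from .genotype import GenotypeMatrix, ibs_kinship, variant_qc
from .lmm import SpectralKinship
from .scans import (classify_top_egenes, cis_eqtl_scan, differential_expression,
                    enumerate_cis_pairs, interaction_scan, permutation_calibration)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_inputs", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    # inputs
    dosage: str = ""
    expression: str = ""
    annotation: str = ""
    variant_annotation: str = ""  # variant_id, chrom, pos (not needed with VCF)
    samples: str = ""
    scores: str = ""          # optional cell-type scores
    vcf: str = ""             # alternative to dosage TSV
    # thresholds
    call_rate_min: float = 0.99
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    cis_window: int = 500_000
    de_fdr: float = 0.001
    de_abs_beta: float = 1.5
    eqtl_fdr: float = 0.05
    interaction_fdr: float = 0.05
    outlier_sd: float = 4.0
    pseudocount: float = 0.5
    n_perm: int = 10
    n_pcs: str | int = "auto"
    max_pcs: int = 18
    coexpression_r_min: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def meta(self) -> dict:
        d = asdict(self)
        return {k: d[k] for k in ("seed", "call_rate_min", "maf_min", "hwe_p_min",
                                  "cis_window", "de_fdr", "de_abs_beta", "eqtl_fdr",
                                  "interaction_fdr", "outlier_sd", "n_pcs")}


@dataclass
class InputBundle:
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    samples: pd.DataFrame
    scores: pd.DataFrame | None
    genes: pd.DataFrame


def load_inputs(config: PipelineConfig) -> InputBundle:
    """Read and reconcile all inputs on their shared samples.

    Sample ids are intersected across genotype, expression, metadata (and
    scores when present); attrition is logged.  Chromosome names are
    normalized (leading 'chr' stripped) in both annotations.  Duplicate gene,
    variant or sample ids raise.
    """
    genes = iomod.read_annotation(config.annotation)
    genes["chrom"] = genes["chrom"].map(iomod.normalize_chrom)
    if config.vcf:
        geno = iomod.read_vcf(config.vcf)
    else:
        vmeta = (iomod.read_variant_annotation(config.variant_annotation)
                 if config.variant_annotation else None)
        geno = iomod.read_dosage(config.dosage, variants_meta=vmeta)
    if "chrom" in geno.variants:
        geno.variants["chrom"] = geno.variants["chrom"].map(iomod.normalize_chrom)
    expr = iomod.read_expression(config.expression, genes=genes)
    samples = iomod.read_samples(config.samples)
    scores = iomod.read_scores(config.scores) if config.scores else None

    shared = samples.index.intersection(expr.values.columns).intersection(geno.dosage.index)
    if scores is not None:
        shared = shared.intersection(scores.index)
    if len(shared) == 0:
        raise ValueError("no samples shared across all inputs")
    for name, total in (("samples", len(samples)), ("expression", expr.values.shape[1]),
                        ("genotypes", geno.dosage.shape[0])):
        if total != len(shared):
            log.info("dropping %d %s sample(s) absent from other inputs",
                     total - len(shared), name)
    samples = samples.loc[shared]
    expr = ExpressionMatrix(values=expr.values[shared], genes=expr.genes, is_log=expr.is_log)
    geno = GenotypeMatrix(dosage=geno.dosage.loc[shared], variants=geno.variants)
    if scores is not None:
        scores = scores.loc[shared]
        validate_celltype_names(scores)
    return InputBundle(genotypes=geno, expression=expr, samples=samples,
                       scores=scores, genes=genes)


def _stage(name, t0):
    log.info("stage %-12s done in %.1fs", name, time.time() - t0)
    return time.time()


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage and write results under ``out_dir``.

    Returns the output directory.  Any stage failure raises RuntimeError
    naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"package": "inflaqtl", **config.meta()}
    stage = "load"
    try:
        t0 = time.time()
        bundle = load_inputs(config)
        t0 = _stage(stage, t0)

        stage = "qc"
        geno, qc_report = variant_qc(bundle.genotypes, config.call_rate_min,
                                     config.maf_min, config.hwe_p_min)
        iomod.write_tsv(pd.DataFrame([qc_report]).drop(columns="thresholds"),
                        out / "qc_report.tsv", meta, index=False)
        t0 = _stage(stage, t0)

        stage = "kinship"
        K = ibs_kinship(geno)
        iomod.write_kinship(K, out / "kinship.tsv", meta)
        sk = SpectralKinship(K.to_numpy(), K.sample_ids)
        t0 = _stage(stage, t0)

        stage = "normalize"
        expr = bundle.expression
        if not expr.is_log:
            expr = tmm_log_normalize(expr, pseudocount=config.pseudocount)
            iomod.write_expression(expr, out / "expression_normalized.tsv", meta)
        t0 = _stage(stage, t0)

        stage = "pca"
        pcs, outliers = pca_and_outliers(expr, outlier_sd=config.outlier_sd)
        if outliers:
            keep = [s for s in expr.values.columns if s not in outliers]
            expr = ExpressionMatrix(values=expr.values[keep], genes=expr.genes, is_log=True)
            samples = bundle.samples.loc[keep]
            geno = GenotypeMatrix(dosage=geno.dosage.loc[keep], variants=geno.variants)
            K = ibs_kinship(geno)
            sk = SpectralKinship(K.to_numpy(), K.sample_ids)
            scores = bundle.scores.loc[keep] if bundle.scores is not None else None
        else:
            samples, scores = bundle.samples, bundle.scores
        if config.n_pcs == "auto":
            pcs.n_selected = select_num_pcs(pcs, max_pcs=config.max_pcs)
        else:
            pcs.n_selected = int(config.n_pcs)
        pcs.n_selected = max(pcs.n_selected, 2)
        scree = pd.DataFrame({"component": np.arange(1, len(pcs.variance_explained) + 1),
                              "variance_explained": pcs.variance_explained})
        iomod.write_tsv(scree, out / "pca_scree.tsv",
                        {**meta, "n_selected": pcs.n_selected,
                         "outliers": ",".join(outliers) or "none"}, index=False)
        iomod.write_tsv(pcs.scores, out / "pca_scores.tsv", meta)
        covs = samples[["inflamed"]].assign(
            ileum=(samples["location"] == "ileum").astype(int))
        iomod.write_tsv(pc_covariate_association(pcs, covs),
                        out / "pc_covariates.tsv", meta, index=False)
        t0 = _stage(stage, t0)

        stage = "de"
        for contrast in ("inflammation", "diagnosis", "location"):
            try:
                de = differential_expression(expr, samples, sk, contrast, pcs,
                                             fdr_max=config.de_fdr,
                                             abs_beta_min=config.de_abs_beta)
            except ValueError as exc:
                log.warning("skipping DE contrast %s: %s", contrast, exc)
                continue
            iomod.write_tsv(de, out / f"de_{contrast}.tsv", meta, index=False)
        t0 = _stage(stage, t0)

        stage = "eqtl"
        pairs = enumerate_cis_pairs(expr.genes, geno.variants, window=config.cis_window)
        rec, top = cis_eqtl_scan(expr, geno, sk, pcs, pairs, fdr_max=config.eqtl_fdr)
        iomod.write_tsv(rec, out / "cis_eqtl.tsv", meta, index=False)
        iomod.write_tsv(top, out / "cis_eqtl_top.tsv", meta, index=False)
        t0 = _stage(stage, t0)

        stage = "interact"
        env = samples["inflamed"].to_numpy(float)
        ires = interaction_scan(expr, geno, sk, pcs, env, pairs,
                                alpha=config.interaction_fdr)
        classified = classify_top_egenes(ires.top, alpha=config.interaction_fdr)
        iomod.write_tsv(ires.records, out / "interaction_all.tsv", meta, index=False)
        iomod.write_tsv(classified, out / "interaction_top.tsv", meta, index=False)
        t0 = _stage(stage, t0)

        stage = "calibrate"
        if config.n_perm > 0:
            rep = permutation_calibration(expr, geno, sk, pcs, env, pairs, ires,
                                          n_perm=config.n_perm, seed=config.seed)
            iomod.write_tsv(pd.DataFrame([{
                "n_real_significant": rep["n_real_significant"],
                "n_perm": rep["n_perm"],
                "mean_permuted_hits": rep["mean_permuted_hits"],
                "per_permutation_hits": ",".join(map(str, rep["per_permutation_hits"])),
                "adequate": rep["adequate"],
            }]), out / "calibration.tsv", meta, index=False)
        else:
            iomod.write_tsv(pd.DataFrame([{"skipped": True}]), out / "calibration.tsv",
                            meta, index=False)
            log.info("calibration stage skipped (n_perm=0)")
        t0 = _stage(stage, t0)

        stage = "celltype"
        if scores is not None and len(classified):
            crec = celltype_interaction_scan(expr, geno, sk, pcs, scores, classified,
                                             alpha=config.interaction_fdr)
            iomod.write_tsv(crec, out / "celltype_interactions.tsv", meta, index=False)
            iomod.write_tsv(summarize_celltype_counts(crec, alpha=config.interaction_fdr),
                            out / "celltype_counts.tsv", meta, index=False)
        t0 = _stage(stage, t0)

        stage = "coexpress"
        coex = []
        for gid in classified["gene_id"].unique():
            tab = coexpression_scan(expr, gid, pcs, r_min=config.coexpression_r_min)
            coex.append(tab[tab["coexpressed"]])
        coex = (pd.concat(coex, ignore_index=True) if coex
                else pd.DataFrame(columns=["gene_id", "target", "r", "p", "q", "coexpressed"]))
        iomod.write_tsv(coex, out / "coexpression.tsv", meta, index=False)
        _stage(stage, t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return out
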