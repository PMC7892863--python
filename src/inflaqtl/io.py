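"""Readers and writers for the pipeline's tab-separated formats.

All outputs are TSV with '#'-prefixed metadata header lines (version, seed,
thresholds) and 'NA' for missing values, so results diff cleanly and round-
trip bit-exactly.  Coordinate conventions: gene annotation is BED-like
0-based half-open; variant positions are 1-based.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genotype import GenotypeMatrix, KinshipMatrix, annotate_variants

log = logging.getLogger(__name__)

__all__ = [
    "write_tsv", "read_tsv",
    "write_dosage", "read_dosage",
    "write_expression", "read_expression",
    "write_annotation", "read_annotation",
    "write_variant_annotation", "read_variant_annotation",
    "write_samples", "read_samples",
    "write_scores", "read_scores",
    "write_kinship", "read_kinship",
    "read_vcf",
]


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None, index: bool = True) -> None:
    """Write a DataFrame as TSV with '#key=value' metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", index=index, float_format="%.10g")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col, na_values="NA")


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} ids: {dups[:10]}")


def write_dosage(g: GenotypeMatrix, path, meta=None) -> None:
    """Dosage TSV: rows = samples, header row = variant ids."""
    write_tsv(g.dosage, path, meta)


def _raw_header(path) -> list[str]:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return line.rstrip("\n").split("\t")
    return []


def read_dosage(path, variants_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    # pandas silently renames duplicated header entries, so check the raw line
    _check_unique(_raw_header(path)[1:], "variant")
    dosage = read_tsv(path)
    _check_unique(dosage.index, "sample")
    meta = annotate_variants(dosage, variants_meta)
    return GenotypeMatrix(dosage=dosage, variants=meta)


def write_expression(e: ExpressionMatrix, path, meta=None) -> None:
    meta = dict(meta or {})
    meta["normalized"] = "log2" if e.is_log else "raw_counts"
    write_tsv(e.values, path, meta)


def read_expression(path, genes: pd.DataFrame | None = None) -> ExpressionMatrix:
    is_log = False
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.strip() == "#normalized=log2":
                is_log = True
    values = read_tsv(path)
    _check_unique(values.index, "gene")
    if genes is not None:
        shared = values.index.intersection(genes.index)
        values = values.loc[shared]
        genes = genes.loc[shared]
    return ExpressionMatrix(values=values, genes=genes, is_log=is_log)


def write_variant_annotation(variants: pd.DataFrame, path, meta=None) -> None:
    """Variant metadata TSV: variant_id, chrom, pos (1-based), ref, alt."""
    cols = [c for c in ("chrom", "pos", "ref", "alt") if c in variants.columns]
    out = variants.reset_index()[[variants.index.name or "index", *cols]]
    out.columns = ["variant_id", *cols]
    write_tsv(out, path, meta, index=False)


def read_variant_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values="NA", dtype={"chrom": str})
    _check_unique(df["variant_id"], "variant")
    return df.set_index("variant_id")


def write_annotation(genes: pd.DataFrame, path, meta=None) -> None:
    """BED-like gene annotation: chrom, start, end, gene_id (0-based half-open)."""
    out = genes.reset_index()[["chrom", "start", "end", genes.index.name or "index"]]
    out.columns = ["chrom", "start", "end", "gene_id"]
    write_tsv(out, path, meta, index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values="NA",
                     dtype={"chrom": str})
    _check_unique(df["gene_id"], "gene")
    return df.set_index("gene_id")[["chrom", "start", "end"]]


def write_samples(samples: pd.DataFrame, path, meta=None) -> None:
    write_tsv(samples, path, meta)


def read_samples(path) -> pd.DataFrame:
    df = read_tsv(path)
    _check_unique(df.index, "sample")
    return df


def write_scores(scores: pd.DataFrame, path, meta=None) -> None:
    write_tsv(scores, path, meta)


def read_scores(path) -> pd.DataFrame:
    df = read_tsv(path)
    bad = [(c, float(df[c].min()), float(df[c].max())) for c in df.columns
           if df[c].min() < 0 or df[c].max() > 1]
    if bad:
        raise ValueError(f"cell-type scores outside [0, 1]: {bad[:3]}")
    return df


def write_kinship(k: KinshipMatrix, path, meta=None) -> None:
    write_tsv(k.values, path, meta)


def read_kinship(path) -> KinshipMatrix:
    return KinshipMatrix(values=read_tsv(path))


def normalize_chrom(c: str) -> str:
    """Strip any 'chr' prefix so chromosome naming matches across inputs."""
    s = str(c)
    return s[3:] if s.lower().startswith("chr") else s


def read_vcf(path, max_variants: int | None = None) -> GenotypeMatrix:
    """Read GT fields of a VCF into a dosage matrix (alt-allele counts).

    Multiallelic records are skipped with a warning.  Requires cyvcf2.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, rows, meta = [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        gts = var.gt_types.astype(float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dos = np.where(gts == 3, 2.0, gts)
        dos[var.gt_types == 2] = np.nan
        cols.append(vid)
        rows.append(dos)
        meta.append({"variant_id": vid, "chrom": normalize_chrom(var.CHROM),
                     "pos": var.POS, "ref": var.REF, "alt": var.ALT[0]})
        if max_variants and len(cols) >= max_variants:
            break
    if n_multi:
        log.warning("skipped %d multiallelic VCF record(s)", n_multi)
    dosage = pd.DataFrame(np.array(rows).T, index=samples, columns=cols)
    _check_unique(cols, "variant")
    vmeta = pd.DataFrame(meta).set_index("variant_id")
    return GenotypeMatrix(dosage=dosage, variants=annotate_variants(dosage, vmeta))
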