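"""Differential expression, cis-eQTL and interaction scans on planted data."""

import numpy as np
import pandas as pd
import pytest

from inflaqtl.genotype import ibs_kinship
from inflaqtl.lmm import SpectralKinship
from inflaqtl.scans import (classify_top_egenes, cis_eqtl_scan,
                            differential_expression, enumerate_cis_pairs,
                            interaction_scan, permutation_calibration)
from inflaqtl.simulate import (expand_to_samples, genome_layout, simulate_cohort,
                               simulate_expression, simulate_genotypes)


def _planted(seed, n_genes=24, n_variants=48, maf=0.3, n_individuals=165,
             gxe=None, main=None, de=None, noise_sd=1.0, individual_sd=1.0):
    """One cohort with explicit planted effects; returns everything a scan needs."""
    samples = simulate_cohort(n_individuals=n_individuals, seed=seed)
    genes, vmeta = genome_layout(n_genes, n_variants, seed=seed)
    g = expand_to_samples(
        simulate_genotypes(n_individuals, n_variants, maf_range=(maf, maf),
                           seed=seed, variants_meta=vmeta), samples)
    rows = []
    for gid, vid, beta in (gxe or []):
        rows.append({"gene_id": gid, "variant_id": vid,
                     "effect_class": "gxe_inflammation", "effect_size": beta,
                     "context": "inflamed"})
    for gid, vid, beta in (main or []):
        rows.append({"gene_id": gid, "variant_id": vid, "effect_class": "main_eqtl",
                     "effect_size": beta, "context": ""})
    for gid, beta in (de or []):
        rows.append({"gene_id": gid, "variant_id": "", "effect_class": "de_shift",
                     "effect_size": beta, "context": "inflamed"})
    truth = pd.DataFrame(rows, columns=["gene_id", "variant_id", "effect_class",
                                        "effect_size", "context"])
    expr, _ = simulate_expression(g, samples, truth if len(truth) else None,
                                  n_genes, genes_meta=genes, noise_sd=noise_sd,
                                  individual_random_sd=individual_sd, seed=seed + 1)
    sk = SpectralKinship(ibs_kinship(g).to_numpy())
    from inflaqtl.expression import pca_and_outliers

    pcs, _ = pca_and_outliers(expr)
    pcs.n_selected = 2
    pairs = enumerate_cis_pairs(genes, g.variants)
    return samples, genes, g, expr, sk, pcs, pairs


# ---------------------------------------------------------------- cis pairs


def test_cis_pair_center_and_boundary_conventions():
    genes = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [300]},
                         index=pd.Index(["g"], name="gene_id"))
    # center: floor((100+300)/2) = 200 in 0-based -> 201 in 1-based
    variants = pd.DataFrame({"chrom": ["1"] * 3, "pos": [500_201, 500_202, 201]},
                            index=pd.Index(["at_edge", "beyond", "at_center"],
                                           name="variant_id"))
    pairs = enumerate_cis_pairs(genes, variants, window=500_000)
    assert set(pairs["variant_id"]) == {"at_edge", "at_center"}
    assert pairs.loc[pairs.variant_id == "at_center", "distance"].iloc[0] == 0
    assert pairs.loc[pairs.variant_id == "at_edge", "distance"].iloc[0] == 500_000


def test_cis_pair_rejects_degenerate_gene():
    genes = pd.DataFrame({"chrom": ["1"], "start": [300], "end": [300]},
                         index=pd.Index(["g"], name="gene_id"))
    variants = pd.DataFrame({"chrom": ["1"], "pos": [400]},
                            index=pd.Index(["v"], name="variant_id"))
    with pytest.raises(ValueError, match="end <= start"):
        enumerate_cis_pairs(genes, variants)


def test_cis_pair_requires_same_chromosome():
    genes = pd.DataFrame({"chrom": ["2"], "start": [0], "end": [100]},
                         index=pd.Index(["g"], name="gene_id"))
    variants = pd.DataFrame({"chrom": ["1"], "pos": [50]},
                            index=pd.Index(["v"], name="variant_id"))
    assert enumerate_cis_pairs(genes, variants).empty


# ---------------------------------------------------- differential expression


def test_de_recovers_planted_shifts():
    de = [(f"G{i + 1:05d}", 2.0) for i in range(8)]
    samples, genes, g, expr, sk, pcs, pairs = _planted(21, de=de)
    rec = differential_expression(expr, samples, sk, "inflammation", pcs)
    flagged = set(rec.loc[rec.flagged, "gene_id"])
    assert len(flagged & {g for g, _ in de}) >= 7


def test_de_effect_size_gate_blocks_small_shifts():
    # shift 1.0 with little noise: strongly significant but |beta| <= 1.5
    de = [("G00001", 1.0)]
    samples, genes, g, expr, sk, pcs, pairs = _planted(
        22, de=de, noise_sd=0.25, individual_sd=0.1)
    rec = differential_expression(expr, samples, sk, "inflammation", pcs)
    row = rec[rec.gene_id == "G00001"].iloc[0]
    assert row.q < 0.001 and abs(row.beta) < 1.5 and not row.flagged


def test_de_permuted_labels_yield_no_flags():
    total = 0
    for seed in (31, 32, 33):
        samples, genes, g, expr, sk, pcs, pairs = _planted(seed, de=[("G00001", 2.0)])
        rng = np.random.default_rng(seed)
        shuffled = samples.copy()
        shuffled["inflamed"] = rng.permutation(shuffled["inflamed"].to_numpy())
        rec = differential_expression(expr, shuffled, sk, "inflammation", pcs)
        total += int(rec.flagged.sum())
    assert total == 0


def test_de_rejects_constant_contrast():
    samples, genes, g, expr, sk, pcs, pairs = _planted(23, n_genes=5, n_variants=5)
    mono = samples.copy()
    mono["inflamed"] = 1
    with pytest.raises(ValueError, match="constant"):
        differential_expression(expr, mono, sk, "inflammation", pcs)


# ------------------------------------------------------------- cis-eQTL scan


def test_cis_scan_recovers_planted_egene_with_top_variant():
    main = [("G00003", "rs000003", 0.8), ("G00010", "rs000010", 0.8)]
    samples, genes, g, expr, sk, pcs, pairs = _planted(24, main=main)
    rec, top = cis_eqtl_scan(expr, g, sk, pcs, pairs)
    top_map = dict(zip(top.gene_id, top.variant_id))
    assert top_map.get("G00003") == "rs000003"
    assert top_map.get("G00010") == "rs000010"


def test_cis_scan_null_has_no_egenes():
    samples, genes, g, expr, sk, pcs, pairs = _planted(25)
    rec, top = cis_eqtl_scan(expr, g, sk, pcs, pairs)
    assert len(top) == 0


def test_cis_scan_skips_monomorphic_and_breaks_ties_by_distance():
    main = [("G00001", "rs000001", 0.9)]
    samples, genes, g, expr, sk, pcs, pairs = _planted(26, main=main)
    # duplicate the planted variant's dosages under a new id, farther away
    twin = g.dosage["rs000001"].copy()
    g.dosage["rs_twin"] = twin
    g.variants.loc["rs_twin"] = g.variants.loc["rs000001"]
    g.variants.loc["rs_twin", "pos"] = g.variants.loc["rs000001", "pos"] + 90_000
    # and one monomorphic variant
    g.dosage["rs_mono"] = 0.0
    g.variants.loc["rs_mono"] = g.variants.loc["rs000001"]
    pairs = enumerate_cis_pairs(genes, g.variants)
    rec, top = cis_eqtl_scan(expr, g, sk, pcs, pairs)
    assert "rs_mono" not in set(rec.variant_id)
    assert rec.attrs["n_skipped_monomorphic"] >= 1
    row = top[top.gene_id == "G00001"].iloc[0]
    near = min(
        ("rs000001", "rs_twin"),
        key=lambda v: (abs(int(g.variants.loc[v, "pos"])
                           - int((genes.loc["G00001", "start"] + genes.loc["G00001", "end"]) // 2 + 1)), v),
    )
    assert row.variant_id == near  # identical p-values resolved by distance


def test_scan_invariant_to_constant_shift_of_gene():
    samples, genes, g, expr, sk, pcs, pairs = _planted(
        27, n_genes=6, n_variants=12, main=[("G00002", "rs000002", 0.8)])
    rec1, _ = cis_eqtl_scan(expr, g, sk, pcs, pairs)
    shifted = expr.values.copy()
    shifted.loc["G00002"] += 100.0
    from inflaqtl.expression import ExpressionMatrix

    expr2 = ExpressionMatrix(values=shifted, genes=expr.genes, is_log=True)
    rec2, _ = cis_eqtl_scan(expr2, g, sk, pcs, pairs)
    r1 = rec1[rec1.gene_id == "G00002"].set_index("variant_id")
    r2 = rec2[rec2.gene_id == "G00002"].set_index("variant_id")
    np.testing.assert_allclose(r1["p"], r2.loc[r1.index, "p"], atol=1e-7)


# ------------------------------------------------------------ interaction


def test_interaction_scan_detects_planted_gxe_and_classifies():
    gxe = [("G00005", "rs000005", 2.0)]
    samples, genes, g, expr, sk, pcs, pairs = _planted(28, gxe=gxe)
    env = samples["inflamed"].to_numpy(float)
    res = interaction_scan(expr, g, sk, pcs, env, pairs)
    cls = classify_top_egenes(res.top)
    row = cls[cls.gene_id == "G00005"]
    assert len(row) == 1
    assert row.iloc[0].q_interaction < 0.05
    assert row.iloc[0].class_label == "interaction_only"
    # stage-1 / stage-2 bookkeeping: one top row per significant eGene
    sig_genes = set(res.records.loc[res.records.q_interaction < 0.05, "gene_id"])
    assert set(res.top.gene_id) == sig_genes
    assert res.top.gene_id.is_unique


def test_interaction_null_type_i_rate_nominal():
    samples, genes, g, expr, sk, pcs, pairs = _planted(
        29, main=[("G00001", "rs000001", 0.8)])
    env = samples["inflamed"].to_numpy(float)
    res = interaction_scan(expr, g, sk, pcs, env, pairs)
    # a pure main effect must not masquerade as interaction
    frac = (res.records["p_interaction"] < 0.05).mean()
    assert frac < 0.15


def test_interaction_rejects_constant_env(bundle, spectral, pcs):
    pairs = enumerate_cis_pairs(bundle.genes, bundle.genotypes.variants)
    with pytest.raises(ValueError, match="constant"):
        interaction_scan(bundle.expression, bundle.genotypes, spectral, pcs,
                         np.ones(len(bundle.samples)), pairs)


@pytest.mark.parametrize(
    "qg, qi, label",
    [
        (1.0, 0.046, "interaction_only"),           # rs12582553-IL26 pattern
        (1e-16, 0.014, "genotype_and_interaction"),  # rs6860700-C6 pattern
        (0.5, 0.2, "not_significant"),
    ],
)
def test_classification_thresholds(qg, qi, label):
    top = pd.DataFrame([{"gene_id": "g", "variant_id": "v",
                         "q_genotype": qg, "q_env": 0.5, "q_interaction": qi}])
    assert classify_top_egenes(top).iloc[0].class_label == label


def test_classification_requires_fdr_columns():
    with pytest.raises(ValueError, match="q_genotype"):
        classify_top_egenes(pd.DataFrame([{"q_interaction": 0.01}]))


# ------------------------------------------------------------- calibration


def test_permutation_calibration_adequate_on_signal():
    gxe = [("G00002", "rs000002", 1.5), ("G00007", "rs000007", 1.5)]
    samples, genes, g, expr, sk, pcs, pairs = _planted(30, gxe=gxe)
    env = samples["inflamed"].to_numpy(float)
    res = interaction_scan(expr, g, sk, pcs, env, pairs)
    assert len(res.top) >= 1
    rep = permutation_calibration(expr, g, sk, pcs, env, pairs, res, n_perm=4, seed=9)
    assert rep["adequate"] is True
    rep2 = permutation_calibration(expr, g, sk, pcs, env, pairs, res, n_perm=4, seed=9)
    assert rep["per_permutation_hits"] == rep2["per_permutation_hits"]


def test_permutation_calibration_degenerate_null():
    samples, genes, g, expr, sk, pcs, pairs = _planted(31, n_genes=8, n_variants=16)
    env = samples["inflamed"].to_numpy(float)
    res = interaction_scan(expr, g, sk, pcs, env, pairs)
    rep = permutation_calibration(expr, g, sk, pcs, env, pairs, res, n_perm=2, seed=1)
    if rep["n_real_significant"] == 0:
        assert rep["adequate"] is None
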