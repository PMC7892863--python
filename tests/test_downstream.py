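"""Colocalization, replication, heterogeneity, co-expression, cohort table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inflaqtl.downstream import (cochran_q, coexpression_scan, cohort_compare,
                                 coloc_abf, replication_rate, wakefield_log_abf)
from inflaqtl.expression import ExpressionMatrix, PCSet, pca_and_outliers


def _stats(beta, se, ids=None):
    ids = ids or [f"v{i}" for i in range(len(beta))]
    return pd.DataFrame({"beta": beta, "se": se}, index=ids)


# ------------------------------------------------------------------- coloc


def test_coloc_null_region_matches_prior_arithmetic():
    # all per-variant ABFs equal 1 -> closed form over the hypothesis priors
    s = _stats(np.zeros(100), np.full(100, 1e9))  # se >> prior sd => logABF ~ 0
    r = coloc_abf(s, s)
    expected_pp0 = 1.0 / (1 + 100e-4 + 100e-4 + 9900e-8 + 100e-5)
    assert r.pp[0] == pytest.approx(expected_pp0, abs=1e-6)
    assert r.pp.sum() == pytest.approx(1.0, abs=1e-9)


def test_coloc_shared_strong_variant_colocalizes():
    beta = np.zeros(60)
    beta[11] = 0.8  # z = 8
    s1 = _stats(beta, np.full(60, 0.1))
    s2 = _stats(beta * 0.9, np.full(60, 0.1))
    r = coloc_abf(s1, s2)
    assert r.pp4 > 0.5 and r.colocalized


def test_coloc_distinct_variants_favour_h3():
    b1 = np.zeros(60); b1[5] = 0.8
    b2 = np.zeros(60); b2[40] = 0.8
    r = coloc_abf(_stats(b1, np.full(60, 0.1)), _stats(b2, np.full(60, 0.1)))
    assert np.argmax(r.pp) == 3


def test_coloc_swap_symmetry_and_order_invariance():
    rng = np.random.default_rng(0)
    b1, b2 = rng.normal(0, 0.05, 50), rng.normal(0, 0.05, 50)
    b1[3] = 0.6
    s1, s2 = _stats(b1, np.full(50, 0.1)), _stats(b2, np.full(50, 0.1))
    r = coloc_abf(s1, s2)
    rs = coloc_abf(s2, s1)
    assert r.pp[1] == pytest.approx(rs.pp[2], abs=1e-12)
    assert r.pp[2] == pytest.approx(rs.pp[1], abs=1e-12)
    for h in (0, 3, 4):
        assert r.pp[h] == pytest.approx(rs.pp[h], abs=1e-12)
    shuffled = s1.sample(frac=1, random_state=1)
    r2 = coloc_abf(shuffled, s2)
    np.testing.assert_allclose(r.pp, r2.pp, atol=1e-12)


def test_coloc_accepts_p_maf_n_input():
    rng = np.random.default_rng(1)
    beta = np.zeros(40); beta[7] = 0.5
    se = np.full(40, 0.08)
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    s1 = _stats(beta, se)
    s2 = pd.DataFrame({"p": p, "maf": 0.3, "n": 500}, index=s1.index)
    r = coloc_abf(s1, s2)
    assert r.pp4 > 0.5


def test_coloc_input_validation():
    s1 = _stats([0.1, 0.2], [0.1, 0.1], ids=["a", "b"])
    s2 = _stats([0.1, 0.2], [0.1, 0.1], ids=["c", "d"])
    with pytest.raises(ValueError, match="shared"):
        coloc_abf(s1, s2)
    with pytest.raises(ValueError, match="positive"):
        wakefield_log_abf([0.1], [0.0])


# -------------------------------------------------------------- replication


@pytest.mark.parametrize(
    "n_overlap, n_conc, expected",
    [(1113, 1085, 97.48), (47, 39, 82.98), (10, 10, 100.0)],
)
def test_replication_percent_from_counts(n_overlap, n_conc, expected):
    internal = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n_overlap)],
        "gene_id": [f"g{i}" for i in range(n_overlap)],
        "beta": 1.0,
    })
    external = internal.copy()
    external["beta"] = np.where(np.arange(n_overlap) < n_overlap - n_conc, -1.0, 1.0)
    out = replication_rate(internal, external)
    assert out["n_overlapping"] == n_overlap
    assert out["n_concordant"] == n_conc
    assert out["percent"] == pytest.approx(expected, abs=0.005)


def test_replication_allele_harmonization():
    internal = pd.DataFrame({
        "variant_id": ["v1", "v2", "v3"], "gene_id": ["g1", "g2", "g3"],
        "beta": [1.0, 1.0, 1.0],
        "effect_allele": ["A", "A", "A"], "other_allele": ["G", "G", "G"],
    })
    external = pd.DataFrame({
        "variant_id": ["v1", "v2", "v3"], "gene_id": ["g1", "g2", "g3"],
        "beta": [-1.0, 1.0, 1.0],
        "effect_allele": ["G", "A", "C"], "other_allele": ["A", "G", "T"],
    })
    out = replication_rate(internal, external)
    # v1: swapped alleles, beta flips to +1 (concordant); v3: mismatch, dropped
    assert out["n_overlapping"] == 2
    assert out["n_concordant"] == 2
    assert out["n_dropped_allele_mismatch"] == 1


def test_replication_zero_overlap_flagged():
    a = pd.DataFrame({"variant_id": ["x"], "gene_id": ["g"], "beta": [1.0]})
    b = pd.DataFrame({"variant_id": ["y"], "gene_id": ["g"], "beta": [1.0]})
    out = replication_rate(a, b)
    assert out["n_overlapping"] == 0 and np.isnan(out["percent"])


# ------------------------------------------------------------ heterogeneity


def test_cochran_q_worked_examples():
    r = cochran_q([0.5, 0.5], [0.1, 0.1])
    assert r.Q == pytest.approx(0.0, abs=1e-12) and r.p == pytest.approx(1.0)
    r = cochran_q([0.5, -0.5], [0.1, 0.1])
    assert r.Q == pytest.approx(50.0, rel=1e-9)
    assert r.p == pytest.approx(1.54e-12, rel=0.01)
    assert r.heterogeneous and r.df == 1


def test_cochran_q_scale_invariance_and_validation():
    r1 = cochran_q([0.2, 0.5, -0.1], [0.1, 0.2, 0.15])
    r2 = cochran_q([0.6, 1.5, -0.3], [0.3, 0.6, 0.45])
    assert r1.Q == pytest.approx(r2.Q, rel=1e-9)
    with pytest.raises(ValueError):
        cochran_q([0.5], [0.1])
    with pytest.raises(ValueError):
        cochran_q([0.5, 0.5], [0.1, 0.0])


# ------------------------------------------------------------ co-expression


def test_coexpression_finds_shared_latent_factor():
    rng = np.random.default_rng(5)
    n = 280
    latent = rng.standard_normal(n)
    genes = {"target": latent + 0.7 * rng.standard_normal(n),
             "partner": latent + 0.7 * rng.standard_normal(n)}
    for j in range(40):
        genes[f"null{j}"] = rng.standard_normal(n)
    vals = pd.DataFrame(genes).T
    vals.columns = [f"s{i}" for i in range(n)]
    em = ExpressionMatrix(values=vals, genes=None, is_log=True)
    pcs, _ = pca_and_outliers(em)
    pcs.n_selected = 2  # latent factor deliberately shared; PCs come from data
    # residualize on nothing relevant: use two leading PCs of mostly-noise data
    pcs_null = PCSet(scores=pd.DataFrame(
        {"PC1": rng.standard_normal(n), "PC2": rng.standard_normal(n)},
        index=vals.columns), variance_explained=np.array([0.01, 0.01]), n_selected=2)
    out = coexpression_scan(em, "target", pcs_null)
    assert "target" not in set(out.gene_id)
    hit = out[out.gene_id == "partner"].iloc[0]
    assert hit.coexpressed and abs(hit.r) > 0.5
    assert not out[out.gene_id.str.startswith("null")].coexpressed.any()


def test_coexpression_unknown_target():
    em = ExpressionMatrix(values=pd.DataFrame(np.eye(3)), genes=None, is_log=True)
    pcs = PCSet(scores=pd.DataFrame(np.zeros((3, 1)), columns=["PC1"]),
                variance_explained=np.array([1.0]), n_selected=0)
    with pytest.raises(ValueError, match="target"):
        coexpression_scan(em, "nope", pcs)


# ------------------------------------------------------------- cohort table


def _cohort_frame(spec):
    rows = []
    for inflamed, value, count in spec:
        rows += [{"inflamed": inflamed, "v": value}] * count
    return pd.DataFrame(rows)


def test_cohort_location_table_chi2():
    df = _cohort_frame([(1, "colon", 81), (1, "ileum", 31),
                        (0, "colon", 110), (0, "ileum", 58)])
    out = cohort_compare(df, "v")
    assert out["test"] == "chi2"
    assert out["p"] == pytest.approx(0.28, abs=0.005)


def test_cohort_diagnosis_table_chi2():
    df = _cohort_frame([(1, "CD", 63), (1, "IBDU", 12), (1, "UC", 37),
                        (0, "CD", 110), (0, "IBDU", 15), (0, "UC", 43)])
    out = cohort_compare(df, "v")
    assert out["df"] == 2
    assert out["p"] == pytest.approx(0.29, abs=0.005)


def test_cohort_identical_proportions_give_p_one():
    df = _cohort_frame([(1, "F", 30), (1, "M", 20), (0, "F", 60), (0, "M", 40)])
    assert cohort_compare(df, "v")["p"] == pytest.approx(1.0)


def test_cohort_continuous_uses_rank_sum():
    rng = np.random.default_rng(6)
    df = pd.DataFrame({"inflamed": rng.integers(0, 2, 200),
                       "v": rng.normal(40, 15, 200)})
    out = cohort_compare(df, "v")
    assert out["test"] == "wilcoxon" and 0.0 <= out["p"] <= 1.0


def test_cohort_2x2_continuity_correction_matches_hand_oracle():
    rng = np.random.default_rng(7)
    for _ in range(25):
        t = rng.integers(5, 60, size=(2, 2)).astype(float)
        df = _cohort_frame([(1, "a", int(t[0, 0])), (1, "b", int(t[0, 1])),
                            (0, "a", int(t[1, 0])), (0, "b", int(t[1, 1]))])
        out = cohort_compare(df, "v")
        n = t.sum()
        row, col = t.sum(1), t.sum(0)
        exp = np.outer(row, col) / n
        chi2 = ((np.abs(t - exp) - 0.5).clip(min=0) ** 2 / exp).sum()
        assert out["statistic"] == pytest.approx(chi2, rel=1e-9)


def test_cohort_validation():
    df = pd.DataFrame({"inflamed": [1, 0], "v": ["a", "a"]})
    with pytest.raises(ValueError, match="constant"):
        cohort_compare(df, "v")
    df = pd.DataFrame({"inflamed": [1, 1], "v": ["a", "b"]})
    with pytest.raises(ValueError, match="binary"):
        cohort_compare(df, "v")
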