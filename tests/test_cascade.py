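"""Cascade contracts: harmonization, composition, variance propagation."""

import numpy as np
import pandas as pd
import pytest

from cewas import (cascade_zscores, compose_weights, compute_gene_sd,
                   cpg_zscores, exclude_mhc, harmonize_alleles,
                   map_cpg_to_gene)
from cewas.containers import CovarianceStore, CpGModel, GeneModel, HarmonizedStats

from conftest import random_toy_system


def _model_snps(rows):
    df = pd.DataFrame(rows, columns=["snp", "a1", "a2"]).set_index("snp")
    return df


# -------------------------------------------------------- harmonization

def test_harmonize_swap_flips_sign():
    model = _model_snps([("rs1", "C", "T")])
    gwas = pd.DataFrame({"snp": ["rs1"], "a1": ["T"], "a2": ["C"], "z": [2.5]})
    h = harmonize_alleles(gwas, model)
    assert h.stats.loc["rs1", "z"] == -2.5
    assert h.drops["flipped"] == 1


def test_harmonize_drops_ambiguous_even_when_matching():
    model = _model_snps([("rs1", "A", "T"), ("rs2", "G", "C")])
    gwas = pd.DataFrame({"snp": ["rs1", "rs2"], "a1": ["A", "G"],
                         "a2": ["T", "C"], "z": [1.0, 2.0]})
    h = harmonize_alleles(gwas, model)
    assert len(h.stats) == 0
    assert h.drops["ambiguous"] == 2


def test_harmonize_keeps_matches_drops_mismatches():
    model = _model_snps([("rs1", "A", "G"), ("rs2", "C", "T"), ("rs3", "A", "C")])
    gwas = pd.DataFrame({"snp": ["rs1", "rs2", "rs3", "rs4"],
                         "a1": ["A", "G", "A", "A"],
                         "a2": ["G", "A", "C", "C"],
                         "z": [1.0, 2.0, 3.0, 9.0]})
    h = harmonize_alleles(gwas, model)
    assert h.stats.loc["rs1", "z"] == 1.0      # identical coding kept as-is
    assert h.stats.loc["rs3", "z"] == 3.0
    assert "rs2" not in h.stats.index          # G/A does not match C/T
    assert h.drops["mismatched"] == 1


def test_harmonize_rejects_duplicate_gwas_ids():
    model = _model_snps([("rs1", "A", "G")])
    gwas = pd.DataFrame({"snp": ["rs1", "rs1"], "a1": ["A", "A"],
                         "a2": ["G", "G"], "z": [1.0, 1.0]})
    with pytest.raises(ValueError):
        harmonize_alleles(gwas, model)


# ----------------------------------------------------------- composition

def test_compose_weights_single_path_and_cancellation():
    cm = {"c0": CpGModel("c0", "1", 1, ["s0"], np.array([3.0])),
          "c1": CpGModel("c1", "1", 2, ["s0"], np.array([0.5])),
          "c2": CpGModel("c2", "1", 3, ["s0"], np.array([0.5]))}
    g_single = GeneModel("g", "1", 1, ["c0"], np.array([2.0]))
    assert compose_weights(cm, g_single)["s0"] == 6.0
    g_cancel = GeneModel("g", "1", 1, ["c1", "c2"], np.array([1.0, -1.0]))
    assert compose_weights(cm, g_cancel)["s0"] == 0.0


def test_compose_weights_matches_dense_product():
    rng = np.random.default_rng(1)
    _, cpg_models, gene_models, _, W_c, W_g = random_toy_system(rng, 3, 2, 1)
    cm = {m.cpg_id: m for m in cpg_models}
    w = compose_weights(cm, gene_models[0])
    dense = W_g[0] @ W_c
    for k, s in enumerate(f"s{i}" for i in range(3)):
        assert w.get(s, 0.0) == pytest.approx(dense[k], abs=1e-12)


def test_gene_sd_known_cases_and_oracle():
    g1 = GeneModel("g", "1", 1, ["c0"], np.array([1.0]))
    cov1 = pd.DataFrame([[4.0]], index=["c0"], columns=["c0"])
    assert compute_gene_sd(g1, cov1) == 2.0

    g2 = GeneModel("g", "1", 1, ["c0", "c1"], np.array([1.0, 1.0]))
    cov2 = pd.DataFrame(np.ones((2, 2)), index=["c0", "c1"], columns=["c0", "c1"])
    assert compute_gene_sd(g2, cov2) == 2.0

    rng = np.random.default_rng(2)
    A = rng.standard_normal((6, 4))
    cov = pd.DataFrame(A.T @ A, index=list("abcd"), columns=list("abcd"))
    w = rng.standard_normal(4)
    g3 = GeneModel("g", "1", 1, list("abcd"), w)
    assert compute_gene_sd(g3, cov) == pytest.approx(
        np.sqrt(w @ cov.to_numpy() @ w), abs=1e-12)


# --------------------------------------------------------- cascade core

def _harmonized(z: dict) -> HarmonizedStats:
    df = pd.DataFrame({"z": pd.Series(z, dtype=float)})
    df.index.name = "snp"
    return HarmonizedStats(df)


def test_cascade_single_path_passthrough():
    cm = [CpGModel("c0", "1", 1, ["s0"], np.array([1.0]), sd_pred=1.0)]
    gm = [GeneModel("g0", "1", 1, ["c0"], np.array([1.0]))]
    cov = CovarianceStore(snp_sd=pd.Series({"s0": 1.0}),
                          cpg_cov=pd.DataFrame([[1.0]], index=["c0"], columns=["c0"]))
    table, _ = cascade_zscores(_harmonized({"s0": 1.7}), cm, gm, cov)
    assert table.loc[0, "zscore"] == pytest.approx(1.7, abs=1e-12)


def test_cascade_equals_dense_composite_formula():
    """Sequential cascading equals the single-stage composite-weight
    statistic computed by an independent dense implementation."""
    for trial in range(10):
        rng = np.random.default_rng(100 + trial)
        panel, cpg_models, gene_models, cov, W_c, W_g = random_toy_system(rng)
        snps = list(panel.frame.columns)
        z = pd.Series(rng.standard_normal(len(snps)), index=snps)
        table, _ = cascade_zscores(_harmonized(z.to_dict()), cpg_models,
                                   gene_models, cov)
        sigma_k = panel.frame.std(axis=0, ddof=1).to_numpy()
        centered = panel.frame.to_numpy() - panel.frame.to_numpy().mean(axis=0)
        mp = centered @ W_c.T
        cov_mp = np.cov(mp, rowvar=False)
        comp = W_g @ W_c
        for i, gm in enumerate(gene_models):
            sigma_g = np.sqrt(W_g[i] @ cov_mp @ W_g[i])
            expected = comp[i] @ (sigma_k * z.to_numpy()) / sigma_g
            got = table.set_index("gene").loc[gm.gene_id, "zscore"]
            assert got == pytest.approx(expected, abs=1e-10)


def test_cascade_sign_equivariance_and_flip_invariance(small_system):
    sys = small_system
    ds = sys.dataset
    cov = CovarianceStore(snp_sd=ds.dosage.sd(), cpg_cov=sys.m_pred.cov())
    rng = np.random.default_rng(3)
    ann = ds.truth.snp_annotation
    gwas = pd.DataFrame({"snp": ann.index, "a1": ann["a1"].to_numpy(),
                         "a2": ann["a2"].to_numpy(),
                         "z": rng.standard_normal(len(ann))})
    h = harmonize_alleles(gwas, ann)
    base, _ = cascade_zscores(h, sys.cpg_models, sys.retained, cov)

    neg = gwas.assign(z=-gwas["z"])
    table_neg, _ = cascade_zscores(harmonize_alleles(neg, ann),
                                   sys.cpg_models, sys.retained, cov)
    assert np.allclose(table_neg["zscore"], -base["zscore"])

    flipped = gwas.assign(a1=gwas["a2"], a2=gwas["a1"], z=-gwas["z"])
    table_flip, _ = cascade_zscores(harmonize_alleles(flipped, ann),
                                    sys.cpg_models, sys.retained, cov)
    assert np.allclose(table_flip["zscore"], base["zscore"])


def test_cascade_missing_snps_counted_and_untestable_logged():
    cm = [CpGModel("c0", "1", 1, ["s0", "s1"], np.array([1.0, 1.0]), sd_pred=1.0),
          CpGModel("c1", "1", 2, ["s2"], np.array([1.0]), sd_pred=1.0)]
    gm = [GeneModel("g0", "1", 1, ["c0"], np.array([1.0])),
          GeneModel("g1", "1", 1, ["c1"], np.array([1.0]))]
    idx = ["c0", "c1"]
    cov = CovarianceStore(snp_sd=pd.Series({"s0": 1.0, "s1": 1.0, "s2": 1.0}),
                          cpg_cov=pd.DataFrame(np.eye(2), index=idx, columns=idx))
    table, log = cascade_zscores(_harmonized({"s0": 2.0}), cm, gm, cov)
    assert log["n_snps_missing"]["g0"] == 1
    assert table.set_index("gene").loc["g0", "zscore"] == pytest.approx(2.0)
    assert [g for g, _ in log["untestable"]] == ["g1"]  # no overlapping SNPs


def test_cpg_zscores_passthrough_and_oracle():
    rng = np.random.default_rng(4)
    snps = ["s0", "s1", "s2"]
    A = rng.standard_normal((9, 3))
    snp_cov = pd.DataFrame(A.T @ A / 8, index=snps, columns=snps)
    w = np.array([0.5, -1.0, 2.0])
    cm = [CpGModel("c0", "1", 1, snps, w)]
    z = {s: v for s, v in zip(snps, rng.standard_normal(3))}
    out = cpg_zscores(_harmonized(z), cm, snp_cov)
    sd = np.sqrt(np.diag(snp_cov))
    zv = np.array([z[s] for s in snps])
    oracle = (w * sd) @ zv / np.sqrt(w @ snp_cov.to_numpy() @ w)
    assert out.loc[0, "zscore"] == pytest.approx(oracle, abs=1e-12)

    unit = pd.DataFrame([[1.0]], index=["s0"], columns=["s0"])
    single = cpg_zscores(_harmonized({"s0": 1.3}),
                         [CpGModel("c0", "1", 1, ["s0"], np.array([1.0]))], unit)
    assert single.loc[0, "zscore"] == pytest.approx(1.3, abs=1e-12)


# ------------------------------------------------------- CpG-gene maps

def test_map_cpg_to_gene_modes_and_oracle():
    tbl = pd.DataFrame({"pos": [990, 1500], "pvalue": [0.5, 0.001],
                        "cv_r2": [0.02, 0.9]},
                       index=pd.Index(["near", "far"], name="cpg"))
    genes = pd.DataFrame({"tss": [1000]}, index=pd.Index(["g"], name="gene"))
    closest = map_cpg_to_gene(tbl, genes, mode="closest", window=10_000)
    maxr2 = map_cpg_to_gene(tbl, genes, mode="max_r2", window=10_000)
    assert closest.loc[0, "cpg"] == "near" and maxr2.loc[0, "cpg"] == "far"

    rng = np.random.default_rng(5)
    pos = rng.integers(0, 100_000, 40)
    tbl2 = pd.DataFrame({"pos": pos, "pvalue": rng.uniform(size=40),
                         "cv_r2": rng.uniform(size=40)},
                        index=pd.Index([f"c{i}" for i in range(40)], name="cpg"))
    genes2 = pd.DataFrame({"tss": rng.integers(0, 100_000, 10)},
                          index=pd.Index([f"g{i}" for i in range(10)], name="gene"))
    got = map_cpg_to_gene(tbl2, genes2, mode="closest", window=20_000)
    for row in got.itertuples(index=False):
        tss = genes2.loc[row.gene, "tss"]
        dists = (tbl2["pos"] - tss).abs()
        eligible = dists[dists <= 20_000]
        best = eligible.min()
        # exhaustive search; ties broken by smaller coordinate
        cands = tbl2.loc[eligible[eligible == best].index]
        expect = cands.sort_values("pos").index[0]
        assert row.cpg == expect


def test_map_single_cpg_agrees_across_modes():
    tbl = pd.DataFrame({"pos": [500], "pvalue": [0.2], "cv_r2": [0.5]},
                       index=pd.Index(["c"], name="cpg"))
    genes = pd.DataFrame({"tss": [600]}, index=pd.Index(["g"], name="gene"))
    for mode in ("closest", "max_r2"):
        out = map_cpg_to_gene(tbl, genes, mode=mode, window=1_000)
        assert out.loc[0, "pvalue"] == 0.2


# ------------------------------------------------------- MHC exclusion

def test_exclude_mhc_boundaries():
    mk = lambda tss: GeneModel(f"g{tss}", "6", tss, ["c"], np.array([1.0]))
    region = ("6", 1_000_000, 2_000_000)
    inside = mk(1_500_000)
    boundary_out = mk(2_500_001)   # window reaches 2,000,001 > end? no: 2,000,001
    just_touching = mk(2_500_000)  # window [2,000,000, 3,000,000] touches end
    other_chrom = GeneModel("gx", "7", 1_500_000, ["c"], np.array([1.0]))
    kept = exclude_mhc([inside, boundary_out, just_touching, other_chrom],
                       region, window=500_000)
    names = [g.gene_id for g in kept]
    assert inside.gene_id not in names
    assert just_touching.gene_id not in names
    assert boundary_out.gene_id in names
    assert "gx" in names
    assert len(exclude_mhc([inside], None)) == 1
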