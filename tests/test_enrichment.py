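"""Enrichment contracts: OAS shrinkage, GLS, set tests, region t-values."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cewas import (brain_region_association, count_selected_snps,
                   enrich_gene_sets, gls_fit, oas_shrinkage, region_tvalues)
from cewas.containers import CpGModel, GeneModel
from cewas._utils import rng_for


def _oas_transcription(X):
    """Independent loop-style transcription of the shrinkage closed form."""
    X = np.asarray(X, dtype=float)
    n, q = X.shape
    Xc = X - X.mean(axis=0)
    S = np.zeros((q, q))
    for i in range(n):
        S += np.outer(Xc[i], Xc[i])
    S /= n
    tr_s = sum(S[j, j] for j in range(q))
    tr_s2 = sum(S[a, b] * S[b, a] for a in range(q) for b in range(q))
    num = (1 - 2.0 / q) * tr_s2 + tr_s**2
    den = (n + 1 - 2.0 / q) * (tr_s2 - tr_s**2 / q)
    rho = min(1.0, num / den)
    return (1 - rho) * S + rho * (tr_s / q) * np.eye(q), rho


def test_oas_identity_fixed_point():
    rng = np.random.default_rng(0)
    Q, _ = np.linalg.qr(rng.standard_normal((40, 4)))
    X = Q * np.sqrt(40)  # exactly identity 1/n covariance after centering? no:
    X = X - X.mean(axis=0)
    # force exact identity sample covariance via whitening
    S = X.T @ X / 40
    X = X @ np.linalg.inv(np.linalg.cholesky(S)).T
    sigma, rho = oas_shrinkage(X, standardize=False)
    assert np.allclose(sigma, np.eye(4), atol=1e-10)


def test_oas_matches_independent_transcription():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((10, 3)) @ rng.standard_normal((3, 3))
    sigma, rho = oas_shrinkage(X, standardize=False)
    sig_ref, rho_ref = _oas_transcription(X)
    assert rho == pytest.approx(rho_ref, abs=1e-12)
    assert np.allclose(sigma, sig_ref, atol=1e-12)


def test_oas_shrinkage_vanishes_with_n():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((100_000, 5)) @ rng.standard_normal((5, 5))
    sigma, rho = oas_shrinkage(X, standardize=False)
    assert rho < 0.01
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / len(X)
    assert np.allclose(sigma, S, rtol=0.02, atol=0.01)


def test_oas_improves_conditioning_when_q_exceeds_n():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((15, 40))
    sigma, rho = oas_shrinkage(X, standardize=True)
    w = np.linalg.eigvalsh(sigma)
    assert w.min() > 0  # positive definite despite singular sample covariance
    assert 0 < rho <= 1


def test_oas_rejects_constant_column():
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.raises(ValueError):
        oas_shrinkage(X, standardize=True)


# ------------------------------------------------------------- confound

def test_count_selected_snps_pair_rule():
    cm = {"c0": CpGModel("c0", "1", 1, ["s0", "s1", "s2"], np.array([1.0, 2.0, 3.0])),
          "c1": CpGModel("c1", "1", 2, ["s0"], np.array([1.0])),
          "c2": CpGModel("c2", "1", 3, ["s0"], np.array([-1.0]))}
    g3 = GeneModel("g", "1", 1, ["c0"], np.array([2.0]))
    assert count_selected_snps(cm, g3) == 3
    g_shared = GeneModel("g", "1", 1, ["c1", "c2"], np.array([1.0, 1.0]))
    assert count_selected_snps(cm, g_shared) == 2     # pairs, not SNPs
    assert count_selected_snps(cm, g_shared, strict_positive=True) == 1
    g_zero = GeneModel("g", "1", 1, ["c0", "c1"], np.array([0.0, 1.0]))
    assert count_selected_snps(cm, g_zero) == 1


# ------------------------------------------------------------------ GLS

def test_gls_identity_sigma_two_group_means():
    rng = np.random.default_rng(4)
    z = rng.standard_normal(30)
    x = np.zeros(30)
    x[:12] = 1.0
    fit = gls_fit(z, np.ones((30, 1)), x, np.eye(30))
    assert fit.beta[-1] == pytest.approx(z[:12].mean() - z[12:].mean(), abs=1e-10)


def test_gls_matches_statsmodels_and_normal_equations():
    rng = np.random.default_rng(5)
    q = 20
    A = rng.standard_normal((q, q))
    sigma = A @ A.T + q * np.eye(q)
    C = np.column_stack([np.ones(q), rng.standard_normal(q)])
    x = rng.standard_normal(q)
    z = rng.standard_normal(q)
    fit = gls_fit(z, C, x, sigma)

    X = np.column_stack([C, x])
    si = np.linalg.inv(sigma)
    beta_ref = np.linalg.inv(X.T @ si @ X) @ X.T @ si @ z
    assert np.allclose(fit.beta, beta_ref, atol=1e-10)

    sm_fit = sm.GLS(z, X, sigma=sigma).fit()
    assert np.allclose(fit.beta, sm_fit.params, atol=1e-10)
    assert fit.se[-1] == pytest.approx(sm_fit.bse[-1], abs=1e-10)
    assert fit.p_two_sided == pytest.approx(sm_fit.pvalues[-1], abs=1e-10)


def test_gls_rejects_collinear_covariate():
    q = 12
    z = np.arange(q, dtype=float)
    with pytest.raises(ValueError, match="rank deficient"):
        gls_fit(z, np.ones((q, 1)), np.ones(q), np.eye(q))


# ----------------------------------------------------------- gene sets

def _planted_universe(rng, q=400, set_size=40, shift=0.8):
    genes = [f"g{i:04d}" for i in range(q)]
    z = pd.Series(rng.standard_normal(q), index=genes)
    planted = rng.choice(genes, size=set_size, replace=False)
    z.loc[planted] += shift
    sets = {"planted": set(planted)}
    for i in range(19):
        sets[f"null{i:02d}"] = set(rng.choice(genes, size=set_size, replace=False))
    sigma = pd.DataFrame(np.eye(q), index=genes, columns=genes)
    return z, sets, sigma


def test_planted_set_recovered():
    hits = 0
    for rep in range(10):
        rng = rng_for(rep, "planted")
        z, sets, sigma = _planted_universe(rng)
        res = enrich_gene_sets(z, sets, sigma).set_index("set")
        if res["p"].idxmin() == "planted" and res.loc["planted", "fdr_q"] < 0.05:
            hits += 1
    assert hits >= 9


def test_size_filter_and_fdr_monotone():
    rng = rng_for(0, "sizes")
    genes = [f"g{i}" for i in range(100)]
    z = pd.Series(rng.standard_normal(100), index=genes)
    sigma = pd.DataFrame(np.eye(100), index=genes, columns=genes)
    sets = {"tiny": set(genes[:9]), "ok": set(genes[:30]),
            "big": set(genes)}  # 100 > max_size
    res = enrich_gene_sets(z, sets, sigma, min_size=10, max_size=50)
    assert list(res["set"]) == ["ok"]

    many = {f"s{i}": set(rng.choice(genes, 20, replace=False)) for i in range(30)}
    res2 = enrich_gene_sets(z, many, sigma).sort_values("p")
    assert res2["fdr_q"].is_monotonic_increasing
    assert (res2["fdr_q"] >= res2["p"] - 1e-12).all()


def test_enrichment_invariant_to_orderings():
    rng = rng_for(1, "order")
    z, sets, sigma = _planted_universe(rng, q=120, set_size=15)
    base = enrich_gene_sets(z, sets, sigma).set_index("set")["p"]
    perm = rng.permutation(len(z))
    z2 = z.iloc[perm]
    sigma2 = sigma.iloc[perm, perm]
    shuffled_sets = dict(reversed(list(sets.items())))
    again = enrich_gene_sets(z2, shuffled_sets, sigma2).set_index("set")["p"]
    for name in base.index:
        assert again[name] == pytest.approx(base[name], abs=1e-10)


# ------------------------------------------------------------- regions

def _long_expression(values: dict, subjects, genes, regions):
    rows = []
    for s in subjects:
        for g in genes:
            for r in regions:
                rows.append({"subject": s, "gene": g, "region": r,
                             "value": values[(s, g, r)]})
    return pd.DataFrame(rows)


def test_region_tvalues_uniform_gene_is_zero():
    subjects, genes, regions = ["a", "b", "c"], ["g1"], ["r1", "r2", "r3"]
    vals = {(s, g, r): 5.0 for s in subjects for g in genes for r in regions}
    t = region_tvalues(_long_expression(vals, subjects, genes, regions))
    assert np.allclose(t.to_numpy(), 0.0)


def test_region_tvalues_elevated_region_capped_then_finite_with_noise():
    subjects, genes, regions = ["a", "b", "c", "d"], ["g1"], ["r1", "r2"]
    vals = {(s, "g1", r): (1.0 if r == "r2" else 0.0) for s in subjects
            for r in regions}
    t = region_tvalues(_long_expression(vals, subjects, genes, regions))
    assert t.loc["g1", "r2"] == pytest.approx(1e6)
    assert t.loc["g1", "r1"] == pytest.approx(-1e6)

    rng = rng_for(2, "regions")
    noisy = {k: v + 0.05 * rng.standard_normal() for k, v in vals.items()}
    tn = region_tvalues(_long_expression(noisy, subjects, genes, regions))
    assert 2 < tn.loc["g1", "r2"] < 1e6


def test_region_tvalues_match_hand_formula():
    subjects, regions = ["a", "b", "c", "d", "e"], ["r1", "r2", "r3"]
    rng = rng_for(3, "thand")
    vals = {(s, "g1", r): float(rng.standard_normal())
            for s in subjects for r in regions}
    t = region_tvalues(_long_expression(vals, subjects, ["g1"], regions))
    centered = {}
    for s in subjects:
        mu = np.mean([vals[(s, "g1", r)] for r in regions])
        for r in regions:
            centered[(s, r)] = vals[(s, "g1", r)] - mu
    for r in regions:
        v = np.array([centered[(s, r)] for s in subjects])
        expect = v.mean() / (v.std(ddof=1) / np.sqrt(len(v)))
        assert t.loc["g1", r] == pytest.approx(expect, abs=1e-10)


def test_region_tvalues_averages_duplicates_and_requires_two_subjects():
    df = pd.DataFrame({
        "subject": ["a", "a", "a", "b", "b"],
        "gene": ["g1"] * 5,
        "region": ["r1", "r1", "r2", "r1", "r2"],
        "value": [1.0, 3.0, 0.0, 2.0, 0.0],
    })
    t = region_tvalues(df)
    # subject a: r1 averaged to 2.0; both subjects centered then t over 2
    assert np.isfinite(t.loc["g1", "r1"])

    single = df[df.subject == "a"]
    t1 = region_tvalues(single)
    assert t1.isna().all().all()


def test_brain_region_association_identical_columns_and_planted():
    rng = rng_for(4, "region-assoc")
    q = 300
    genes = [f"g{i}" for i in range(q)]
    t_common = rng.standard_normal(q)
    tmat = pd.DataFrame({"r1": t_common, "r2": t_common}, index=genes)
    z = pd.Series(rng.standard_normal(q), index=genes)
    sigma = pd.DataFrame(np.eye(q), index=genes, columns=genes)
    res = brain_region_association(z, tmat, sigma).set_index("region")
    assert res.loc["r1", "beta"] == pytest.approx(res.loc["r2", "beta"], abs=1e-12)

    t_assoc = rng.standard_normal(q)
    z2 = pd.Series(0.5 * t_assoc + np.sqrt(1 - 0.25) * rng.standard_normal(q),
                   index=genes)
    tmat2 = pd.DataFrame({"signal": t_assoc,
                          "noise1": rng.standard_normal(q),
                          "noise2": rng.standard_normal(q)}, index=genes)
    res2 = brain_region_association(z2, tmat2, sigma).set_index("region")
    assert res2["p"].idxmin() == "signal"
    assert res2.loc["signal", "fdr_q"] < 0.05
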