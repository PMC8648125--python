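"""Apply trained two-stage models to GWAS summary statistics.

The gene-level statistic propagates SNP z-scores through the stage-1
SNP->CpG weights and the stage-2 CpG->gene weights:

    z_g = sum_j w_gj * sd_j * z_cj / sigma_g,
    z_cj = sum_k w_jk * sigma_k * z_k / sd^pred_j,

where sigma_k is the reference-panel dosage SD of SNP k, sd^pred_j the
SD of CpG j's predicted methylation, sd_j the SD of CpG j under the
chosen CpG covariance source, and sigma_g = sqrt(w_g' Cov w_g) under the
same source. With the predicted-methylation covariance (the calibrated
choice) the per-CpG scales cancel and the statistic collapses to the
single composite-weight formula

    z_g = sum_k (sum_j w_gj w_jk) sigma_k z_k / sigma_g.

Using measured-methylation covariance instead rescales CpG terms by the
measured SDs and changes the denominator, reproducing the mis-calibrated
variant that motivates estimating the covariance from predicted levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CovarianceStore, CpGModel, GeneModel, HarmonizedStats

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def harmonize_alleles(gwas: pd.DataFrame,
                      model_snps: pd.DataFrame) -> HarmonizedStats:
    """Align GWAS z-scores to the model's allele coding.

    ``gwas`` needs columns snp, a1 (effect), a2, z; ``model_snps`` is
    indexed by SNP id with columns a1 (effect), a2. Matching alleles are
    kept as-is, swapped alleles have their z negated, strand-ambiguous
    SNPs (complementary allele pairs) are dropped regardless of match,
    and any other mismatch is dropped. Counts per category are logged in
    the result.
    """
    if gwas["snp"].duplicated().any():
        dups = gwas.loc[gwas["snp"].duplicated(), "snp"].head(5).tolist()
        raise ValueError(f"duplicate SNP ids in GWAS input: {dups}")
    if not model_snps.index.is_unique:
        raise ValueError("model SNP table has duplicate ids")

    g = gwas.set_index("snp")
    present = g.index.intersection(model_snps.index)
    drops = {"absent": int(len(model_snps.index.difference(g.index)))}

    g = g.loc[present]
    m = model_snps.loc[present]
    ga1, ga2 = g["a1"].str.upper(), g["a2"].str.upper()
    ma1, ma2 = m["a1"].str.upper(), m["a2"].str.upper()

    ambiguous = ga1.map(COMPLEMENT) == ga2
    same = (ga1 == ma1) & (ga2 == ma2)
    swapped = (ga1 == ma2) & (ga2 == ma1)

    keep_same = same & ~ambiguous
    keep_swap = swapped & ~ambiguous & ~same
    mismatch = ~same & ~swapped & ~ambiguous

    z = g["z"].astype(float).copy()
    z[keep_swap] = -z[keep_swap]
    kept = keep_same | keep_swap

    drops["ambiguous"] = int(ambiguous.sum())
    drops["mismatched"] = int(mismatch.sum())
    drops["kept"] = int(kept.sum())
    drops["flipped"] = int(keep_swap.sum())

    stats_df = pd.DataFrame({"z": z[kept]})
    stats_df.index.name = "snp"
    return HarmonizedStats(stats_df, drops)


def compose_weights(cpg_models: dict[str, CpGModel],
                    gene_model: GeneModel,
                    cpg_scale: pd.Series | None = None) -> pd.Series:
    """Per-SNP composite weights w_k = sum_j w_gj * scale_j * w_jk.

    ``cpg_scale`` (default 1) carries the per-CpG rescaling used when a
    non-predicted CpG covariance source is requested.
    """
    acc: dict[str, float] = {}
    cpgs, wg = gene_model.nonzero()
    for cpg, w_g in zip(cpgs, wg):
        model = cpg_models[cpg]
        scale = 1.0 if cpg_scale is None else float(cpg_scale[cpg])
        snps, wc = model.nonzero()
        for snp, w_c in zip(snps, wc):
            acc[snp] = acc.get(snp, 0.0) + w_g * scale * w_c
    return pd.Series(acc, dtype=float).sort_index()


def compute_gene_sd(gene_model: GeneModel, cpg_covariance: pd.DataFrame) -> float:
    """sigma_g = sqrt(w_g' Cov(M) w_g) over the gene's weighted CpGs."""
    cpgs, w = gene_model.nonzero()
    if len(cpgs) == 0:
        return 0.0
    missing = [c for c in cpgs if c not in cpg_covariance.index]
    if missing:
        raise KeyError(f"covariance missing CpGs: {missing}")
    C = cpg_covariance.loc[cpgs, cpgs].to_numpy(dtype=float)
    q = float(w @ C @ w)
    return float(np.sqrt(max(q, 0.0)))


def _cpg_scale_ratios(gene_model: GeneModel, cpg_models: dict[str, CpGModel],
                      cpg_cov: pd.DataFrame) -> pd.Series:
    """Per-CpG factor sd_src_j / sd_pred_j relating the covariance source
    to the stage-1 prediction scale (exactly 1 for the predicted source
    estimated on the training panel)."""
    cpgs, _ = gene_model.nonzero()
    out = {}
    for c in cpgs:
        sd_pred = cpg_models[c].sd_pred
        if sd_pred <= 0:
            raise ValueError(f"CpG {c} has zero predicted SD")
        out[c] = float(np.sqrt(max(cpg_cov.loc[c, c], 0.0))) / sd_pred
    return pd.Series(out)


def gene_cascade_terms(gene_model: GeneModel, cpg_models: dict[str, CpGModel],
                       cov: CovarianceStore):
    """Composite per-SNP coefficients and sigma_g for one gene.

    Returns (coef, sigma_g) with coef_k = w_k * sigma_k such that
    z_g = coef . z / sigma_g; coef is indexed by SNP id.
    """
    scale = _cpg_scale_ratios(gene_model, cpg_models, cov.cpg_cov)
    w = compose_weights(cpg_models, gene_model, cpg_scale=scale)
    sigma_g = compute_gene_sd(gene_model, cov.cpg_cov)
    missing_sd = [s for s in w.index if s not in cov.snp_sd.index]
    if missing_sd:
        raise KeyError(f"reference SD missing for SNPs: {missing_sd[:10]}")
    coef = w * cov.snp_sd.reindex(w.index)
    return coef, sigma_g


def cascade_zscores(harmonized: HarmonizedStats,
                    cpg_models: list[CpGModel] | dict,
                    gene_models: list[GeneModel],
                    cov: CovarianceStore) -> tuple[pd.DataFrame, dict]:
    """Gene-level z-scores from harmonized GWAS z-scores.

    SNPs absent from the harmonized input contribute zero and are
    counted in the diagnostics. Genes with sigma_g = 0 or no overlapping
    SNP are excluded and listed in the diagnostics log.
    """
    cmodels = {m.cpg_id: m for m in cpg_models} if not isinstance(cpg_models, dict) else cpg_models
    z = harmonized.z
    rows = []
    log = {"untestable": [], "n_snps_missing": {}}
    for gm in gene_models:
        if not gm.usable:
            log["untestable"].append((gm.gene_id, "no nonzero CpG weights"))
            continue
        coef, sigma_g = gene_cascade_terms(gm, cmodels, cov)
        if sigma_g <= 0 or coef.abs().sum() == 0:
            log["untestable"].append((gm.gene_id, "zero predicted variance"))
            continue
        avail = coef.index.intersection(z.index)
        n_missing = len(coef.index) - len(avail)
        if len(avail) == 0:
            log["untestable"].append((gm.gene_id, "no overlapping GWAS SNPs"))
            continue
        zg = float(coef.loc[avail] @ z.loc[avail]) / sigma_g
        log["n_snps_missing"][gm.gene_id] = n_missing
        rows.append({
            "gene": gm.gene_id,
            "zscore": zg,
            "pvalue": 2 * stats.norm.sf(abs(zg)),
            "n_snps_used": int((coef.loc[avail] != 0).sum()),
            "n_cpgs_used": len(gm.nonzero()[0]),
            "sigma_g": sigma_g,
            "cascade_r2": gm.cascade_r2,
        })
    cols = ["gene", "zscore", "pvalue", "n_snps_used", "n_cpgs_used",
            "sigma_g", "cascade_r2"]
    return pd.DataFrame(rows, columns=cols), log


def cpg_zscores(harmonized: HarmonizedStats,
                cpg_models: list[CpGModel],
                snp_cov: pd.DataFrame) -> pd.DataFrame:
    """CpG-level z-scores: z_c = w' (sigma * z) / sqrt(w' Cov(S) w)."""
    z = harmonized.z
    snp_sd = pd.Series(np.sqrt(np.diag(snp_cov)), index=snp_cov.index)
    rows = []
    for m in cpg_models:
        if not m.usable:
            continue
        snps, w = m.nonzero()
        C = snp_cov.loc[snps, snps].to_numpy(dtype=float)
        sigma_c = float(np.sqrt(max(w @ C @ w, 0.0)))
        if sigma_c == 0:
            continue
        coef = pd.Series(w * snp_sd.reindex(snps).to_numpy(), index=snps)
        avail = coef.index.intersection(z.index)
        if len(avail) == 0:
            continue
        zc = float(coef.loc[avail] @ z.loc[avail]) / sigma_c
        rows.append({"cpg": m.cpg_id, "zscore": zc,
                     "pvalue": 2 * stats.norm.sf(abs(zc)),
                     "n_snps_used": int(len(avail)), "cv_r2": m.cv_r2})
    return pd.DataFrame(rows)


def map_cpg_to_gene(cpg_table: pd.DataFrame, gene_annotation: pd.DataFrame,
                    mode: str = "closest",
                    window: int = 500_000) -> pd.DataFrame:
    """Assign per-gene p-values from CpG-level results without expression.

    ``cpg_table`` is indexed by CpG id with columns pos, pvalue and (for
    mode="max_r2") cv_r2. mode="closest" picks the minimum-|distance|
    CpG (ties broken by smaller coordinate); mode="max_r2" picks the
    highest-cv_r2 CpG within the window of the TSS. Genes with no CpG in
    the window are excluded.
    """
    if mode not in ("closest", "max_r2"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    tbl = cpg_table.sort_values("pos", kind="mergesort")
    for gene in gene_annotation.index:
        tss = int(gene_annotation.loc[gene, "tss"])
        dist = (tbl["pos"] - tss).abs()
        in_window = tbl[dist <= window]
        if in_window.empty:
            continue
        if mode == "closest":
            d = (in_window["pos"] - tss).abs()
            # stable sort on (distance, position): ties go to the smaller coordinate
            pick = in_window.loc[d.sort_values(kind="mergesort").index[0]]
            chosen = d.sort_values(kind="mergesort").index[0]
        else:
            r2 = in_window["cv_r2"]
            chosen = r2.sort_values(ascending=False, kind="mergesort").index[0]
            pick = in_window.loc[chosen]
        rows.append({"gene": gene, "pvalue": float(pick["pvalue"]), "cpg": chosen})
    return pd.DataFrame(rows)


def exclude_mhc(gene_models: list[GeneModel],
                mhc_region: tuple | None,
                window: int = 500_000) -> list[GeneModel]:
    """Drop genes whose [TSS - window, TSS + window] interval overlaps
    the given (chrom, start, end) region (closed intervals). ``None``
    disables the filter."""
    if mhc_region is None:
        return list(gene_models)
    chrom, start, end = mhc_region
    if end < start:
        raise ValueError("malformed region: end < start")
    kept = []
    for g in gene_models:
        if str(g.chrom) == str(chrom) and g.tss - window <= end and g.tss + window >= start:
            continue
        kept.append(g)
    return kept
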