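"""Competitive gene-set and brain-region association of gene z-scores.

Gene-level z-scores are modeled by generalized least squares,

    z = C a + x b + eps,   eps ~ N(0, s^2 * Sigma),

where C holds an intercept plus confounds (by default the number of
SNP-CpG pairs selected for each gene), x is either a binary set-
membership indicator or a continuous per-gene covariate (e.g. regional
expression t-values), and Sigma is a gene-gene correlation estimated
from expression data with oracle-approximating shrinkage (OAS) so that
its inverse is well conditioned. Sigma is treated as known up to the
scalar s^2, which is estimated from the GLS residuals; the enrichment
test is one-sided for b > 0 by default, following the competitive
gene-set testing convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .containers import CpGModel, GeneModel

T_CAP = 1e6  # cap for t-statistics with zero residual variance


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def oas_shrinkage(feature_matrix, standardize: bool = True):
    """Oracle-approximating shrinkage covariance (Chen-Wiesel-Eldar-Hero).

    Returns (Sigma_hat, rho_hat) with

        Sigma_hat = (1 - rho) S + rho (tr S / q) I,
        rho = min(1, [(1 - 2/q) tr(S^2) + tr(S)^2] /
                     [(n + 1 - 2/q) (tr(S^2) - tr(S)^2 / q)]),

    where S is the empirical covariance (1/n convention) of the n x q
    input, or the sample correlation when ``standardize`` is on.
    The result is positive definite whenever rho > 0.
    """
    is_frame = isinstance(feature_matrix, pd.DataFrame)
    X = feature_matrix.to_numpy(dtype=float) if is_frame else np.asarray(feature_matrix, dtype=float)
    n, q = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for shrinkage estimation")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = Xc.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0)[:5]
            names = list(feature_matrix.columns[bad]) if is_frame else bad.tolist()
            raise ValueError(f"constant columns cannot be standardized: {names}")
        Xc = Xc / sd
    S = Xc.T @ Xc / n
    tr_s = float(np.trace(S))
    tr_s2 = float(np.sum(S * S))  # tr(S @ S) for symmetric S
    mu = tr_s / q
    denom = (n + 1 - 2.0 / q) * (tr_s2 - tr_s**2 / q)
    if denom <= 0:
        rho = 1.0
    else:
        rho = min(1.0, ((1 - 2.0 / q) * tr_s2 + tr_s**2) / denom)
    sigma = (1 - rho) * S + rho * mu * np.eye(q)
    if is_frame:
        sigma = pd.DataFrame(sigma, index=feature_matrix.columns,
                             columns=feature_matrix.columns)
    return sigma, float(rho)


def count_selected_snps(cpg_models: dict[str, CpGModel] | list,
                        gene_model: GeneModel,
                        strict_positive: bool = False) -> int:
    """Confound value: number of (CpG, SNP) pairs on active paths.

    Counts pairs with w_g * w_c != 0 (or > 0 with ``strict_positive``);
    a SNP shared by two weighted CpGs counts twice.
    """
    cmodels = {m.cpg_id: m for m in cpg_models} if not isinstance(cpg_models, dict) else cpg_models
    count = 0
    cpgs, wg = gene_model.nonzero()
    for cpg, w_g in zip(cpgs, wg):
        _, wc = cmodels[cpg].nonzero()
        prod = w_g * wc
        count += int(np.sum(prod > 0)) if strict_positive else int(np.sum(prod != 0))
    return count


@dataclass
class GlsFit:
    beta: np.ndarray      # coefficients for [C | x]
    se: np.ndarray
    t: float              # t statistic of the covariate of interest
    p: float              # one-sided p for beta_x > 0
    p_two_sided: float
    dof: int


def _gls_whitened(zw: np.ndarray, Xw: np.ndarray,
                  covariate_name: str = "x") -> GlsFit:
    """OLS on Sigma^(-1/2)-whitened responses and design."""
    q, p = Xw.shape
    if np.linalg.matrix_rank(Xw) < p:
        raise ValueError(f"design is rank deficient (covariate {covariate_name!r} "
                         "may be constant or collinear with confounds)")
    dof = q - p
    if dof < 1:
        raise ValueError("not enough genes for the requested design")
    xtx = Xw.T @ Xw
    beta = np.linalg.solve(xtx, Xw.T @ zw)
    resid = zw - Xw @ beta
    s2 = float(resid @ resid) / dof
    cov_beta = s2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[-1] / se[-1] if se[-1] > 0 else np.sign(beta[-1]) * T_CAP
    t = float(np.clip(t, -T_CAP, T_CAP))
    return GlsFit(beta=beta, se=se, t=t,
                  p=float(stats.t.sf(t, dof)),
                  p_two_sided=float(2 * stats.t.sf(abs(t), dof)),
                  dof=dof)


def gls_fit(z: np.ndarray, C: np.ndarray, x: np.ndarray,
            sigma: np.ndarray, covariate_name: str = "x") -> GlsFit:
    """Generalized least squares of z on [C | x] with error covariance sigma.

    beta = (X' Sigma^-1 X)^-1 X' Sigma^-1 z; the residual scale is
    estimated on q - d - 1 degrees of freedom (d = columns of C) and the
    covariate p-value is one-sided (beta > 0) from the t distribution.
    Computed by Cholesky whitening followed by ordinary least squares,
    which is algebraically identical and numerically stabler than the
    normal equations.
    """
    z = np.asarray(z, dtype=float).ravel()
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[0] != z.shape[0]:
        C = C.T
    x = np.asarray(x, dtype=float).ravel()
    X = np.column_stack([C, x])
    L = np.linalg.cholesky(np.asarray(sigma, dtype=float))
    zw = linalg.solve_triangular(L, z, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    return _gls_whitened(zw, Xw, covariate_name)


def _design_confounds(genes, confounds: pd.DataFrame | pd.Series | None):
    C = np.ones((len(genes), 1))
    if confounds is not None:
        cf = confounds.reindex(genes)
        arr = cf.to_numpy(dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if np.isnan(arr).any():
            raise ValueError("confounds missing for some tested genes")
        C = np.column_stack([C, arr])
    return C


def enrich_gene_sets(gene_z: pd.Series, collections: dict,
                     sigma: pd.DataFrame,
                     confounds: pd.DataFrame | pd.Series | None = None,
                     min_size: int = 10, max_size: int = 200,
                     one_sided: bool = True) -> pd.DataFrame:
    """Competitive GLS enrichment of each gene set in each collection.

    ``collections`` maps collection label -> {set name -> gene ids};
    a flat {set name -> gene ids} dict is treated as one collection.
    Sets are retained when their intersection with the tested genes has
    ``min_size`` to ``max_size`` members; Benjamini-Hochberg FDR is
    applied within each collection separately.
    """
    if collections and not isinstance(next(iter(collections.values())), dict):
        collections = {"sets": collections}
    genes = [g for g in gene_z.index if g in sigma.index]
    if not genes:
        raise ValueError("no overlap between gene z-scores and Sigma")
    z = gene_z.loc[genes].to_numpy(dtype=float)
    S = sigma.loc[genes, genes].to_numpy(dtype=float)
    C = _design_confounds(genes, confounds)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # factor Sigma once; each set only whitens its own indicator
    L = np.linalg.cholesky(S)
    zw = linalg.solve_triangular(L, z, lower=True)
    Cw = linalg.solve_triangular(L, C, lower=True)

    out = []
    for label, sets in collections.items():
        rows = []
        for name in sorted(sets):
            members = set(sets[name]) & set(genes)
            if not (min_size <= len(members) <= max_size):
                continue
            x = np.zeros(len(genes))
            x[[gene_pos[g] for g in members]] = 1.0
            xw = linalg.solve_triangular(L, x, lower=True)
            fit = _gls_whitened(zw, np.column_stack([Cw, xw]),
                                covariate_name=name)
            rows.append({"collection": label, "set": name,
                         "n_genes": len(members),
                         "beta": float(fit.beta[-1]), "se": float(fit.se[-1]),
                         "p": fit.p if one_sided else fit.p_two_sided})
        if rows:
            df = pd.DataFrame(rows)
            df["fdr_q"] = multipletests(df["p"], method="fdr_bh")[1]
            out.append(df)
    if not out:
        import warnings
        warnings.warn("no gene sets retained after size filtering")
        return pd.DataFrame(columns=["collection", "set", "n_genes",
                                     "beta", "se", "p", "fdr_q"])
    return pd.concat(out, ignore_index=True)


def region_tvalues(expression: pd.DataFrame, t_cap: float = T_CAP) -> pd.DataFrame:
    """Gene x region t-statistics of region-specific expression elevation.

    ``expression`` is long format with columns gene, region, subject,
    value. Duplicate gene-region measurements are averaged within each
    subject; each subject's values are centered by that subject's
    cross-region mean for the gene; a one-sample t across subjects is
    computed per gene-region pair (>= 2 subjects required, otherwise the
    entry is missing). Zero-variance pairs get a capped +/- t_cap.
    """
    needed = {"gene", "region", "subject", "value"}
    if not needed.issubset(expression.columns):
        raise ValueError(f"expected columns {sorted(needed)}")
    avg = (expression.groupby(["subject", "gene", "region"], sort=True)["value"]
           .mean().reset_index())
    # center within subject-gene across regions
    avg["centered"] = avg["value"] - avg.groupby(["subject", "gene"])["value"].transform("mean")

    def _t(vals: pd.Series) -> float:
        v = vals.to_numpy(dtype=float)
        if v.size < 2:
            return np.nan
        m, s = v.mean(), v.std(ddof=1)
        if s == 0:
            return 0.0 if m == 0 else float(np.sign(m) * t_cap)
        return float(m / (s / np.sqrt(v.size)))

    t = avg.groupby(["gene", "region"])["centered"].apply(_t).unstack("region")
    return t


def brain_region_association(gene_z: pd.Series, t_matrix: pd.DataFrame,
                             sigma: pd.DataFrame,
                             confounds: pd.DataFrame | pd.Series | None = None,
                             one_sided: bool = True) -> pd.DataFrame:
    """GLS association of gene z-scores with each region's t-profile.

    Each region's per-gene t-values are the continuous covariate in the
    GLS model; FDR is applied across regions.
    """
    genes = [g for g in gene_z.index
             if g in sigma.index and g in t_matrix.index]
    if not genes:
        raise ValueError("no genes shared between z-scores, Sigma and t-matrix")
    z = gene_z.loc[genes].to_numpy(dtype=float)
    S = sigma.loc[genes, genes].to_numpy(dtype=float)
    C = _design_confounds(genes, confounds)
    L = np.linalg.cholesky(S)
    zw = linalg.solve_triangular(L, z, lower=True)
    Cw = linalg.solve_triangular(L, C, lower=True)
    rows = []
    for region in t_matrix.columns:
        x = t_matrix.loc[genes, region].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"region {region!r} has missing t-values for tested genes")
        xw = linalg.solve_triangular(L, x, lower=True)
        fit = _gls_whitened(zw, np.column_stack([Cw, xw]),
                            covariate_name=str(region))
        rows.append({"region": region, "n_genes": len(genes),
                     "beta": float(fit.beta[-1]), "se": float(fit.se[-1]),
                     "p": fit.p if one_sided else fit.p_two_sided})
    df = pd.DataFrame(rows)
    df["fdr_q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
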