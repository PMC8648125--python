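"""Two-stage sparse model training.

Stage 1 regresses each CpG's methylation on the dosages of SNPs within
+/- 50 kb (elastic net, regularization chosen by 10-fold CV at the
minimum mean CV error). Stage 2 regresses each gene's expression on the
*predicted* methylation of CpGs within +/- 500 kb of its TSS. Genes are
retained only when the squared correlation between the sequential
prediction and measured expression exceeds 0.01.

Predictors and responses are mean-centered (not variance-standardized)
before fitting, so weights stay on the centered-dosage scale that the
summary-statistic cascade expects; a ``standardize`` flag is available.
Training entry points sort samples by id before fitting so results are
invariant to the row order of the inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .containers import CpGModel, DosageMatrix, GeneModel

WINDOW_CPG = 50_000
WINDOW_GENE = 500_000


@dataclass
class TrainingConfig:
    """Settings for both elastic-net stages.

    ``mixing`` is the elastic-net L1/L2 mixing parameter (0.5, the
    PredictDB/MetaXcan convention for cis prediction models);
    ``alphas`` is either the number of points on the automatic
    regularization path or an explicit list of penalty strengths.
    ``lambda_rule`` picks the penalty from the CV curve: "1se" (the
    glmnet coefficient-extraction default: largest penalty within one
    standard error of the CV minimum, which collapses null fits to zero)
    or "min" (the CV-minimum penalty).
    """

    window_cpg: int = WINDOW_CPG
    window_gene: int = WINDOW_GENE
    mixing: float = 0.5
    n_folds: int = 10
    r2_threshold: float = 0.01
    seed: int = 0
    standardize: bool = False
    alphas: object = 100
    max_iter: int = 1000
    lambda_rule: str = "1se"

    def __post_init__(self):
        if self.window_cpg <= 0 or self.window_gene <= 0:
            raise ValueError("windows must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not (0 < self.mixing <= 1):
            raise ValueError("mixing must be in (0, 1]")
        if self.lambda_rule not in ("1se", "min"):
            raise ValueError(f"unknown lambda_rule {self.lambda_rule!r}")


def residualize_top_pcs(matrix, k: int):
    """Remove the top-k principal components from a feature matrix.

    Columns are mean-centered first; with ``k=0`` the centered input is
    returned. The residual has exactly zero projection onto the removed
    component scores.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    Xc = X - X.mean(axis=0)
    if k == 0:
        out = Xc
    else:
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(s > s[0] * max(Xc.shape) * np.finfo(float).eps)) if s.size else 0
        if k >= rank:
            raise ValueError(f"k={k} >= rank {rank}: nothing would remain")
        out = Xc - (U[:, :k] * s[:k]) @ Vt[:k]
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def select_cis_snps(cpg_chrom: str, cpg_position: int,
                    snp_annotation: pd.DataFrame,
                    window: int = WINDOW_CPG) -> list:
    """SNP ids with |pos - cpg_position| <= window on the same chromosome."""
    ann = snp_annotation
    mask = (ann["chrom"].astype(str) == str(cpg_chrom)) & \
           ((ann["pos"] - cpg_position).abs() <= window)
    return list(ann.index[mask])


def select_cis_cpgs(gene_chrom: str, tss: int,
                    cpg_annotation: pd.DataFrame,
                    window: int = WINDOW_GENE) -> list:
    """CpG ids within +/- window of the TSS (strand ignored)."""
    ann = cpg_annotation
    if ann.empty:
        return []
    mask = (ann["chrom"].astype(str) == str(gene_chrom)) & \
           ((ann["pos"] - tss).abs() <= window)
    return list(ann.index[mask])


def fit_sparse_model(X: np.ndarray, y: np.ndarray, config: TrainingConfig,
                     penalty_weights: np.ndarray | None = None):
    """Elastic-net fit with CV-selected penalty; returns (weights, cv_r2).

    ``penalty_weights`` are per-predictor penalty factors (glmnet-style);
    they are applied by rescaling columns, which reproduces the weighted
    L1 penalty exactly. A zero-variance response or an empty predictor
    matrix yields all-zero weights and cv_r2 = 0 rather than an error.

    cv_r2 is 1 - (minimum mean CV MSE) / var(y), floored at 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"X {X.shape} and y {y.shape} are misaligned")
    n, p = X.shape
    if p == 0:
        return np.zeros(0), 0.0
    var_y = y.var(ddof=0)
    if var_y == 0:
        return np.zeros(p), 0.0
    if n < config.n_folds:
        raise ValueError(f"need >= {config.n_folds} samples, got {n}")

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    if config.standardize:
        sd = Xc.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    else:
        sd = np.ones(p)
    if penalty_weights is not None:
        pw = np.asarray(penalty_weights, dtype=float)
        if pw.shape != (p,) or np.any(pw <= 0):
            raise ValueError("penalty_weights must be positive, one per predictor")
        Xc = Xc / pw
    else:
        pw = np.ones(p)

    model = ElasticNetCV(
        l1_ratio=config.mixing,
        alphas=config.alphas,
        fit_intercept=False,
        max_iter=config.max_iter,
        cv=KFold(config.n_folds, shuffle=True, random_state=config.seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at tiny penalties
        model.fit(Xc, yc)
        mse_mean = model.mse_path_.mean(axis=-1)
        i_min = int(np.argmin(mse_mean))
        if config.lambda_rule == "min":
            coef, i_chosen = model.coef_, i_min
        else:
            se = model.mse_path_.std(axis=-1, ddof=1) / np.sqrt(config.n_folds)
            within = np.flatnonzero(mse_mean <= mse_mean[i_min] + se[i_min])
            # alphas_ is sorted descending: the first qualifying index is
            # the largest penalty within one SE of the minimum
            i_chosen = int(within[0])
            if i_chosen == i_min:
                coef = model.coef_
            else:
                from sklearn.linear_model import ElasticNet

                refit = ElasticNet(alpha=float(model.alphas_[i_chosen]),
                                   l1_ratio=config.mixing, fit_intercept=False,
                                   max_iter=config.max_iter)
                refit.fit(Xc, yc)
                coef = refit.coef_
    cv_r2 = max(0.0, 1.0 - float(mse_mean[i_chosen]) / var_y)
    weights = coef / (pw * sd)
    return weights, cv_r2


def mqtl_penalty_weights(mqtl_pvalues) -> np.ndarray:
    """Penalty factors from per-SNP minimum mQTL p-values.

    factor = min(1, 1e10 * p + 0.5): SNPs with genome-wide-significant
    mQTL evidence are penalized at half the strength of SNPs with
    weak or no evidence.
    """
    p = np.asarray(mqtl_pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("mQTL p-values must lie in [0, 1]")
    return np.minimum(1.0, 1e10 * p + 0.5)


def _align_sorted(a: pd.DataFrame, b: pd.DataFrame):
    common = a.index.intersection(b.index).sort_values()
    if len(common) == 0:
        raise ValueError("no shared samples between matrices")
    return a.loc[common], b.loc[common]


def train_cpg_models(dosage: DosageMatrix, methylation: pd.DataFrame,
                     cpg_annotation: pd.DataFrame, config: TrainingConfig,
                     penalty_weights: pd.Series | None = None) -> list[CpGModel]:
    """Fit one stage-1 model per CpG with a nonempty cis SNP set.

    ``sd_pred`` is the SD (ddof=1) of the in-sample model prediction.
    ``penalty_weights`` is an optional per-SNP penalty-factor Series.
    """
    if not dosage.frame.index.intersection(methylation.index).size:
        raise ValueError("dosage and methylation share no samples")
    dos, meth = _align_sorted(dosage.frame, methylation)
    models = []
    for cpg in cpg_annotation.index:
        chrom, pos = cpg_annotation.loc[cpg, "chrom"], int(cpg_annotation.loc[cpg, "pos"])
        cis = select_cis_snps(chrom, pos, dosage.annotation, config.window_cpg)
        cis = [s for s in cis if s in dos.columns]
        if not cis or cpg not in meth.columns:
            models.append(CpGModel(cpg, str(chrom), pos, [], np.zeros(0)))
            continue
        X = dos[cis].to_numpy(dtype=float)
        y = meth[cpg].to_numpy(dtype=float)
        pw = penalty_weights.reindex(cis).to_numpy() if penalty_weights is not None else None
        w, cv_r2 = fit_sparse_model(X, y, config, penalty_weights=pw)
        pred = (X - X.mean(axis=0)) @ w
        sd_pred = float(np.std(pred, ddof=1)) if np.any(w != 0) else 0.0
        models.append(CpGModel(cpg, str(chrom), pos, cis, w,
                               sd_pred=sd_pred, cv_r2=cv_r2))
    return models


def predict_methylation(dosage: DosageMatrix,
                        cpg_models: list[CpGModel]) -> pd.DataFrame:
    """Predicted methylation M^p = centered dosage @ stage-1 weights.

    Every model with a nonempty cis set contributes a column; an
    all-zero-weight model yields a zero column (such CpGs can never be
    selected as stage-2 predictors). Weighted SNPs missing from the
    dosage matrix raise a KeyError naming them.
    """
    missing = sorted({s for m in cpg_models for s in m.nonzero()[0]
                      if s not in dosage.frame.columns})
    if missing:
        raise KeyError(f"weighted SNPs absent from dosage: {missing[:10]}")
    centered = dosage.frame - dosage.frame.mean(axis=0)
    n = len(dosage.frame)
    out = {}
    for m in cpg_models:
        if not m.cis_snps:
            continue
        snps, w = m.nonzero()
        out[m.cpg_id] = (centered[snps].to_numpy(dtype=float) @ w
                         if len(snps) else np.zeros(n))
    return pd.DataFrame(out, index=dosage.frame.index)


def train_gene_models(m_pred: pd.DataFrame, expression: pd.DataFrame,
                      gene_annotation: pd.DataFrame,
                      cpg_annotation: pd.DataFrame,
                      config: TrainingConfig) -> list[GeneModel]:
    """Fit one stage-2 model per gene on predicted methylation.

    Candidate predictors are the usable stage-1 CpGs within the gene
    window. ``cascade_r2`` is the squared Pearson correlation between
    the sequential prediction and measured expression (0 when the
    prediction is constant).
    """
    mp, expr = _align_sorted(m_pred, expression)
    models = []
    for gene in gene_annotation.index:
        chrom = gene_annotation.loc[gene, "chrom"]
        tss = int(gene_annotation.loc[gene, "tss"])
        cis = select_cis_cpgs(chrom, tss, cpg_annotation, config.window_gene)
        # unusable stage-1 models surface as zero-variance columns
        cis = [c for c in cis if c in mp.columns and mp[c].std() > 0]
        if not cis or gene not in expr.columns:
            models.append(GeneModel(gene, str(chrom), tss, [], np.zeros(0)))
            continue
        X = mp[cis].to_numpy(dtype=float)
        y = expr[gene].to_numpy(dtype=float)
        w, cv_r2 = fit_sparse_model(X, y, config)
        pred = (X - X.mean(axis=0)) @ w
        sd_pred = float(np.std(pred, ddof=1)) if np.any(w != 0) else 0.0
        models.append(GeneModel(gene, str(chrom), tss, cis, w,
                                sd_pred=sd_pred, cv_r2=cv_r2,
                                cascade_r2=_squared_correlation(pred, y)))
    return models


def _squared_correlation(pred: np.ndarray, measured: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(measured) == 0:
        return 0.0
    r = np.corrcoef(pred, measured)[0, 1]
    return float(r * r)


def compute_cascade_r2(dosage: DosageMatrix, expression: pd.DataFrame,
                       cpg_models: list[CpGModel],
                       gene_model: GeneModel) -> float:
    """Squared correlation of the sequential two-stage prediction.

    Applies stage 1 then stage 2 from the dosages and correlates the
    result with measured expression; returns 0 for a constant
    prediction.
    """
    mp = predict_methylation(dosage, cpg_models)
    mp, expr = _align_sorted(mp, expression)
    cpgs, w = gene_model.nonzero()
    missing = [c for c in cpgs if c not in mp.columns]
    if missing:
        raise KeyError(f"gene model references unusable CpGs: {missing}")
    if len(cpgs) == 0:
        return 0.0
    X = mp[cpgs].to_numpy(dtype=float)
    pred = (X - X.mean(axis=0)) @ w
    return _squared_correlation(pred, expr[gene_model.gene_id].to_numpy(dtype=float))


def filter_models(gene_models: list[GeneModel],
                  r2_threshold: float = 0.01) -> list[GeneModel]:
    """Keep genes with cascade R^2 strictly above the threshold."""
    return [g for g in gene_models if g.cascade_r2 > r2_threshold]
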