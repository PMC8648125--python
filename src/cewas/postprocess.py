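"""Detection calls, distinct-signal estimation and replication metrics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._utils import rng_for


@dataclass
class DetectionResult:
    significant: pd.Series  # boolean, indexed by gene
    n_tested: int
    n_significant: int
    threshold: float

    @property
    def detection_rate(self) -> float:
        return self.n_significant / self.n_tested


def bonferroni_detect(pvalues: pd.Series, alpha: float = 0.05) -> DetectionResult:
    """Flag genes with p <= alpha / n_tested (Bonferroni, inclusive cutoff)."""
    p = pd.Series(pvalues, dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values supplied")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    threshold = alpha / len(p)
    sig = p <= threshold
    return DetectionResult(sig, len(p), int(sig.sum()), threshold)


@dataclass
class DistinctSignalResult:
    n_significant_pcs: int
    pc_pvalues: np.ndarray
    observed_pct_variance: np.ndarray
    n_permutations: int


def distinct_signals(predicted_expression: pd.DataFrame | np.ndarray,
                     n_perm: int = 1000, alpha: float = 0.05,
                     seed: int = 0,
                     scheme: str = "within_column") -> DistinctSignalResult:
    """Estimate the number of distinct association signals via PCA + permutation.

    The observed percentage variance of each PC of the (centered)
    predicted-expression matrix is compared to its null distribution
    obtained by permuting the matrix entries: ``within_column`` shuffles
    each gene's column independently (destroying sample and gene
    structure while preserving per-gene marginals); ``full_matrix``
    shuffles all entries jointly. p = (1 + #{perm >= obs}) / (1 + n_perm)
    and PCs with p < alpha are counted as distinct signals.
    """
    X = predicted_expression.to_numpy(dtype=float) \
        if isinstance(predicted_expression, pd.DataFrame) else np.asarray(predicted_expression, dtype=float)
    n, p = X.shape
    if p < 2 or n < 3:
        raise ValueError("need >= 2 genes and >= 3 samples")
    if scheme not in ("within_column", "full_matrix"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    def pct_variance(M):
        Mc = M - M.mean(axis=0)
        s = np.linalg.svd(Mc, compute_uv=False)
        tot = np.sum(s**2)
        if tot == 0:
            return None
        return s**2 / tot

    obs = pct_variance(X)
    if obs is None:
        warnings.warn("constant matrix: no principal components")
        return DistinctSignalResult(0, np.array([]), np.array([]), n_perm)

    rng = rng_for(seed, "distinct-signals")
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        if scheme == "within_column":
            perm = rng.permuted(X, axis=0)
        else:
            perm = rng.permutation(X.ravel()).reshape(X.shape)
        null = pct_variance(perm)
        if null is not None:
            exceed += null >= obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return DistinctSignalResult(int(np.sum(pvals < alpha)), pvals, obs, n_perm)


def _top_fraction_positives(p_reference: pd.Series, top_frac: float) -> pd.Index:
    q = len(p_reference)
    k = int(np.ceil(top_frac * q))
    if k < 5:
        raise ValueError(f"top fraction yields {k} positives; need >= 5 for a stable AUC")
    # ties in reference p broken lexicographically by gene id
    order = p_reference.reset_index()
    order.columns = ["gene", "p"]
    order = order.sort_values(["p", "gene"], kind="mergesort")
    return pd.Index(order["gene"].iloc[:k])


def replication_auc(p_reference: pd.Series, p_test: pd.Series,
                    top_frac: float = 0.01) -> float:
    """Rank-based AUC of recovering one study's top genes with another's p-values.

    Positives are the smallest ceil(top_frac * q) reference p-values on
    the shared gene universe; the AUC is the Mann-Whitney statistic of
    -p_test with midrank tie handling, equivalent to sweeping a p-value
    threshold from 0 to 1.
    """
    shared = p_reference.index.intersection(p_test.index)
    if len(shared) == 0:
        raise ValueError("no shared genes")
    ref = p_reference.loc[shared]
    tst = p_test.loc[shared]
    positives = _top_fraction_positives(ref, top_frac)
    q, k = len(shared), len(positives)
    ranks = pd.Series(rankdata(-tst.to_numpy()), index=shared)
    rank_sum = float(ranks.loc[positives].sum())
    return (rank_sum - k * (k + 1) / 2) / (k * (q - k))


def auc_permutation_null(p_reference: pd.Series, p_test: pd.Series,
                         top_frac: float = 0.01, n_perm: int = 10_000,
                         seed: int = 0) -> dict:
    """Permutation null of the replication AUC.

    Test p-values are permuted over gene labels ``n_perm`` times; since
    the AUC depends only on which ranks land on the positive set, each
    permutation draws the positive positions at random. Returns the null
    mean and SD, the observed AUC and its empirical p-value
    (1 + #{perm >= obs}) / (1 + n_perm).
    """
    shared = p_reference.index.intersection(p_test.index)
    ref = p_reference.loc[shared]
    tst = p_test.loc[shared]
    positives = _top_fraction_positives(ref, top_frac)
    q, k = len(shared), len(positives)
    ranks = rankdata(-tst.to_numpy())
    pos_mask = shared.isin(positives)
    observed = (float(ranks[pos_mask].sum()) - k * (k + 1) / 2) / (k * (q - k))

    rng = rng_for(seed, "auc-permutation")
    aucs = np.empty(n_perm)
    offset = k * (k + 1) / 2
    denom = k * (q - k)
    for i in range(n_perm):
        idx = rng.choice(q, size=k, replace=False)
        aucs[i] = (ranks[idx].sum() - offset) / denom
    emp_p = (1.0 + np.sum(aucs >= observed)) / (1.0 + n_perm)
    return {"observed": observed, "null_mean": float(aucs.mean()),
            "null_sd": float(aucs.std(ddof=1)), "p": float(emp_p),
            "n_perm": n_perm}


def genomic_correlation(z_a: pd.Series, z_b: pd.Series,
                        min_shared: int = 10) -> float:
    """Pearson correlation of two studies' gene z-scores on shared genes."""
    shared = z_a.index.intersection(z_b.index)
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared genes (< {min_shared})")
    a = z_a.loc[shared].to_numpy(dtype=float)
    b = z_b.loc[shared].to_numpy(dtype=float)
    return float(np.corrcoef(a, b)[0, 1])
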