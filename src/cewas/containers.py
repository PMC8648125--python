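"""In-memory containers shared across the pipeline.

Conventions
-----------
- Sample-by-feature matrices are ``pandas.DataFrame`` objects: rows are
  samples (index = sample ids), columns are feature ids.
- Annotations are ``pandas.DataFrame`` objects indexed by feature id.
  SNP annotation carries ``chrom``, ``pos``, ``a1`` (effect allele) and
  ``a2`` (other allele); CpG annotation carries ``chrom`` and ``pos``;
  gene annotation carries ``chrom`` and ``tss``.
- All standard deviations and covariances use the unbiased (ddof=1)
  convention so that correlation * sd products reproduce covariances
  exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DosageMatrix:
    """Genotype dosages (samples x SNPs) plus per-SNP annotation.

    ``frame`` holds dosages in [0, 2] counting copies of the effect
    allele ``a1``; ``annotation`` is indexed by SNP id with columns
    ``chrom``, ``pos``, ``a1``, ``a2``.
    """

    frame: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self):
        missing = [s for s in self.frame.columns if s not in self.annotation.index]
        if missing:
            raise ValueError(f"SNPs without annotation: {missing[:5]}")

    @property
    def snps(self) -> pd.Index:
        return self.frame.columns

    @property
    def samples(self) -> pd.Index:
        return self.frame.index

    def sd(self, snps=None) -> pd.Series:
        """Per-SNP dosage standard deviation (ddof=1)."""
        sub = self.frame if snps is None else self.frame[list(snps)]
        return sub.std(axis=0, ddof=1)

    def correlation(self, snps) -> pd.DataFrame:
        """Pearson correlation of the given SNP columns."""
        sub = self.frame[list(snps)].to_numpy(dtype=float)
        sd = sub.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [s for s, v in zip(snps, sd) if v == 0]
            raise ValueError(f"monomorphic SNPs have no correlation: {bad[:5]}")
        R = np.corrcoef(sub, rowvar=False)
        R = np.atleast_2d(R)
        return pd.DataFrame(R, index=list(snps), columns=list(snps))


@dataclass
class CpGModel:
    """Stage-1 model: sparse SNP weights predicting one CpG's methylation.

    ``cis_snps`` is the full candidate set within the cis window of the
    CpG; ``weights`` is aligned with it (mostly zeros). ``sd_pred`` is
    the standard deviation of the model prediction in the training data
    and ``cv_r2`` the cross-validated fit. Models whose weights are all
    zero are flagged ``usable=False`` and excluded downstream.
    """

    cpg_id: str
    chrom: str
    pos: int
    cis_snps: list
    weights: np.ndarray
    sd_pred: float = 0.0
    cv_r2: float = 0.0

    @property
    def usable(self) -> bool:
        return len(self.cis_snps) > 0 and bool(np.any(self.weights != 0))

    def nonzero(self) -> tuple[list, np.ndarray]:
        idx = np.flatnonzero(self.weights)
        return [self.cis_snps[i] for i in idx], self.weights[idx]


@dataclass
class GeneModel:
    """Stage-2 model: sparse CpG weights predicting one gene's expression.

    Predictors are stage-1 *predicted* methylation levels. ``cascade_r2``
    is the squared correlation between the sequential (SNP -> CpG ->
    gene) prediction and measured expression.
    """

    gene_id: str
    chrom: str
    tss: int
    cis_cpgs: list
    weights: np.ndarray
    sd_pred: float = 0.0
    cv_r2: float = 0.0
    cascade_r2: float = 0.0

    @property
    def usable(self) -> bool:
        return len(self.cis_cpgs) > 0 and bool(np.any(self.weights != 0))

    def nonzero(self) -> tuple[list, np.ndarray]:
        idx = np.flatnonzero(self.weights)
        return [self.cis_cpgs[i] for i in idx], self.weights[idx]


@dataclass
class HarmonizedStats:
    """GWAS z-scores aligned to the model's allele coding.

    ``stats`` is indexed by SNP id with a ``z`` column (signs already
    flipped where the GWAS coding was swapped); ``drops`` counts SNPs
    removed per category (ambiguous / mismatched / absent).
    """

    stats: pd.DataFrame
    drops: dict = field(default_factory=dict)

    @property
    def z(self) -> pd.Series:
        return self.stats["z"]


@dataclass
class CovarianceStore:
    """Reference second moments consumed by the cascade.

    ``snp_sd``: per-SNP dosage SD from the reference panel.
    ``cpg_cov``: CpG-by-CpG covariance of (predicted or measured) DNAm.
    ``snp_cov``: optional SNP-by-SNP covariance for CpG-level z-scores.
    ``source`` labels where the CpG covariance came from
    ("predicted" | "measured").
    """

    snp_sd: pd.Series
    cpg_cov: pd.DataFrame
    snp_cov: pd.DataFrame | None = None
    source: str = "predicted"

    def __post_init__(self):
        cc = self.cpg_cov
        if not cc.index.equals(cc.columns):
            raise ValueError("cpg_cov must be square with matching labels")


@dataclass
class ModelStore:
    """A trained two-stage model set plus metadata, as persisted on disk."""

    cpg_models: dict
    gene_models: dict
    snp_annotation: pd.DataFrame
    metadata: dict = field(default_factory=dict)
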