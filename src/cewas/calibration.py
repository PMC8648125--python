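"""Null z-score calibration of the gene-level cascade.

For each gene the test draws many null SNP z-score vectors from
N(0, R_i), where R_i is the LD correlation of all SNPs feeding that
gene's model, pushes them through the cascade, and summarizes the
dispersion of the resulting gene z-scores. With LD matched to the model
panel and the CpG covariance estimated from *predicted* methylation,
the per-gene SD converges to 1; substituting measured-methylation
covariance inflates it, and ignoring LD when drawing the inputs
deflates it. A mismatch experiment swaps in an external reference panel
for R_i to quantify sensitivity to LD mis-specification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import correlation_sqrt, nearest_psd_correlation, rng_for
from .containers import CovarianceStore, CpGModel, DosageMatrix, GeneModel
from .cascade import gene_cascade_terms
from .training import predict_methylation


@dataclass
class CalibrationConfig:
    """Settings of one calibration run.

    ``ld_source``: "model_panel" draws inputs under the panel LD;
    "independent" draws i.i.d. N(0,1) inputs (the naive scheme that
    ignores LD). ``cpg_cov_source``: "predicted" | "measured".
    """

    n_draws: int = 10_000
    ld_source: str = "model_panel"
    cpg_cov_source: str = "predicted"
    seed: int = 0
    genes: list | None = None
    outlier_sd: float = 1.2

    def __post_init__(self):
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")
        if self.ld_source not in ("model_panel", "independent"):
            raise ValueError(f"unknown ld_source {self.ld_source!r}")
        if self.cpg_cov_source not in ("predicted", "measured"):
            raise ValueError(f"unknown cpg_cov_source {self.cpg_cov_source!r}")


@dataclass
class CalibrationReport:
    """Per-gene dispersion of null gene z-scores plus a global summary."""

    table: pd.DataFrame  # gene, sd, mean, n_draws [, coverage]
    settings: dict
    skipped: list = field(default_factory=list)

    def fraction_in_band(self, lo: float = 0.9, hi: float = 1.1) -> float:
        sd = self.table["sd"]
        return float(((sd >= lo) & (sd <= hi)).mean()) if len(sd) else float("nan")


def build_ld_correlation(gene_model: GeneModel,
                         cpg_models: dict[str, CpGModel],
                         dosage_panel: DosageMatrix) -> pd.DataFrame:
    """LD correlation R_i over the union of the gene's model SNPs.

    The union runs over the weighted SNPs of every CpG the gene weights;
    SNP order follows genomic position. The matrix is PSD-repaired
    (eigenvalue clipping + diagonal renormalization) before return.
    """
    cpgs, _ = gene_model.nonzero()
    snps: set = set()
    for c in cpgs:
        snps.update(cpg_models[c].nonzero()[0])
    missing = [s for s in snps if s not in dosage_panel.frame.columns]
    if missing:
        raise KeyError(f"panel missing SNPs: {sorted(missing)[:10]}")
    order = sorted(snps, key=lambda s: (dosage_panel.annotation.loc[s, "pos"], s))
    R = dosage_panel.correlation(order)
    repaired = nearest_psd_correlation(R.to_numpy())
    return pd.DataFrame(repaired, index=order, columns=order)


def _covariance_store(cpg_models: list[CpGModel], panel: DosageMatrix,
                      cpg_cov_source: str,
                      measured_methylation: pd.DataFrame | None) -> CovarianceStore:
    m_pred = predict_methylation(panel, cpg_models)
    if cpg_cov_source == "predicted":
        cov = m_pred.cov()
    else:
        if measured_methylation is None:
            raise ValueError("measured_methylation required for the measured source")
        cov = measured_methylation[m_pred.columns].cov()
    return CovarianceStore(snp_sd=panel.sd(), cpg_cov=cov, source=cpg_cov_source)


def _gene_null_sds(gene_models, cmodels, cov, ld_lookup, config,
                   coverage: dict | None = None):
    """Shared driver: per gene, draw null z and push through the cascade."""
    rows, skipped = [], []
    for gm in gene_models:
        if config.genes is not None and gm.gene_id not in config.genes:
            continue
        if not gm.usable:
            skipped.append((gm.gene_id, "unusable model"))
            continue
        coef, sigma_g = gene_cascade_terms(gm, cmodels, cov)
        if sigma_g <= 0:
            skipped.append((gm.gene_id, "zero predicted variance"))
            continue
        R = ld_lookup(gm)
        if R is None:
            skipped.append((gm.gene_id, "insufficient panel coverage"))
            continue
        snps = list(R.index)
        c = coef.reindex(snps).fillna(0.0).to_numpy() / sigma_g
        # project the coefficient through the correlation square root and
        # draw scalars directly: z_g = eps' (L' c), eps ~ N(0, I)
        L = correlation_sqrt(R.to_numpy())
        v = L.T @ c
        rng = rng_for(config.seed, "calibration", gm.gene_id)
        zg = rng.standard_normal((config.n_draws, v.size)) @ v
        row = {"gene": gm.gene_id, "sd": float(np.std(zg, ddof=1)),
               "mean": float(np.mean(zg)), "n_draws": config.n_draws}
        if coverage is not None:
            row["coverage"] = coverage.get(gm.gene_id, 1.0)
        rows.append(row)
    return pd.DataFrame(rows), skipped


def run_calibration(cpg_models: list[CpGModel], gene_models: list[GeneModel],
                    panel: DosageMatrix, config: CalibrationConfig,
                    measured_methylation: pd.DataFrame | None = None) -> CalibrationReport:
    """Null-input calibration under the configured LD and covariance sources."""
    cmodels = {m.cpg_id: m for m in cpg_models}
    cov = _covariance_store(cpg_models, panel, config.cpg_cov_source,
                            measured_methylation)

    def ld_lookup(gm):
        R = build_ld_correlation(gm, cmodels, panel)
        if config.ld_source == "independent":
            return pd.DataFrame(np.eye(len(R)), index=R.index, columns=R.columns)
        return R

    table, skipped = _gene_null_sds(gene_models, cmodels, cov, ld_lookup, config)
    settings = {"n_draws": config.n_draws, "ld_source": config.ld_source,
                "cpg_cov_source": config.cpg_cov_source, "seed": config.seed}
    return CalibrationReport(table, settings, skipped)


def mismatch_experiment(cpg_models: list[CpGModel], gene_models: list[GeneModel],
                        panel: DosageMatrix, alt_panel: DosageMatrix,
                        config: CalibrationConfig,
                        min_coverage: float = 0.5) -> CalibrationReport:
    """Calibration with R_i from an external reference panel.

    Model terms (SNP SDs, CpG covariance, weights) stay on the training
    panel; only the null-draw LD comes from ``alt_panel``. Model SNPs
    missing from the alternative panel contribute zero (they are never
    drawn); genes whose coverage falls below ``min_coverage`` are
    flagged and skipped. Genes with SD above ``config.outlier_sd`` are
    counted in the settings summary.
    """
    cmodels = {m.cpg_id: m for m in cpg_models}
    cov = _covariance_store(cpg_models, panel, config.cpg_cov_source, None)
    coverage: dict = {}

    def ld_lookup(gm):
        cpgs, _ = gm.nonzero()
        snps: set = set()
        for c in cpgs:
            snps.update(cmodels[c].nonzero()[0])
        avail = [s for s in snps if s in alt_panel.frame.columns]
        cover = len(avail) / len(snps) if snps else 0.0
        coverage[gm.gene_id] = cover
        if cover < min_coverage:
            return None
        order = sorted(avail, key=lambda s: (alt_panel.annotation.loc[s, "pos"], s))
        R = nearest_psd_correlation(alt_panel.correlation(order).to_numpy())
        return pd.DataFrame(R, index=order, columns=order)

    table, skipped = _gene_null_sds(gene_models, cmodels, cov, ld_lookup,
                                    config, coverage=coverage)
    n_outliers = int((table["sd"] > config.outlier_sd).sum()) if len(table) else 0
    settings = {"n_draws": config.n_draws, "ld_source": "external_reference",
                "cpg_cov_source": config.cpg_cov_source, "seed": config.seed,
                "outlier_sd": config.outlier_sd, "n_outliers": n_outliers}
    return CalibrationReport(table, settings, skipped)
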