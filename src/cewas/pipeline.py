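"""End-to-end orchestration: simulate -> train -> cascade -> detect -> enrich."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import config_hash, rng_for, write_tsv
from .cascade import cascade_zscores, exclude_mhc, harmonize_alleles
from .containers import CovarianceStore, ModelStore
from .enrichment import count_selected_snps, enrich_gene_sets, oas_shrinkage, read_gmt
from .io import RunConfig, read_gwas, write_covariance_triplets, write_model_store
from .postprocess import bonferroni_detect
from .synthetic import (SimulationConfig, simulate_dataset, simulate_gwas_null,
                        zscores_to_summary_stats)
from .training import (TrainingConfig, filter_models, predict_methylation,
                       train_cpg_models, train_gene_models)


def train_two_stage(dataset, training: TrainingConfig):
    """Fit both stages on one dataset; returns (cpg_models, gene_models, m_pred)."""
    cpg_models = train_cpg_models(dataset.dosage, dataset.methylation,
                                  dataset.truth.cpg_annotation, training)
    m_pred = predict_methylation(dataset.dosage, cpg_models)
    gene_models = train_gene_models(m_pred, dataset.expression,
                                    dataset.truth.gene_annotation,
                                    dataset.truth.cpg_annotation, training)
    return cpg_models, gene_models, m_pred


def _synthetic_gene_sets(genes: list, n_sets: int, rng) -> dict:
    sets = {}
    genes = list(genes)
    for i in range(n_sets):
        size = int(rng.integers(10, min(50, max(11, len(genes)))))
        size = min(size, len(genes))
        sets[f"set{i + 1:03d}"] = set(rng.choice(genes, size=size, replace=False))
    return sets


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a map of output paths.

    Deterministic given the config (the config hash and seed are stamped
    into every output header). When ``gwas_path`` is not given, one null
    GWAS draw under the training-panel LD is simulated; when
    ``gmt_path`` is not given, random gene sets over the simulated genes
    are used so the enrichment stage always runs.
    """
    import dataclasses

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash the scientific settings only, not where they are written
    chash = config_hash({k: v for k, v in dataclasses.asdict(config).items()
                         if k != "outdir"})
    meta = {"config_hash": chash, "seed": config.seed}
    paths = {}

    sim = SimulationConfig(**{"seed": config.seed, **config.simulation})
    dataset = simulate_dataset(sim)

    training = TrainingConfig(window_cpg=config.window_cpg,
                              window_gene=config.window_gene,
                              mixing=config.mixing, n_folds=config.n_folds,
                              r2_threshold=config.r2_threshold,
                              seed=config.seed)
    cpg_models, gene_models, m_pred = train_two_stage(dataset, training)
    retained = filter_models(gene_models, config.r2_threshold)
    retained = exclude_mhc(retained, config.mhc_region, config.window_gene)

    store = ModelStore({m.cpg_id: m for m in cpg_models},
                       {g.gene_id: g for g in retained},
                       dataset.truth.snp_annotation,
                       metadata={"config_hash": chash, "seed": config.seed,
                                 "n_training_samples": sim.n_samples})
    paths["model_store"] = outdir / "models.sqlite"
    write_model_store(store, paths["model_store"], tsv_dir=outdir / "models_tsv")

    cpg_cov = m_pred.cov()
    paths["cpg_covariance"] = outdir / "cpg_covariance.txt.gz"
    write_covariance_triplets(cpg_cov, paths["cpg_covariance"])
    cov = CovarianceStore(snp_sd=dataset.dosage.sd(), cpg_cov=cpg_cov,
                          source="predicted")

    if config.gwas_path:
        gwas, _ = read_gwas(config.gwas_path)
    else:
        model_snps = sorted({s for m in cpg_models if m.usable
                             for s in m.nonzero()[0]})
        R = dataset.dosage.correlation(model_snps).to_numpy()
        z = simulate_gwas_null(R, 1, config.seed)[0]
        gwas = zscores_to_summary_stats(
            z, dataset.truth.snp_annotation.loc[model_snps])
    harmonized = harmonize_alleles(gwas, dataset.truth.snp_annotation)

    genes_df, log = cascade_zscores(harmonized, cpg_models, retained, cov)
    paths["gene_zscores"] = outdir / "gene_zscores.tsv"
    write_tsv(genes_df, paths["gene_zscores"], meta=meta)
    report = pd.DataFrame([harmonized.drops])
    paths["harmonization"] = outdir / "harmonization.tsv"
    write_tsv(report, paths["harmonization"], meta=meta)

    if len(genes_df):
        det = bonferroni_detect(genes_df.set_index("gene")["pvalue"], config.alpha)
        det_df = pd.DataFrame({"gene": det.significant.index,
                               "significant": det.significant.to_numpy()})
    else:
        det_df = pd.DataFrame(columns=["gene", "significant"])
    paths["detection"] = outdir / "detection.tsv"
    write_tsv(det_df, paths["detection"], meta=meta)

    if len(genes_df) >= 12:
        gene_z = genes_df.set_index("gene")["zscore"]
        expr = dataset.expression[gene_z.index]
        sigma, _ = oas_shrinkage(expr, standardize=True)
        confounds = pd.Series(
            {g.gene_id: count_selected_snps(cpg_models, g) for g in retained},
            name="n_selected_snps").reindex(gene_z.index)
        if config.gmt_path:
            collections = {"gmt": read_gmt(config.gmt_path)}
        else:
            rng = rng_for(config.seed, "synthetic-gene-sets")
            collections = {"synthetic": _synthetic_gene_sets(
                list(gene_z.index), config.n_synthetic_gene_sets, rng)}
        enr = enrich_gene_sets(gene_z, collections, sigma, confounds,
                               min_size=min(10, max(2, len(gene_z) // 3)))
    else:
        enr = pd.DataFrame(columns=["collection", "set", "n_genes",
                                    "beta", "se", "p", "fdr_q"])
    paths["enrichment"] = outdir / "enrichment.tsv"
    write_tsv(enr, paths["enrichment"], meta=meta)

    if config.calibration_draws:
        from .calibration import CalibrationConfig, run_calibration
        cal = run_calibration(cpg_models, retained, dataset.dosage,
                              CalibrationConfig(n_draws=config.calibration_draws,
                                                seed=config.seed))
        paths["calibration"] = outdir / "calibration.tsv"
        write_tsv(cal.table, paths["calibration"], meta=meta)

    return paths
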