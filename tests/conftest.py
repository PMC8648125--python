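"""Shared fixtures: trained synthetic systems at several scales.

The session-scoped systems are trained once and reused; tests must not
mutate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from cewas import (SimulationConfig, SyntheticDataset, TrainingConfig,
                   filter_models, train_two_stage)
from cewas.containers import CovarianceStore, CpGModel, DosageMatrix, GeneModel
from cewas.synthetic import simulate_dataset


@dataclass
class TrainedSystem:
    dataset: SyntheticDataset
    training: TrainingConfig
    cpg_models: list
    gene_models: list
    retained: list
    m_pred: pd.DataFrame

    @property
    def cmodels(self) -> dict:
        return {m.cpg_id: m for m in self.cpg_models}


def _train(sim: SimulationConfig, seed: int) -> TrainedSystem:
    ds = simulate_dataset(sim)
    tc = TrainingConfig(seed=seed)
    cpg_models, gene_models, m_pred = train_two_stage(ds, tc)
    return TrainedSystem(ds, tc, cpg_models, gene_models,
                         filter_models(gene_models, tc.r2_threshold), m_pred)


@pytest.fixture(scope="session")
def small_system() -> TrainedSystem:
    """Quick system for unit-level checks of the trained chain."""
    sim = SimulationConfig(n_samples=400, n_snps=120, n_cpgs=12, n_genes=4,
                           ld_block_size=5, within_block_rho=0.6,
                           snps_per_cpg=2, cpgs_per_gene=2,
                           h2_cpg=0.8, h2_gene=0.8, seed=11)
    return _train(sim, seed=11)


@pytest.fixture(scope="session")
def strong_system() -> TrainedSystem:
    """Full-scale strong-signal study: 1,500 SNPs, 150 CpGs, 30 genes,
    1,000 samples, h2 = 0.8 at both stages."""
    sim = SimulationConfig(h2_cpg=0.8, h2_gene=0.8, seed=1)
    return _train(sim, seed=1)


@pytest.fixture(scope="session")
def h2half_system() -> TrainedSystem:
    """Moderate-heritability study (h2_cpg = 0.5) for the covariance-source
    and LD-mismatch contrasts."""
    sim = SimulationConfig(n_samples=800, n_snps=800, n_cpgs=80, n_genes=16,
                           h2_cpg=0.5, h2_gene=0.5, seed=7)
    return _train(sim, seed=7)


def random_toy_system(rng: np.random.Generator, n_snps: int = 8,
                      n_cpgs: int = 4, n_genes: int = 2,
                      n_samples: int = 60):
    """Hand-built random models + panel for exact-arithmetic oracles.

    Weights are dense random (no training involved) so cascading can be
    compared against direct matrix formulas.
    """
    snps = [f"s{i}" for i in range(n_snps)]
    cpgs = [f"c{j}" for j in range(n_cpgs)]
    genes = [f"g{i}" for i in range(n_genes)]
    dos = pd.DataFrame(rng.integers(0, 3, size=(n_samples, n_snps)).astype(float)
                       + 0.01 * rng.standard_normal((n_samples, n_snps)),
                       columns=snps,
                       index=[f"smp{i}" for i in range(n_samples)])
    ann = pd.DataFrame({"chrom": "1", "pos": 1000 * np.arange(1, n_snps + 1),
                        "a1": "A", "a2": "C"}, index=pd.Index(snps, name="snp"))
    panel = DosageMatrix(dos, ann)

    W_c = rng.standard_normal((n_cpgs, n_snps)) * rng.integers(0, 2, (n_cpgs, n_snps))
    W_c[np.all(W_c == 0, axis=1), 0] = 1.0  # every CpG keeps a live path
    centered = dos - dos.mean(axis=0)
    m_pred = pd.DataFrame(centered.to_numpy() @ W_c.T, columns=cpgs,
                          index=dos.index)
    cpg_models = []
    for j, c in enumerate(cpgs):
        cpg_models.append(CpGModel(c, "1", 1000 * (j + 1), snps, W_c[j],
                                   sd_pred=float(m_pred[c].std(ddof=1))))
    W_g = rng.standard_normal((n_genes, n_cpgs)) * rng.integers(0, 2, (n_genes, n_cpgs))
    W_g[np.all(W_g == 0, axis=1), 0] = 1.0
    gene_models = [GeneModel(g, "1", 5000 * (i + 1), cpgs, W_g[i],
                             sd_pred=0.0, cascade_r2=0.5)
                   for i, g in enumerate(genes)]
    cov = CovarianceStore(snp_sd=panel.sd(), cpg_cov=m_pred.cov())
    return panel, cpg_models, gene_models, cov, W_c, W_g
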