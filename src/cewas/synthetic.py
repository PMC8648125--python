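"""Synthetic multi-omic data with the statistical structure the cascade assumes.

The generator emulates, at desk scale, the kind of training data the
two-stage models require: LD-block genotypes, CpG methylation with a
sparse cis-genetic component, gene expression with a sparse CpG-mediated
component, and GWAS summary-statistic z-scores drawn under a specified
LD correlation.

Genotypes are produced by thresholding a latent equicorrelated Gaussian
into {0, 1, 2} at Hardy-Weinberg cut points for the drawn minor-allele
frequency, which gives exact control of within-block LD while producing
valid dosages. All features live on one synthetic chromosome with
uniformly spaced SNPs so that cis-window logic is genuinely exercised.
Residuals are Gaussian and homoscedastic per feature, matching the
implicit assumption of the linear models being emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import nearest_psd_correlation, rng_for, sample_mvn, write_tsv
from .containers import DosageMatrix

CHROM = "1"

# allele pairs that are never strand-ambiguous (no complementary pairs)
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Sizes default to a desk-scale study: 1,000 training samples, 1,500
    SNPs in blocks of 10 with within-block latent correlation 0.7,
    150 CpGs each driven by 2 cis SNPs, and 30 genes each driven by
    3 cis CpGs. ``h2_cpg`` / ``h2_gene`` set the fraction of feature
    variance explained by the genetic / epigenomic component.

    Neighboring CpGs form clusters of ``cpg_cluster_size`` that draw
    their causal SNPs from a shared per-cluster pool, emulating
    co-methylated CpG clusters with shared mQTLs; this gives the
    genetic components of nearby CpGs the mutual correlation that makes
    modeling CpG covariance consequential. Set the cluster size to 1
    for fully independent causal architectures.
    """

    n_samples: int = 1000
    n_snps: int = 1500
    n_cpgs: int = 150
    n_genes: int = 30
    ld_block_size: int = 10
    within_block_rho: float = 0.7
    maf_range: tuple = (0.05, 0.5)
    snps_per_cpg: int = 2
    cpgs_per_gene: int = 3
    cpg_cluster_size: int = 3
    h2_cpg: float = 0.5
    h2_gene: float = 0.3
    seed: int = 0
    snp_spacing: int = 1000  # bp between adjacent SNPs

    def __post_init__(self):
        for name in ("n_samples", "n_snps", "n_cpgs", "n_genes",
                     "ld_block_size", "snp_spacing"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.within_block_rho < 1):
            raise ValueError("within_block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < min <= max <= 0.5")
        for name in ("h2_cpg", "h2_gene"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.snps_per_cpg < 0 or self.cpgs_per_gene < 0:
            raise ValueError("per-feature causal counts must be >= 0")
        if self.cpg_cluster_size < 1:
            raise ValueError("cpg_cluster_size must be >= 1")


@dataclass
class TrueModel:
    """Ground-truth sparse weights and coordinates of the simulated cascade.

    ``true_w_c`` is CpG x SNP, ``true_w_g`` gene x CpG; nonzero entries
    respect the cis windows (50 kb for CpGs, 500 kb for gene TSS) used
    downstream, so window selection can be validated against the truth.
    """

    true_w_c: np.ndarray
    true_w_g: np.ndarray
    snp_annotation: pd.DataFrame
    cpg_annotation: pd.DataFrame
    gene_annotation: pd.DataFrame

    def composite_weights(self) -> np.ndarray:
        """True gene x SNP weights of the composed two-stage model."""
        return self.true_w_g @ self.true_w_c


def _spread_positions(n: int, lo: int, hi: int) -> np.ndarray:
    if n == 1:
        return np.array([(lo + hi) // 2], dtype=int)
    return np.unique(np.linspace(lo, hi, n).astype(int)) if n > 1 else np.array([lo])


def simulate_true_model(config: SimulationConfig,
                        window_cpg: int = 50_000,
                        window_gene: int = 500_000) -> TrueModel:
    """Draw ground-truth coordinates and sparse weights.

    Causal SNPs of a CpG are sampled within +/- ``window_cpg`` of it;
    causal CpGs of a gene within +/- ``window_gene`` of its TSS. Causal
    weights are standard normal.
    """
    rng = rng_for(config.seed, "truth")
    snp_pos = config.snp_spacing * np.arange(1, config.n_snps + 1)
    lo, hi = int(snp_pos[0]), int(snp_pos[-1])
    span = hi - lo
    cpg_margin = min(window_cpg, span // 4)
    cpg_pos = _spread_positions(config.n_cpgs, lo + cpg_margin, hi - cpg_margin)
    cpg_pos = np.resize(cpg_pos, config.n_cpgs)  # tolerate collisions at tiny n
    gene_tss = np.resize(_spread_positions(config.n_genes, lo, hi), config.n_genes)

    snp_ids = [f"snp{i + 1:05d}" for i in range(config.n_snps)]
    cpg_ids = [f"cg{i + 1:05d}" for i in range(config.n_cpgs)]
    gene_ids = [f"gene{i + 1:04d}" for i in range(config.n_genes)]

    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), config.n_snps)]
    snp_annotation = pd.DataFrame(
        {"chrom": CHROM, "pos": snp_pos,
         "a1": [p[0] for p in pairs], "a2": [p[1] for p in pairs]},
        index=pd.Index(snp_ids, name="snp"))
    cpg_annotation = pd.DataFrame(
        {"chrom": CHROM, "pos": cpg_pos}, index=pd.Index(cpg_ids, name="cpg"))
    gene_annotation = pd.DataFrame(
        {"chrom": CHROM, "tss": gene_tss}, index=pd.Index(gene_ids, name="gene"))

    # CpGs in the same cluster reuse a shared pool of causal SNPs *and*
    # their effect directions (shared mQTLs of a co-methylated cluster,
    # whose methylation levels are positively correlated); pool SNPs
    # outside a member's own cis window are topped up independently.
    true_w_c = np.zeros((config.n_cpgs, config.n_snps))
    pools: dict[int, tuple] = {}
    for j, pos in enumerate(cpg_pos):
        cis = np.flatnonzero(np.abs(snp_pos - pos) <= window_cpg)
        k = min(config.snps_per_cpg, cis.size)
        if not k:
            continue
        cluster = j // config.cpg_cluster_size
        if cluster not in pools:
            pool_snps = rng.choice(cis, size=k, replace=False)
            pools[cluster] = (pool_snps, rng.standard_normal(k))
        pool_snps, pool_w = pools[cluster]
        in_window = np.abs(snp_pos[pool_snps] - pos) <= window_cpg
        chosen = list(pool_snps[in_window][:k])
        weights = list(pool_w[in_window][:k])
        extra = np.setdiff1d(cis, chosen)
        if len(chosen) < k and extra.size:
            top_up = rng.choice(extra, size=min(k - len(chosen), extra.size),
                                replace=False)
            chosen += list(top_up)
            weights += list(rng.standard_normal(len(top_up)))
        true_w_c[j, chosen] = weights

    true_w_g = np.zeros((config.n_genes, config.n_cpgs))
    for i, tss in enumerate(gene_tss):
        cis = np.flatnonzero(np.abs(cpg_pos - tss) <= window_gene)
        k = min(config.cpgs_per_gene, cis.size)
        if k:
            chosen = rng.choice(cis, size=k, replace=False)
            true_w_g[i, chosen] = rng.standard_normal(k)

    return TrueModel(true_w_c, true_w_g, snp_annotation, cpg_annotation,
                     gene_annotation)


def simulate_genotypes(config: SimulationConfig,
                       truth: TrueModel | None = None) -> DosageMatrix:
    """Simulate LD-block dosages by thresholding a latent Gaussian.

    SNPs are grouped into consecutive blocks of ``ld_block_size`` (the
    last block may be short); the latent variables are equicorrelated at
    ``within_block_rho`` inside a block and independent across blocks.
    Each SNP's latent value is cut at the Hardy-Weinberg quantiles of a
    MAF drawn uniformly from ``maf_range``, yielding dosages in {0,1,2}.
    """
    if truth is None:
        truth = simulate_true_model(config)
    rng = rng_for(config.seed, "genotypes")
    n, m = config.n_samples, config.n_snps
    rho = config.within_block_rho
    maf = rng.uniform(*config.maf_range, size=m)

    latent = np.empty((n, m))
    for start in range(0, m, config.ld_block_size):
        width = min(config.ld_block_size, m - start)
        shared = rng.standard_normal((n, 1))
        idio = rng.standard_normal((n, width))
        latent[:, start:start + width] = (
            np.sqrt(rho) * shared + np.sqrt(1 - rho) * idio)

    # HWE genotype frequencies for effect-allele frequency p:
    # P(0)=(1-p)^2, P(1)=2p(1-p), P(2)=p^2
    q0 = stats.norm.ppf((1 - maf) ** 2)
    q1 = stats.norm.ppf((1 - maf) ** 2 + 2 * maf * (1 - maf))
    dosages = (latent > q0).astype(float) + (latent > q1)

    frame = pd.DataFrame(dosages,
                         index=pd.Index([f"S{i + 1:05d}" for i in range(n)],
                                        name="sample"),
                         columns=truth.snp_annotation.index)
    return DosageMatrix(frame, truth.snp_annotation)


def _scaled_noise_mix(genetic: np.ndarray, h2: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Add homoscedastic Gaussian noise so each column has variance
    fraction ``h2`` explained by its genetic part.

    h2 = 1 returns the genetic part untouched; h2 = 0 (or a column with
    no genetic variance) yields unit-variance pure noise.
    """
    n, p = genetic.shape
    if h2 == 1.0:
        return genetic.copy()
    var_g = genetic.var(axis=0, ddof=0)
    out = np.empty_like(genetic)
    noise = rng.standard_normal((n, p))
    for j in range(p):
        if h2 == 0.0 or var_g[j] == 0.0:
            out[:, j] = noise[:, j]
        else:
            sd_e = np.sqrt(var_g[j] * (1 - h2) / h2)
            out[:, j] = genetic[:, j] + sd_e * noise[:, j]
    return out


def simulate_methylation(dosage: DosageMatrix, truth: TrueModel,
                         h2_cpg: float, seed: int) -> pd.DataFrame:
    """Methylation = sparse cis-genetic component + Gaussian noise.

    Each CpG column is ``dosage @ w_c`` plus noise scaled so the genetic
    variance fraction equals ``h2_cpg``.
    """
    missing = [s for s in truth.snp_annotation.index if s not in dosage.frame.columns]
    if missing:
        raise KeyError(f"truth references SNPs absent from dosage: {missing[:5]}")
    S = dosage.frame[truth.snp_annotation.index].to_numpy(dtype=float)
    genetic = S @ truth.true_w_c.T
    M = _scaled_noise_mix(genetic, h2_cpg, rng_for(seed, "methylation"))
    return pd.DataFrame(M, index=dosage.frame.index,
                        columns=truth.cpg_annotation.index)


def simulate_expression(methylation: pd.DataFrame, truth: TrueModel,
                        h2_gene: float, seed: int) -> pd.DataFrame:
    """Expression = sparse CpG-mediated component + Gaussian noise."""
    missing = [c for c in truth.cpg_annotation.index if c not in methylation.columns]
    if missing:
        raise KeyError(f"truth references CpGs absent from methylation: {missing[:5]}")
    M = methylation[truth.cpg_annotation.index].to_numpy(dtype=float)
    genetic = M @ truth.true_w_g.T
    E = _scaled_noise_mix(genetic, h2_gene, rng_for(seed, "expression"))
    return pd.DataFrame(E, index=methylation.index,
                        columns=truth.gene_annotation.index)


def simulate_gwas_null(ld: np.ndarray, n_draws: int, seed: int) -> np.ndarray:
    """Draw null SNP z-score vectors from N(0, ld).

    Returns an (n_draws, n_snps) array; each row is one draw, so the
    marginal SD of every SNP's z across draws is ~1. The LD matrix is
    PSD-repaired (eigenvalue clipping + diagonal renormalization) if
    needed before sampling.
    """
    ld = np.asarray(ld, dtype=float)
    if ld.ndim != 2 or ld.shape[0] != ld.shape[1]:
        raise ValueError(f"LD matrix must be square, got {ld.shape}")
    return sample_mvn(ld, n_draws, rng_for(seed, "gwas-null"))


def simulate_gwas_alt(ld: np.ndarray, causal_snp_effects: np.ndarray,
                      seed: int) -> np.ndarray:
    """One alternative-hypothesis z-score draw: z = ld @ u + e, e ~ N(0, ld).

    With ``u = 0`` this reduces exactly to a single null draw; the mean
    shift ``ld @ u`` is the standard propagation of per-SNP
    non-centrality through LD.
    """
    ld = np.asarray(ld, dtype=float)
    u = np.asarray(causal_snp_effects, dtype=float)
    if u.shape != (ld.shape[0],):
        raise ValueError(f"effects shape {u.shape} does not match LD {ld.shape}")
    noise = sample_mvn(ld, 1, rng_for(seed, "gwas-alt"))[0]
    return ld @ u + noise


def zscores_to_summary_stats(z: np.ndarray,
                             snp_annotation: pd.DataFrame) -> pd.DataFrame:
    """Package one z-score vector as a GWAS summary-statistics table."""
    return pd.DataFrame({
        "snp": snp_annotation.index,
        "a1": snp_annotation["a1"].to_numpy(),
        "a2": snp_annotation["a2"].to_numpy(),
        "z": np.asarray(z, dtype=float),
    })


@dataclass
class SyntheticDataset:
    """Bundle of one simulated study: dosages, omics matrices and truth."""

    config: SimulationConfig
    truth: TrueModel
    dosage: DosageMatrix
    methylation: pd.DataFrame
    expression: pd.DataFrame
    extras: dict = field(default_factory=dict)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generative chain for one configuration."""
    truth = simulate_true_model(config)
    dosage = simulate_genotypes(config, truth)
    methylation = simulate_methylation(dosage, truth, config.h2_cpg, config.seed)
    expression = simulate_expression(methylation, truth, config.h2_gene, config.seed)
    return SyntheticDataset(config, truth, dosage, methylation, expression)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write matrices and annotations as TSV; returns the path map."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": ds.config.seed}
    paths = {}
    for name, df in (("dosage", ds.dosage.frame),
                     ("methylation", ds.methylation),
                     ("expression", ds.expression)):
        p = outdir / f"{name}.tsv"
        write_tsv(df, p, meta=meta, index=True)
        paths[name] = p
    for name, ann in (("snp_annotation", ds.truth.snp_annotation),
                      ("cpg_annotation", ds.truth.cpg_annotation),
                      ("gene_annotation", ds.truth.gene_annotation)):
        p = outdir / f"{name}.tsv"
        write_tsv(ann, p, meta=meta, index=True)
        paths[name] = p
    return paths
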