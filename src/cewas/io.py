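"""Readers, writers and run configuration.

The canonical interchange format is TSV; trained models are additionally
persisted to a PredictDB-style SQLite store (``weights`` + ``extra``
tables per stage) with gzipped "ID1 ID2 VALUE" covariance sidecars, the
layout used by summary-statistic TWAS tooling.
"""

from __future__ import annotations

import gzip
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import read_tsv, write_tsv
from .containers import CpGModel, DosageMatrix, GeneModel, ModelStore

SCHEMA_VERSION = "cewas-store-1"
VALID_ALLELES = set("ACGT")

# GRCh37 extended MHC interval, overridable in every entry point
MHC_GRCH37 = ("6", 25_000_000, 35_000_000)


def read_gwas(path, columns: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """Read GWAS summary statistics from TSV.

    Requires columns snp, a1, a2 and either z or beta+se (beta/se rows
    are converted to z = beta / se). ``columns`` maps canonical names to
    the file's header names. Malformed rows (invalid alleles, nonfinite
    or incomputable z) are dropped and counted in the returned log.
    """
    df = read_tsv(path, dtype=str)
    colmap = {k: k for k in ("snp", "a1", "a2", "z", "beta", "se")}
    if columns:
        colmap.update(columns)
    rename = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    for col in ("snp", "a1", "a2"):
        if col not in df.columns:
            raise ValueError(f"GWAS file lacks mandatory column {col!r}")
    if "z" in df.columns:
        z = pd.to_numeric(df["z"], errors="coerce")
    elif {"beta", "se"}.issubset(df.columns):
        beta = pd.to_numeric(df["beta"], errors="coerce")
        se = pd.to_numeric(df["se"], errors="coerce")
        z = beta / se.replace(0, np.nan)
    else:
        raise ValueError("GWAS file needs a z column or beta+se columns")

    out = pd.DataFrame({"snp": df["snp"], "a1": df["a1"].str.upper(),
                        "a2": df["a2"].str.upper(), "z": z})
    ok_alleles = out["a1"].isin(VALID_ALLELES) & out["a2"].isin(VALID_ALLELES)
    ok_z = np.isfinite(out["z"])
    log = {"n_rows": len(out),
           "dropped_alleles": int((~ok_alleles).sum()),
           "dropped_z": int((ok_alleles & ~ok_z).sum())}
    out = out[ok_alleles & ok_z].reset_index(drop=True)
    log["n_kept"] = len(out)
    return out, log


def write_covariance_triplets(cov: pd.DataFrame, path) -> None:
    """Write the upper triangle of a covariance as gzipped 'ID1 ID2 VALUE'."""
    ids = list(cov.index)
    vals = cov.to_numpy(dtype=float)
    with gzip.open(path, "wt") as fh:
        fh.write("ID1 ID2 VALUE\n")
        for i, a in enumerate(ids):
            for j in range(i, len(ids)):
                fh.write(f"{a} {ids[j]} {float(vals[i, j])!r}\n")


def read_covariance_triplets(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=" ")
    ids = pd.unique(pd.concat([df["ID1"], df["ID2"]]))
    cov = pd.DataFrame(0.0, index=ids, columns=ids)
    for a, b, v in df.itertuples(index=False):
        cov.loc[a, b] = v
        cov.loc[b, a] = v
    return cov


def _cpg_frames(cpg_models, snp_annotation):
    w_rows, e_rows = [], []
    for m in cpg_models:
        snps, w = m.nonzero()
        for s, v in zip(snps, w):
            w_rows.append({"feature": m.cpg_id, "predictor": s, "weight": float(v),
                           "ref_allele": snp_annotation.loc[s, "a2"],
                           "eff_allele": snp_annotation.loc[s, "a1"]})
        e_rows.append({"feature": m.cpg_id, "chrom": m.chrom, "pos": m.pos,
                       "n_predictors": len(snps), "cv_r2": m.cv_r2,
                       "sd_pred": m.sd_pred,
                       "cis_set": ",".join(m.cis_snps)})
    wcols = ["feature", "predictor", "weight", "ref_allele", "eff_allele"]
    ecols = ["feature", "chrom", "pos", "n_predictors", "cv_r2", "sd_pred",
             "cis_set"]
    return (pd.DataFrame(w_rows, columns=wcols),
            pd.DataFrame(e_rows, columns=ecols))


def _gene_frames(gene_models):
    w_rows, e_rows = [], []
    for g in gene_models:
        cpgs, w = g.nonzero()
        for c, v in zip(cpgs, w):
            w_rows.append({"feature": g.gene_id, "predictor": c,
                           "weight": float(v), "ref_allele": "NA",
                           "eff_allele": "NA"})
        e_rows.append({"feature": g.gene_id, "chrom": g.chrom, "tss": g.tss,
                       "n_predictors": len(cpgs), "cv_r2": g.cv_r2,
                       "sd_pred": g.sd_pred, "cascade_r2": g.cascade_r2,
                       "cis_set": ",".join(g.cis_cpgs)})
    wcols = ["feature", "predictor", "weight", "ref_allele", "eff_allele"]
    ecols = ["feature", "chrom", "tss", "n_predictors", "cv_r2", "sd_pred",
             "cascade_r2", "cis_set"]
    return (pd.DataFrame(w_rows, columns=wcols),
            pd.DataFrame(e_rows, columns=ecols))


def write_model_store(store: ModelStore, sqlite_path,
                      tsv_dir=None) -> None:
    """Persist both stages to SQLite and (optionally) a TSV mirror."""
    cpg_w, cpg_e = _cpg_frames(store.cpg_models.values(), store.snp_annotation)
    gene_w, gene_e = _gene_frames(store.gene_models.values())
    snp_ann = store.snp_annotation.reset_index()

    with sqlite3.connect(sqlite_path) as con:
        cpg_w.to_sql("cpg_weights", con, if_exists="replace", index=False)
        cpg_e.to_sql("cpg_extra", con, if_exists="replace", index=False)
        gene_w.to_sql("gene_weights", con, if_exists="replace", index=False)
        gene_e.to_sql("gene_extra", con, if_exists="replace", index=False)
        snp_ann.to_sql("snp_annotation", con, if_exists="replace", index=False)
        meta = dict(store.metadata)
        meta["schema_version"] = SCHEMA_VERSION
        pd.DataFrame({"key": list(meta), "value": [str(v) for v in meta.values()]}) \
            .to_sql("metadata", con, if_exists="replace", index=False)

    if tsv_dir is not None:
        tsv_dir = Path(tsv_dir)
        tsv_dir.mkdir(parents=True, exist_ok=True)
        for name, df in (("cpg_weights", cpg_w), ("cpg_extra", cpg_e),
                         ("gene_weights", gene_w), ("gene_extra", gene_e),
                         ("snp_annotation", snp_ann)):
            write_tsv(df, tsv_dir / f"{name}.tsv")


def read_model_store(sqlite_path) -> ModelStore:
    """Load a persisted two-stage model set; validates the schema tag."""
    with sqlite3.connect(sqlite_path) as con:
        meta_df = pd.read_sql("SELECT * FROM metadata", con)
        metadata = dict(zip(meta_df["key"], meta_df["value"]))
        if metadata.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"model store schema {metadata.get('schema_version')!r} "
                f"does not match expected {SCHEMA_VERSION!r}")
        cpg_w = pd.read_sql("SELECT * FROM cpg_weights", con)
        cpg_e = pd.read_sql("SELECT * FROM cpg_extra", con)
        gene_w = pd.read_sql("SELECT * FROM gene_weights", con)
        gene_e = pd.read_sql("SELECT * FROM gene_extra", con)
        snp_ann = pd.read_sql("SELECT * FROM snp_annotation", con).set_index("snp")

    cpg_models = {}
    wmap = dict(tuple(cpg_w.groupby("feature"))) if len(cpg_w) else {}
    for row in cpg_e.itertuples(index=False):
        cis = row.cis_set.split(",") if row.cis_set else []
        weights = np.zeros(len(cis))
        if row.feature in wmap:
            pos = {s: i for i, s in enumerate(cis)}
            for r in wmap[row.feature].itertuples(index=False):
                weights[pos[r.predictor]] = r.weight
        cpg_models[row.feature] = CpGModel(
            row.feature, str(row.chrom), int(row.pos), cis, weights,
            sd_pred=float(row.sd_pred), cv_r2=float(row.cv_r2))

    gene_models = {}
    gmap = dict(tuple(gene_w.groupby("feature"))) if len(gene_w) else {}
    for row in gene_e.itertuples(index=False):
        cis = row.cis_set.split(",") if row.cis_set else []
        weights = np.zeros(len(cis))
        if row.feature in gmap:
            pos = {c: i for i, c in enumerate(cis)}
            for r in gmap[row.feature].itertuples(index=False):
                weights[pos[r.predictor]] = r.weight
        gene_models[row.feature] = GeneModel(
            row.feature, str(row.chrom), int(row.tss), cis, weights,
            sd_pred=float(row.sd_pred), cv_r2=float(row.cv_r2),
            cascade_r2=float(row.cascade_r2))
    return ModelStore(cpg_models, gene_models, snp_ann, metadata)


def read_matrix_tsv(path) -> pd.DataFrame:
    return read_tsv(path, index_col=0)


def read_dosage_tsv(matrix_path, annotation_path) -> DosageMatrix:
    frame = read_matrix_tsv(matrix_path)
    ann = read_tsv(annotation_path, index_col=0)
    return DosageMatrix(frame, ann)


def write_dosage_vcf(dosage: DosageMatrix, path) -> None:
    """Minimal VCF 4.2 with dosages in the DS FORMAT field."""
    samples = list(dosage.frame.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for snp in dosage.frame.columns:
            ann = dosage.annotation.loc[snp]
            ds = "\t".join(f"{v:g}" for v in dosage.frame[snp])
            fh.write(f"{ann['chrom']}\t{int(ann['pos'])}\t{snp}\t{ann['a2']}\t"
                     f"{ann['a1']}\t.\t.\t.\tDS\t{ds}\n")


def read_dosage_vcf(path) -> DosageMatrix:
    """Read a DS-format VCF written by :func:`write_dosage_vcf`."""
    rows, ann_rows, samples = [], [], None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chrom, pos, snp, ref, alt = parts[:5]
            ann_rows.append({"snp": snp, "chrom": chrom, "pos": int(pos),
                             "a1": alt, "a2": ref})
            rows.append([float(v) for v in parts[9:]])
    if samples is None:
        raise ValueError("VCF lacks a #CHROM header line")
    ann = pd.DataFrame(ann_rows).set_index("snp")
    frame = pd.DataFrame(np.asarray(rows).T, index=pd.Index(samples, name="sample"),
                         columns=ann.index)
    return DosageMatrix(frame, ann)


@dataclass
class RunConfig:
    """Single source of truth for one end-to-end run.

    Thresholds default to the published pipeline settings: cascade-R^2
    retention 0.01, Bonferroni alpha 0.05, FDR alpha 0.05, cis windows
    50 kb (CpG) / 500 kb (gene), MHC exclusion on GRCh37 coordinates.
    """

    outdir: str = "cewas_run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    window_cpg: int = 50_000
    window_gene: int = 500_000
    mixing: float = 0.5
    n_folds: int = 10
    r2_threshold: float = 0.01
    alpha: float = 0.05
    mhc_region: tuple | None = None
    gwas_path: str | None = None
    gmt_path: str | None = None
    n_synthetic_gene_sets: int = 20
    calibration_draws: int = 0  # 0 disables the calibration stage

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mhc_region" in raw and raw["mhc_region"] is not None:
            raw["mhc_region"] = tuple(raw["mhc_region"])
        return cls(**raw)
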