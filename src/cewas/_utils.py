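"""Shared numerical and I/O helpers."""

from __future__ import annotations

import hashlib
import zlib

import numpy as np
import pandas as pd

# eigenvalue floor used when repairing indefinite correlation matrices
PSD_EPS = 1e-10


def rng_for(seed: int, *keys) -> np.random.Generator:
    """Deterministic child generator for a (seed, context-keys) pair.

    String keys are hashed with CRC32 so the same textual context always
    maps to the same stream, independent of call order.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


def nearest_psd_correlation(R: np.ndarray, eps: float = PSD_EPS) -> np.ndarray:
    """Repair a symmetric matrix into a PSD correlation matrix.

    Negative eigenvalues are clipped to ``eps`` and the diagonal is
    renormalized to one. A matrix that is already PSD with unit diagonal
    is returned (numerically) unchanged.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"correlation matrix must be square, got {R.shape}")
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    if w.min() >= eps and np.allclose(np.diag(R), 1.0):
        return R
    w = np.clip(w, eps, None)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return (R2 + R2.T) / 2.0


def correlation_sqrt(R: np.ndarray) -> np.ndarray:
    """Matrix square root ``L`` with ``L @ L.T = R`` for sampling.

    Cholesky is attempted first; an eigen square root is used as the
    fallback for matrices that are PSD only up to round-off.
    """
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(R)
        w = np.clip(w, 0.0, None)
        return V * np.sqrt(w)


def sample_mvn(R: np.ndarray, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_draws`` vectors from N(0, R); rows are draws."""
    L = correlation_sqrt(nearest_psd_correlation(R))
    return rng.standard_normal((n_draws, R.shape[0])) @ L.T


def config_hash(obj) -> str:
    """Short stable hash of a configuration object for output provenance."""
    import dataclasses
    import json

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None, index: bool = False) -> None:
    """Write a TSV with a leading ``#``-comment provenance header."""
    with open(path, "w") as fh:
        if meta:
            items = " ".join(f"{k}={v}" for k, v in meta.items())
            fh.write(f"# cewas {items}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
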