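"""Shared numerical helpers: edge vectorization, z-scoring, correlations."""

from __future__ import annotations

import numpy as np


def edge_indices(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the unique edges of an ``n_regions`` symmetric matrix.

    Order is fixed package-wide: lower triangle, row-major, diagonal excluded,
    so edge k connects regions (rows[k], cols[k]) with rows[k] > cols[k].
    """
    return np.tril_indices(n_regions, k=-1)


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def vectorize_edges(mat: np.ndarray) -> np.ndarray:
    """Lower-triangle (diagonal-excluded) vectorization of a symmetric matrix."""
    mat = np.asarray(mat)
    if mat.shape[-1] != mat.shape[-2]:
        raise ValueError("matrix must be square")
    i, j = edge_indices(mat.shape[-1])
    return mat[..., i, j]


def devectorize_edges(vec: np.ndarray, n_regions: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`; diagonal filled with ``diag``."""
    vec = np.asarray(vec)
    if vec.shape[-1] != n_edges(n_regions):
        raise ValueError(
            f"expected {n_edges(n_regions)} edges for {n_regions} regions, got {vec.shape[-1]}"
        )
    i, j = edge_indices(n_regions)
    out = np.full(vec.shape[:-1] + (n_regions, n_regions), float(diag))
    out[..., i, j] = vec
    out[..., j, i] = vec
    return out


def zscore(x: np.ndarray, axis: int = 0, ddof: int = 1) -> np.ndarray:
    """Z-score with sample SD; raises on zero-variance columns."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        bad = np.where(np.squeeze(sd == 0))[0]
        raise ValueError(f"zero-variance columns at positions {bad.tolist()[:10]}")
    return (x - mu) / sd


def column_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of ``a`` with every column of ``b``.

    Returns an (a_cols, b_cols) matrix. Zero-variance columns yield 0 (flagged
    by callers where it matters) rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    n = a.shape[0]
    ac = a - a.mean(0)
    bc = b - b.mean(0)
    sa = ac.std(0, ddof=1)
    sb = bc.std(0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac.T @ bc) / (n - 1) / np.outer(sa, sb)
    return np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)


def rng_from(seed, *stream) -> np.random.Generator:
    """Derive an independent generator for a named sub-stream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))
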