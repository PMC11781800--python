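"""Diffusion map embedding of connectivity into macroscale gradients.

The group connectivity matrix is row-thresholded to its strongest
connections, converted to a cosine-similarity affinity, and embedded with
the diffusion-map operator: an anisotropic normalization
``W' = D^-a W D^-a`` (a = 0.5 balances manifold geometry against sampling
density) followed by the row-stochastic random-walk operator, whose
nontrivial eigenvectors are the gradients. With diffusion time t = 0 the
eigenvectors are used unscaled, retaining global relations between parcels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import connected_components


@dataclass
class GradientResult:
    embedding: np.ndarray  # parcels × n_gradients
    eigenvalues: np.ndarray  # nonincreasing, nonnegative
    variance_explained: np.ndarray
    alignment_rotation: np.ndarray | None = None
    reference_id: str = "unaligned"


def build_affinity(connectivity: np.ndarray, row_top_fraction: float = 0.10) -> np.ndarray:
    """Row-thresholded cosine-similarity affinity of a connectivity matrix.

    Per row, only the strongest ``ceil(fraction * P)`` off-diagonal entries
    are kept; cosine similarity is then computed between thresholded rows
    and negative similarities are clamped to zero (the diffusion operator
    requires a nonnegative affinity).
    """
    C = np.asarray(connectivity, dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("connectivity must be square and symmetric")
    if not 0 < row_top_fraction <= 1:
        raise ValueError("row_top_fraction must be in (0, 1]")
    P = C.shape[0]
    k = int(np.ceil(row_top_fraction * P))
    if k >= P - 1:  # nothing to threshold away
        T = C.copy()
    else:
        T = np.zeros_like(C)
        for i in range(P):
            row = C[i].copy()
            row[i] = -np.inf  # exclude the diagonal from the ranking
            keep = np.argpartition(row, -k)[-k:]
            T[i, keep] = C[i, keep]
    norms = np.linalg.norm(T, axis=1)
    norms[norms == 0] = 1.0
    A = (T @ T.T) / np.outer(norms, norms)
    A = np.clip(A, 0.0, None)
    return 0.5 * (A + A.T)


def diffusion_embed(
    affinity: np.ndarray,
    alpha: float = 0.5,
    t: float = 0.0,
    n_gradients: int = 10,
    seed: int | None = None,
) -> GradientResult:
    """Diffusion map gradients of a nonnegative symmetric affinity.

    Solved as a dense symmetric eigenproblem on the conjugated operator, so
    the result is deterministic (``seed`` is accepted for interface
    symmetry but unused). The trivial constant eigenvector is discarded;
    per-gradient sign is fixed so the largest-magnitude entry is positive.
    """
    W = np.asarray(affinity, dtype=float)
    if W.shape[0] != W.shape[1] or not np.allclose(W, W.T, atol=1e-8):
        raise ValueError("affinity must be square symmetric")
    if np.any(W < 0):
        raise ValueError("affinity must be nonnegative")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if n_gradients < 1:
        raise ValueError("n_gradients must be >= 1")

    n_comp, comp = connected_components(W > 0, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"affinity graph has {n_comp} connected components; embedding each separately"
        )
        P = W.shape[0]
        embedding = np.full((P, n_gradients), np.nan)
        main = None
        for c in range(n_comp):
            mask = comp == c
            if mask.sum() < 2:
                embedding[mask] = 0.0
                continue
            sub = diffusion_embed(W[np.ix_(mask, mask)], alpha, t,
                                  min(n_gradients, mask.sum() - 1))
            embedding[mask, : sub.embedding.shape[1]] = sub.embedding
            if main is None or mask.sum() > main[0]:
                main = (mask.sum(), sub)
        return GradientResult(embedding, main[1].eigenvalues, main[1].variance_explained)

    d = W.sum(1)
    d[d == 0] = 1.0
    Wp = W / np.outer(d**alpha, d**alpha)
    dp = Wp.sum(1)
    inv_sqrt = 1.0 / np.sqrt(dp)
    A = Wp * np.outer(inv_sqrt, inv_sqrt)  # symmetric conjugate of D'^-1 W'
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs * inv_sqrt[:, None]  # right eigenvectors of the walk operator

    # drop the trivial stationary eigenvector (eigenvalue 1, constant psi)
    evals, psi = evals[1:], psi[:, 1:]
    keep = min(n_gradients, psi.shape[1])
    lam = np.clip(evals[:keep], 0.0, None)
    grads = psi[:, :keep] * (lam**t if t != 0 else 1.0)
    # unit-norm gradients with deterministic sign
    norms = np.linalg.norm(grads, axis=0)
    norms[norms == 0] = 1.0
    grads = grads / norms
    idx = np.argmax(np.abs(grads), axis=0)
    signs = np.sign(grads[idx, np.arange(keep)])
    signs[signs == 0] = 1.0
    grads = grads * signs
    return GradientResult(
        embedding=grads,
        eigenvalues=lam,
        variance_explained=variance_explained(lam),
    )


def variance_explained(eigenvalues: np.ndarray) -> np.ndarray:
    """Fraction of connectivity-similarity variance carried by each gradient."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be nonnegative")
    total = lam.sum()
    if total == 0:
        raise ValueError("all eigenvalues are zero")
    return lam / total


def procrustes_align(
    source: GradientResult | np.ndarray,
    reference: np.ndarray,
    reference_id: str = "reference",
) -> GradientResult:
    """Orthogonally rotate gradients onto a reference set (no scaling).

    Columns are centered, then the orthogonal matrix minimizing the
    Frobenius distance to the reference is applied to the leading G source
    gradients (G = reference columns). The unaligned result remains
    available on the input object.
    """
    src = source.embedding if isinstance(source, GradientResult) else np.asarray(source, float)
    ref = np.asarray(reference, dtype=float)
    if src.shape[0] != ref.shape[0]:
        raise ValueError("source and reference must cover the same parcels")
    G = ref.shape[1]
    if G > src.shape[1]:
        raise ValueError("reference has more gradients than the source")
    s = src[:, :G] - src[:, :G].mean(0)
    r = ref - ref.mean(0)
    R, _ = orthogonal_procrustes(s, r)
    aligned = s @ R
    if isinstance(source, GradientResult):
        lam = source.eigenvalues[:G]
        ve = source.variance_explained[:G]
    else:
        lam = np.full(G, np.nan)
        ve = np.full(G, np.nan)
    return GradientResult(
        embedding=aligned,
        eigenvalues=lam,
        variance_explained=ve,
        alignment_rotation=R,
        reference_id=reference_id,
    )
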