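"""Site-restricted permutation and bootstrap inference for latent components.

Acquisition site is a strong nuisance factor in multi-site cohorts, so the
null distribution of the singular values is built by permuting behavior
rows only *within* site, and loading stability is assessed by resampling
subjects with replacement within site (site sizes preserved). Bootstrapped
Z-scores (loading / bootstrap SD) are converted to two-sided normal
p-values and corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import NetworkPartition
from .pls import pls_decompose
from .utils import column_correlations, devectorize_edges, zscore


@dataclass
class PermutationResult:
    n_perm: int
    observed: np.ndarray  # first k_test singular values
    null_distribution: np.ndarray  # n_perm × k_test
    p_values: np.ndarray
    fdr_q: np.ndarray


@dataclass
class BootstrapTarget:
    """One family of loadings tracked across bootstrap resamples.

    data
        Subjects × variables matrix whose correlation with the chosen
        composite defines the loadings (items against LY; imaging features
        or vectorized edges against LX).
    composite
        "LX" or "LY".
    partition / n_regions
        When given, ``data`` columns are vectorized edges; per-resample edge
        loadings are averaged within/between network blocks before Z-scoring,
        limiting the number of comparisons.
    """

    data: np.ndarray
    composite: str = "LX"
    partition: NetworkPartition | None = None
    parcel_order: pd.Index | None = None


@dataclass
class BootstrapResult:
    n_boot: int
    loadings: dict[str, np.ndarray]  # observed (variables × K)
    loading_sd: dict[str, np.ndarray]
    z_scores: dict[str, np.ndarray]
    p_values: dict[str, np.ndarray]
    fdr_mask: dict[str, np.ndarray]
    ci_low: dict[str, np.ndarray]
    ci_high: dict[str, np.ndarray]
    labels: dict[str, list[str]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def permute_within_site(site_labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A subject permutation that maps every site's members onto that site."""
    site_labels = np.asarray(site_labels)
    perm = np.arange(len(site_labels))
    for s in np.unique(site_labels):
        pos = np.where(site_labels == s)[0]
        perm[pos] = pos[rng.permutation(len(pos))]
    return perm


def bootstrap_within_site(site_labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices resampled with replacement within each site (site sizes preserved)."""
    site_labels = np.asarray(site_labels)
    idx = np.empty(len(site_labels), dtype=int)
    for s in np.unique(site_labels):
        pos = np.where(site_labels == s)[0]
        idx[pos] = rng.choice(pos, size=len(pos), replace=True)
    return idx


def _cross_singular_values(Xz: np.ndarray, Yz: np.ndarray, k: int) -> np.ndarray:
    s = np.linalg.svd(Yz.T @ Xz, compute_uv=False)
    return s[:k]


def permutation_test(
    X,
    Y,
    site_labels: np.ndarray,
    n_perm: int = 10_000,
    k_test: int = 5,
    seed: int = 0,
    design: np.ndarray | None = None,
) -> PermutationResult:
    """Significance of the first ``k_test`` components by site-restricted permutation.

    Behavior rows are shuffled within site while imaging stays fixed; each
    permutation's singular values are compared to the observed ones at the
    same component index. p-values use add-one smoothing,
    p = (1 + #{null >= observed}) / (1 + n_perm).

    When the blocks are confound residuals, pass the confound ``design``
    matrix used for the behavior block: each permuted behavior matrix is
    then re-residualized on the design (Freedman-Lane scheme), which
    restores the exchangeability that projecting onto the residual space
    breaks and keeps the test calibrated.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xm = X.to_numpy() if hasattr(X, "to_numpy") else np.asarray(X, float)
    Ym = Y.to_numpy(float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    refit = None
    if design is not None:
        q, _ = np.linalg.qr(np.asarray(design, float))
        refit = lambda M: M - q @ (q.T @ M)
    Xz, Yz = zscore(Xm), zscore(Ym)
    k_test = min(k_test, min(Xz.shape[1], Yz.shape[1]))
    observed = _cross_singular_values(Xz, Yz, k_test)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, k_test))
    for b in range(n_perm):
        perm = permute_within_site(site_labels, rng)
        Yp = Yz[perm]
        if refit is not None:
            Yp = zscore(refit(Yp))
        null[b] = _cross_singular_values(Xz, Yp, k_test)
    p = (1 + (null >= observed).sum(0)) / (1 + n_perm)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return PermutationResult(n_perm, observed, null, p, q)


def block_average_edges(
    edge_loadings: np.ndarray,
    partition: NetworkPartition,
    parcel_order: pd.Index | None = None,
) -> np.ndarray:
    """Average a region × region symmetric loading matrix over network blocks.

    Entry (a, b) is the mean loading over edges with one endpoint in network
    a and the other in b; within-network blocks exclude the diagonal. A
    network with fewer than two regions has an undefined within block (NaN).
    """
    W = np.asarray(edge_loadings, dtype=float)
    if W.shape[0] != W.shape[1] or not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("edge_loadings must be a symmetric square matrix")
    ind = partition.indicator(parcel_order).to_numpy()
    if ind.shape[0] != W.shape[0]:
        raise ValueError("partition does not cover all regions")
    Wz = W.copy()
    np.fill_diagonal(Wz, 0.0)
    sums = ind.T @ Wz @ ind
    counts = ind.T @ np.ones_like(Wz) @ ind
    sizes = ind.sum(0)
    np.fill_diagonal(counts, sizes * (sizes - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    return out


def block_labels(partition: NetworkPartition) -> list[str]:
    """Labels of the B + B(B-1)/2 unique network blocks, upper-triangle order."""
    nets = partition.networks
    return [f"{nets[a]}|{nets[b]}" for a in range(len(nets)) for b in range(a, len(nets))]


def _unique_blocks(block_mat: np.ndarray) -> np.ndarray:
    B = block_mat.shape[0]
    iu, ju = np.triu_indices(B)
    return block_mat[iu, ju]


def _target_loadings(target: BootstrapTarget, result, idx: np.ndarray | None) -> np.ndarray:
    scores = getattr(result, target.composite)
    data = target.data if idx is None else target.data[idx]
    load = column_correlations(data, scores)
    if target.partition is not None:
        n_regions = len(target.partition.labels)
        cols = []
        for k in range(load.shape[1]):
            mat = devectorize_edges(load[:, k], n_regions)
            cols.append(_unique_blocks(block_average_edges(mat, target.partition,
                                                           target.parcel_order)))
        load = np.column_stack(cols)
    return load


def bootstrap_loadings(
    X,
    Y,
    site_labels: np.ndarray,
    n_boot: int = 1000,
    targets: dict[str, BootstrapTarget] | None = None,
    seed: int = 0,
    q: float = 0.05,
) -> BootstrapResult:
    """Loading stability by site-restricted bootstrap.

    Each resample draws subjects with replacement within site, re-runs the
    PLS decomposition, sign-aligns components to the original solution
    (sign of u_k' u0_k; no re-ordering), and records the requested loadings.
    Outputs per target: bootstrap SD, Z = loading / SD, two-sided normal
    p-values, a BH-FDR mask at level ``q``, and 2.5/97.5 percentile CIs.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    Xm = X.to_numpy() if hasattr(X, "to_numpy") else np.asarray(X, float)
    Ym = Y.to_numpy(float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    if targets is None:
        targets = {}
    targets = {"behavior": BootstrapTarget(Ym, composite="LY"), **targets}

    base = pls_decompose(Xm, Ym)
    observed = {name: _target_loadings(t, base, None) for name, t in targets.items()}

    rng = np.random.default_rng(seed)
    draws = {name: np.empty((n_boot,) + obs.shape) for name, obs in observed.items()}
    for b in range(n_boot):
        idx = bootstrap_within_site(site_labels, rng)
        try:
            res = pls_decompose(Xm[idx], Ym[idx])
        except ValueError:  # a resample can kill an item's variance; redraw
            idx = bootstrap_within_site(site_labels, rng)
            res = pls_decompose(Xm[idx], Ym[idx])
        signs = np.sign(np.einsum("ik,ik->k", res.U, base.U))
        signs[signs == 0] = 1.0
        res.LX *= signs
        res.LY *= signs
        for name, t in targets.items():
            draws[name][b] = _target_loadings(t, res, idx)

    out = BootstrapResult(n_boot, observed, {}, {}, {}, {}, {}, {})
    flags: list[str] = []
    for name, obs in observed.items():
        sd = draws[name].std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, obs / np.where(sd > 0, sd, 1.0), np.inf * np.sign(obs))
        if np.any(sd == 0):
            flags.append(f"{name}: zero bootstrap SD for {int((sd == 0).sum())} loadings")
        p = 2 * stats.norm.sf(np.abs(z))  # infinite Z -> p = 0, flagged above
        p = np.where(np.isnan(obs), np.nan, p)
        flat = p.ravel()
        valid = ~np.isnan(flat)
        mask = np.zeros(flat.shape, dtype=bool)
        if valid.any():
            mask[valid], _, _, _ = multipletests(flat[valid], alpha=q, method="fdr_bh")
        out.loading_sd[name] = sd
        out.z_scores[name] = z
        out.p_values[name] = p
        out.fdr_mask[name] = mask.reshape(obs.shape)
        out.ci_low[name] = np.percentile(draws[name], 2.5, axis=0)
        out.ci_high[name] = np.percentile(draws[name], 97.5, axis=0)
    out.flags = flags
    return out


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (reject mask, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted
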