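"""Spin-permutation nulls for correlations between cortical surface maps.

Smooth cortical maps violate the exchangeability assumed by parametric or
naive-permutation correlation tests. The spin test builds a null that
preserves spatial autocorrelation: the spherical coordinates of one map's
parcels are rotated by a uniformly random rotation (mirrored across
hemispheres) and parcel values are reassigned to the rotated centroids
before recomputing the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .containers import NetworkPartition, ParcelSphereCoords
from .inference import fdr_bh


@dataclass
class SpinTestResult:
    observed_r: float
    null_r: np.ndarray
    p_spin: float
    n_spin: int
    two_sided: bool = True


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation (det +1) via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def spin_permutation(
    coords: ParcelSphereCoords,
    n_spin: int = 1000,
    seed: int = 0,
    method: str = "assignment",
) -> np.ndarray:
    """``n_spin`` parcel permutations from random sphere rotations.

    Cortical parcels only (subcortex is excluded from spatial nulls). The
    left hemisphere is rotated by Q and the right by its x-mirrored
    counterpart, preserving bilateral correspondence. With
    ``method="assignment"`` (default) parcels are matched one-to-one to
    rotated centroids by minimum total distance, so every spun map is an
    exact permutation of the original values; ``method="nearest"`` uses
    greedy nearest-centroid lookup, which duplicates a small fraction of
    values.
    """
    cortical = coords.cortical()
    hemi = cortical.hemisphere.to_numpy()
    xyz = cortical.xyz()
    if xyz.shape[0] < 3:
        raise ValueError("need at least 3 cortical parcels to spin")
    if method not in ("assignment", "nearest"):
        raise ValueError("method must be 'assignment' or 'nearest'")
    mirror = np.diag([-1.0, 1.0, 1.0])
    rng = np.random.default_rng(seed)
    perms = np.empty((n_spin, xyz.shape[0]), dtype=int)
    sides = [(h, np.where(hemi == h)[0]) for h in ("L", "R") if (hemi == h).any()]
    for s in range(n_spin):
        Q = random_rotation(rng)
        for h, idx in sides:
            Qh = Q if h == "L" else mirror @ Q @ mirror
            rotated = xyz[idx] @ Qh.T
            if method == "nearest":
                tree = cKDTree(rotated)
                _, nearest = tree.query(xyz[idx])
                perms[s, idx] = idx[nearest]
            else:
                cost = -xyz[idx] @ rotated.T  # chord distance is monotone in -dot
                _, col = linear_sum_assignment(cost)
                perms[s, idx] = idx[col]
    return perms


def spin_correlation(
    map_a: np.ndarray,
    map_b: np.ndarray,
    spins: np.ndarray,
    two_sided: bool = True,
) -> SpinTestResult:
    """Pearson correlation of two cortical maps with a spin null for map_a.

    p = (1 + #{|null| >= |observed|}) / (1 + n_spin) for the two-sided test.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must cover the same cortical parcels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance map")
    observed = float(np.corrcoef(a, b)[0, 1])
    null = np.array([np.corrcoef(a[p], b)[0, 1] for p in spins])
    if two_sided:
        count = (np.abs(null) >= abs(observed)).sum()
    else:
        count = (null >= observed).sum()
    p = (1 + count) / (1 + len(spins))
    return SpinTestResult(observed, null, float(p), len(spins), two_sided)


def parcelwise_network_loadings(
    edge_loadings: np.ndarray,
    partition: NetworkPartition,
    parcel_order: pd.Index | None = None,
    absolute: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-parcel within- and between-network summaries of an edge loading matrix.

    For each region, the within value is the (signed by default) mean
    loading over its edges to regions in the same network, and the between
    value the mean over edges to all other networks.
    """
    W = np.asarray(edge_loadings, dtype=float)
    if absolute:
        W = np.abs(W)
    labels = (partition.labels if parcel_order is None
              else partition.labels.loc[parcel_order]).to_numpy()
    P = W.shape[0]
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    other = ~same
    np.fill_diagonal(other, False)
    with np.errstate(invalid="ignore"):
        within = np.where(same.sum(1) > 0, (W * same).sum(1) / np.maximum(same.sum(1), 1), np.nan)
        between = np.where(other.sum(1) > 0, (W * other).sum(1) / np.maximum(other.sum(1), 1), np.nan)
    return within, between


def gradient_contextualize(
    maps: dict[str, np.ndarray],
    gradient: np.ndarray,
    spins: np.ndarray,
    q: float = 0.05,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Spin-test every cortical loading map against a gradient; FDR across rows.

    ``maps`` is a mapping target name (e.g. ``"thickness_LC1"``,
    ``"rsfc_between_LC1"``) -> cortical parcel map.
    """
    rows = []
    for name, m in maps.items():
        res = spin_correlation(np.asarray(m, float), np.asarray(gradient, float),
                               spins, two_sided=two_sided)
        rows.append((name, res.observed_r, res.p_spin))
    table = pd.DataFrame(rows, columns=["target", "r", "p_spin"])
    reject, adj = fdr_bh(table["p_spin"].to_numpy(), q)
    table["q"] = adj
    table["significant"] = reject
    return table
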