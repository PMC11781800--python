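"""Synthetic multimodal brain-behavior datasets with known ground truth.

The generator emulates the structure of a multi-site pediatric imaging
cohort: per-parcel cortical morphometry (surface area, thickness, volume),
vectorized region-by-region functional connectivity, parent-rated ordinal
symptom items (0/1/2), and a covariate table (age, sex, site, ethnicity,
head motion, intracranial volume, total surface area). Brain-behavior
covariance is carried by a small number of planted latent components whose
saliences are recorded as ground truth, so every downstream stage
(dimensionality reduction, PLS correlation, resampling inference, gradient
embedding, spin tests) can be validated by parameter recovery.

Design of the connectivity generator
------------------------------------
Each subject's region × region matrix is built as

    C_i = C0 + W_i + D_i + r_i * I

where ``C0`` is a group backbone (global offset + within-network blocks +
a Gaussian kernel over a planted 1D gradient, each term positive
semi-definite), ``W_i`` is low-rank Wishart subject noise, ``D_i`` is a
symmetric zero-diagonal term holding the planted latent signal and
subject-level confound effects on edges, and ``r_i = ||D_i||_F`` is a
diagonal compensation that keeps ``C_i`` positive semi-definite while the
off-diagonal edges remain *exactly* linear in the planted subject scores.
Ordinal items are generated by double-thresholding a Gaussian propensity
(graded-response style); site effects are additive mean shifts on both
imaging features and item propensities, which is the simplest mechanism
that makes site-restricted resampling consequential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, eigh
from sklearn.cluster import KMeans

from .containers import (
    MODALITY_ORDER,
    MultimodalDataset,
    NetworkPartition,
    ParcelSphereCoords,
    SyntheticTruth,
)
from .utils import devectorize_edges, edge_indices, n_edges, rng_from, vectorize_edges

# connectivity backbone scales (entries are correlation-like)
_W_GLOBAL = 0.10  # global positive offset
_W_NET = 0.30  # within-network block height
_W_GRAD = 0.30  # gradient-kernel coefficient (times gradient_strength)
_GRAD_KERNEL_WIDTH = 1.0  # kernel width in SD units of the planted gradient
_EDGE_NOISE_IID_SD = 0.10  # independent per-edge subject noise SD
_EDGE_NOISE_WISHART_SD = 0.04  # structured (node-coupled) noise SD
_EDGE_NOISE_SD = math.hypot(0.10, 0.04)  # total per-edge noise SD
_WISHART_RANK = 20
# maps latent_strength units to the per-side signal coefficient in
# noise-normalized feature space; chosen so a strength-2 component is still
# clearly recoverable against sampling noise at cohort scale (n ~ 2000,
# ~100 parcels), emulating a study whose leading components are significant
_SIGNAL_SCALE = 2.0
_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

_ETHNICITY_LEVELS = ("groupA", "groupB", "groupC", "groupD")
_ETHNICITY_PROBS = (0.5, 0.2, 0.2, 0.1)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    latent_strength gives the per-side signal-to-noise of each planted
    component: a component with strength ``s`` contributes ``s * z_k`` to
    both the (noise-normalized) imaging features and the item propensities,
    against unit-variance feature noise.
    """

    n_subjects: int = 500
    n_sites: int = 5
    n_parcels_cortical: int = 400
    n_parcels_subcortical: int = 19
    n_items: int = 118
    n_latent: int = 3
    latent_strength: tuple[float, ...] = (5.0, 3.0, 2.0)
    item_thresholds: np.ndarray | None = None  # (n_items, 2), strictly increasing
    confound_strength: float = 0.5
    site_effect_strength: float | None = None  # defaults to confound_strength
    spatial_smoothing_fwhm: float = 20.0  # degrees on the sphere
    gradient_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sites", "n_parcels_cortical", "n_parcels_subcortical",
                     "n_items", "n_latent"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        self.latent_strength = tuple(float(s) for s in self.latent_strength)
        if len(self.latent_strength) != self.n_latent:
            raise ValueError("latent_strength must have n_latent entries")
        if any(s < 0 for s in self.latent_strength):
            raise ValueError("latent_strength entries must be nonnegative")
        if self.item_thresholds is None:
            self.item_thresholds = np.tile([0.8, 1.8], (self.n_items, 1)).astype(float)
        self.item_thresholds = np.asarray(self.item_thresholds, dtype=float)
        if self.item_thresholds.shape != (self.n_items, 2):
            raise ValueError("item_thresholds must have shape (n_items, 2)")
        if not np.all(self.item_thresholds[:, 1] > self.item_thresholds[:, 0]):
            raise ValueError("item_thresholds must be strictly increasing per item")
        if self.confound_strength < 0 or self.spatial_smoothing_fwhm < 0 or self.gradient_strength < 0:
            raise ValueError("confound_strength, spatial_smoothing_fwhm, gradient_strength must be >= 0")
        if self.site_effect_strength is None:
            self.site_effect_strength = self.confound_strength
        if self.site_effect_strength < 0:
            raise ValueError("site_effect_strength must be >= 0")
        total_features = 3 * self.n_parcels_cortical + n_edges(
            self.n_parcels_cortical + self.n_parcels_subcortical
        )
        if self.n_latent > min(self.n_items, total_features):
            raise ValueError("n_latent exceeds min(n_items, total imaging features)")

    @property
    def n_parcels_total(self) -> int:
        return self.n_parcels_cortical + self.n_parcels_subcortical

    @property
    def default_n_networks(self) -> int:
        # 17 cortical networks + 1 subcortical group when the parcellation
        # is large enough; degrade gracefully for tiny test parcellations
        return min(18, self.n_parcels_cortical // 2 + 1)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    golden = (1.0 + 5.0**0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def generate_parcellation_assets(
    cfg: SyntheticConfig, n_networks: int | None = None
) -> tuple[NetworkPartition, ParcelSphereCoords]:
    """Bilateral spherical parcel centroids plus a network partition.

    One hemisphere's centroids are a Fibonacci lattice on the unit sphere;
    the other hemisphere mirrors them (x -> -x). Cortical parcels are
    clustered into ``n_networks - 1`` bilateral networks by k-means on the
    left-hemisphere centroids; all subcortical parcels form one group.
    """
    if n_networks is None:
        n_networks = cfg.default_n_networks
    n_left = cfg.n_parcels_cortical - cfg.n_parcels_cortical // 2
    n_right = cfg.n_parcels_cortical - n_left
    if n_networks < 2:
        raise ValueError("n_networks must be >= 2")
    if n_networks - 1 > n_left:
        raise ValueError(
            f"n_networks={n_networks} exceeds what {cfg.n_parcels_cortical} cortical parcels support"
        )
    left = _fibonacci_sphere(n_left)
    right = left[:n_right] * np.array([-1.0, 1.0, 1.0])
    sub = _fibonacci_sphere(cfg.n_parcels_subcortical)

    ids = (
        [f"ctx-lh-{i:03d}" for i in range(n_left)]
        + [f"ctx-rh-{i:03d}" for i in range(n_right)]
        + [f"sub-{i:02d}" for i in range(cfg.n_parcels_subcortical)]
    )
    hemi = ["L"] * n_left + ["R"] * n_right + ["SC"] * cfg.n_parcels_subcortical
    xyz = np.vstack([left, right, sub])
    coords = ParcelSphereCoords(
        pd.DataFrame(
            {"hemisphere": hemi, "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]},
            index=pd.Index(ids, name="parcel_id"),
        )
    )

    km = KMeans(
        n_clusters=n_networks - 1,
        n_init=4,
        random_state=int(cfg.seed) % (2**31 - 1),
    ).fit(left)
    left_labels = [f"net{c + 1:02d}" for c in km.labels_]
    labels = left_labels + left_labels[:n_right] + ["subcortex"] * cfg.n_parcels_subcortical
    partition = NetworkPartition(pd.Series(labels, index=coords.parcel_ids, name="network"))
    return partition, coords


def parcel_geodesic_distances(coords: ParcelSphereCoords) -> np.ndarray:
    """Pairwise geodesic distance (radians) between parcel centroids.

    Each hemisphere lives on its own sphere; cross-hemisphere distances are
    computed after mirroring the right hemisphere onto the left, so homotopic
    parcels are close (bilateral symmetry). Subcortical parcels are treated
    as spatially unrelated to cortex (distance pi).
    """
    hemi = coords.hemisphere.to_numpy()
    xyz = coords.xyz().copy()
    xyz[hemi == "R"] *= np.array([-1.0, 1.0, 1.0])
    d = np.arccos(np.clip(xyz @ xyz.T, -1.0, 1.0))
    cortical = np.isin(hemi, ["L", "R"])
    cross = np.logical_xor.outer(cortical, cortical)
    d[cross] = np.pi
    np.fill_diagonal(d, 0.0)
    return d


def generate_smooth_map(
    coords: ParcelSphereCoords, fwhm: float, seed: int
) -> np.ndarray:
    """Zero-mean Gaussian random field on the sphere sampled at parcel centroids.

    ``fwhm`` is the smoothing kernel full width at half maximum in degrees of
    arc; 0 yields i.i.d. values.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(coords.parcel_ids)
    if fwhm == 0:
        x = rng.standard_normal(n)
    else:
        sigma = math.radians(fwhm) / _FWHM_TO_SIGMA
        d = parcel_geodesic_distances(coords)
        cov = np.exp(-0.5 * (d / sigma) ** 2) + 1e-6 * np.eye(n)
        x = cholesky(cov, lower=True) @ rng.standard_normal(n)
    return x - x.mean()


def _orthonormalize_sym(v: np.ndarray) -> np.ndarray:
    """Loewdin (symmetric) orthonormalization: minimally perturbs near-orthogonal columns."""
    g = v.T @ v
    w, q = eigh(g)
    if w.min() <= 1e-12:
        raise np.linalg.LinAlgError("salience columns are degenerate")
    return v @ (q / np.sqrt(w)) @ q.T


def _fix_column_signs(v: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    return v * signs


def _generate(cfg: SyntheticConfig, return_matrices: bool):
    partition, coords = generate_parcellation_assets(cfg)
    P, Pc = cfg.n_parcels_total, cfg.n_parcels_cortical
    E = n_edges(P)
    n, K = cfg.n_subjects, cfg.n_latent
    strength = np.asarray(cfg.latent_strength)
    beta = cfg.confound_strength
    ctx_coords = coords.cortical()

    # --- planted spatial structure -------------------------------------
    seed_map = rng_from(cfg.seed, 10).integers(0, 2**31 - 1, size=max(64, 48 + 5 * K))
    smap_ctx = lambda i: generate_smooth_map(ctx_coords, cfg.spatial_smoothing_fwhm, int(seed_map[i]))
    smap_all = lambda i: generate_smooth_map(coords, cfg.spatial_smoothing_fwhm, int(seed_map[i]))

    g = smap_all(0)
    g = (g - g.mean()) / g.std()
    g -= g.mean()  # zero mean exactly

    same_net = (
        partition.labels.to_numpy()[:, None] == partition.labels.to_numpy()[None, :]
    ).astype(float)
    dg = g[:, None] - g[None, :]
    C0 = (
        _W_GLOBAL
        + _W_NET * same_net
        + _W_GRAD * cfg.gradient_strength * np.exp(-0.5 * (dg / _GRAD_KERNEL_WIDTH) ** 2)
    )

    # --- planted saliences ----------------------------------------------
    rng_s = rng_from(cfg.seed, 11)
    u_raw = rng_s.standard_normal((cfg.n_items, K))
    u_raw[:, 0] = np.abs(u_raw[:, 0]) + 0.3  # general factor: all items load positively
    U_true, _ = np.linalg.qr(u_raw)
    if U_true[:, 0].sum() < 0:
        U_true[:, 0] *= -1
    U_true = np.column_stack([U_true[:, 0], _fix_column_signs(U_true[:, 1:])]) if K > 1 else U_true

    struct_sal = {m: np.column_stack([smap_ctx(1 + 3 * k + j) for k in range(K)])
                  for j, m in enumerate(("area", "thickness", "volume"))}
    # connectivity salience patterns: smooth symmetric rank-2 edge maps
    edge_base = 1 + 3 * K
    edge_sal = np.empty((E, K))
    for k in range(K):
        m1, m2 = smap_all(edge_base + 2 * k), smap_all(edge_base + 1 + 2 * k)
        S = 0.5 * (np.outer(m1, m2) + np.outer(m2, m1))
        np.fill_diagonal(S, 0.0)
        edge_sal[:, k] = vectorize_edges(S)

    # joint salience matrix in noise-normalized feature space; each modality
    # block scaled to equal norm so all four carry comparable signal
    blocks_raw = [struct_sal["area"], struct_sal["thickness"], struct_sal["volume"], edge_sal]
    scaled = []
    for b in blocks_raw:
        norms = np.linalg.norm(b, axis=0)
        scaled.append(b / norms / 2.0)  # four modalities -> 1/sqrt(4) norm each
    V_true = _orthonormalize_sym(np.vstack(scaled))
    V_true = _fix_column_signs(V_true)
    slices = {}
    offset = 0
    for m, b in zip(MODALITY_ORDER, blocks_raw):
        slices[m] = slice(offset, offset + b.shape[0])
        offset += b.shape[0]

    # --- subjects: sites, covariates, factor scores ----------------------
    rng_c = rng_from(cfg.seed, 12)
    site_idx = rng_c.permutation(np.arange(n) % cfg.n_sites)
    site = np.array([f"site{s:02d}" for s in site_idx])
    age = rng_c.uniform(9.0, 11.0, n)
    sex = rng_c.integers(0, 2, n)
    eth_idx = rng_c.choice(len(_ETHNICITY_LEVELS), size=n, p=_ETHNICITY_PROBS)
    mean_fd = np.exp(rng_c.normal(-1.6, 0.5, n))
    mean_dvars = np.exp(rng_c.normal(3.0, 0.3, n))
    icv_z = rng_c.standard_normal(n)
    icv = 1450.0 + 110.0 * icv_z
    ta_z = 0.6 * icv_z + 0.8 * rng_c.standard_normal(n)
    total_area = 1800.0 + 150.0 * ta_z
    Z = rng_c.standard_normal((n, K))

    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": np.where(sex == 1, "M", "F"),
            "site": site,
            "ethnicity": np.array(_ETHNICITY_LEVELS)[eth_idx],
            "mean_fd": mean_fd,
            "mean_dvars": mean_dvars,
            "icv": icv,
            "total_area": total_area,
        },
        index=pd.Index([f"sub{i:05d}" for i in range(n)], name="subject_id"),
    )

    def std(x):
        return (x - x.mean()) / x.std()

    age_z = std(age)
    age2_z = std(age**2)
    sex_c = sex - sex.mean()
    fd_z = std(np.log(mean_fd))
    dv_z = std(np.log(mean_dvars))

    # --- structural modalities -------------------------------------------
    rng_x = rng_from(cfg.seed, 13)
    beta_site = cfg.site_effect_strength
    conf_base = 1 + 5 * K
    conf_maps = {m: np.column_stack([smap_ctx(conf_base + 4 * j + t) for t in range(4)])
                 for j, m in enumerate(("area", "thickness", "volume"))}
    site_shift = {m: beta_site * rng_x.standard_normal((cfg.n_sites, Pc))
                  for m in ("area", "thickness", "volume")}
    eth_shift = {m: 0.5 * beta * rng_x.standard_normal((len(_ETHNICITY_LEVELS), Pc))
                 for m in ("area", "thickness", "volume")}

    modality_blocks: dict[str, pd.DataFrame] = {}
    signal = Z * (_SIGNAL_SCALE * strength)  # n x K
    for j, m in enumerate(("area", "thickness", "volume")):
        X = signal @ V_true[slices[m]].T
        w = conf_maps[m]
        X += beta * (np.outer(age_z, w[:, 0]) + 0.5 * np.outer(age2_z, w[:, 1]) + np.outer(sex_c, w[:, 2]))
        anat = ta_z if m == "area" else icv_z
        X += beta * np.outer(anat, w[:, 3])
        X += site_shift[m][site_idx] + eth_shift[m][eth_idx]
        X += rng_x.standard_normal((n, Pc))
        ctx_ids = coords.parcel_ids[: Pc]
        modality_blocks[m] = pd.DataFrame(
            X, index=covariates.index, columns=[f"{m}:{p}" for p in ctx_ids]
        )

    # --- connectivity ------------------------------------------------------
    rng_e = rng_from(cfg.seed, 14)

    def edge_pattern():
        m1, m2 = rng_e.standard_normal(P), rng_e.standard_normal(P)
        S = 0.5 * (np.outer(m1, m2) + np.outer(m2, m1))
        np.fill_diagonal(S, 0.0)
        v = vectorize_edges(S)
        return v / np.linalg.norm(v)

    conf_edge = {c: edge_pattern() for c in ("age", "fd", "dvars")}
    site_edge = np.stack([edge_pattern() for _ in range(cfg.n_sites)])

    rng_w = rng_from(cfg.seed, 15)
    delta_edges = _EDGE_NOISE_SD * (
        signal @ V_true[slices["rsfc"]].T
        + beta * (np.outer(age_z, conf_edge["age"]) + np.outer(fd_z, conf_edge["fd"])
                  + np.outer(dv_z, conf_edge["dvars"]))
        + beta_site * site_edge[site_idx]
    )
    delta_edges += _EDGE_NOISE_IID_SD * rng_w.standard_normal((n, E))

    base_edges = vectorize_edges(C0)
    ei, ej = edge_indices(P)
    edges = np.empty((n, E))
    wish_scale = _EDGE_NOISE_WISHART_SD / math.sqrt(_WISHART_RANK)
    mats = np.empty((n, P, P)) if return_matrices else None
    for i in range(n):
        G = rng_w.standard_normal((P, _WISHART_RANK))
        W = wish_scale * (G @ G.T)
        edges[i] = base_edges + W[ei, ej] + delta_edges[i]
        if return_matrices:
            rho = math.sqrt(2.0) * np.linalg.norm(delta_edges[i])
            D = devectorize_edges(delta_edges[i], P)
            mats[i] = C0 + W + D + rho * np.eye(P)

    # item propensities -> ordinal responses ------------------------------
    rng_y = rng_from(cfg.seed, 16)
    w_age_i = rng_y.standard_normal(cfg.n_items)
    w_sex_i = rng_y.standard_normal(cfg.n_items)
    site_shift_i = beta_site * rng_y.standard_normal((cfg.n_sites, cfg.n_items))
    eth_shift_i = 0.5 * beta * rng_y.standard_normal((len(_ETHNICITY_LEVELS), cfg.n_items))
    T = (
        signal @ U_true.T
        + beta * (0.5 * np.outer(age_z, w_age_i) + 0.5 * np.outer(sex_c, w_sex_i))
        + site_shift_i[site_idx]
        + eth_shift_i[eth_idx]
        + rng_y.standard_normal((n, cfg.n_items))
    )
    Y = (T > cfg.item_thresholds[:, 0]).astype(int) + (T > cfg.item_thresholds[:, 1]).astype(int)

    behavior = pd.DataFrame(
        Y, index=covariates.index, columns=[f"item:{k:03d}" for k in range(cfg.n_items)]
    )
    modality_blocks["rsfc"] = pd.DataFrame(
        edges, index=covariates.index, columns=[f"rsfc:e{k:06d}" for k in range(E)]
    )
    modality_blocks = {m: modality_blocks[m] for m in MODALITY_ORDER}

    dataset = MultimodalDataset(modality_blocks=modality_blocks, behavior=behavior,
                                covariates=covariates)
    feature_labels = [c for m in MODALITY_ORDER for c in modality_blocks[m].columns]
    truth = SyntheticTruth(
        behavior_saliences=U_true,
        imaging_saliences=V_true,
        subject_scores=Z,
        planted_gradient=g,
        site_assignment=site,
        imaging_feature_labels=feature_labels,
    )
    return dataset, truth, mats


def generate_dataset(cfg: SyntheticConfig) -> tuple[MultimodalDataset, SyntheticTruth]:
    """Generate one synthetic cohort; bit-reproducible from ``cfg.seed``."""
    dataset, truth, _ = _generate(cfg, return_matrices=False)
    return dataset, truth


def generate_connectivity_stack(cfg: SyntheticConfig) -> np.ndarray:
    """Per-subject connectivity matrices (subjects × P × P), as built internally.

    The off-diagonal entries match the ``rsfc`` block of
    :func:`generate_dataset` for the same config; intended for validating
    positive semi-definiteness on small problems.
    """
    _, _, mats = _generate(cfg, return_matrices=True)
    return mats
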