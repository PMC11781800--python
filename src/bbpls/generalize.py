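"""Out-of-sample weight transfer, replication analysis, and post hoc associations.

Within-sample latent-component statistics are optimistic; the honest test
of generalizability freezes every parameter estimated in the discovery
cohort (PCA coefficients, normalization statistics, singular vectors) and
applies it unchanged to replication data. Held-out modalities (tract
metrics, task-state connectivity) are related to the existing composite
scores by simple correlation with site-restricted bootstrap stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NetworkPartition
from .inference import fdr_bh, permute_within_site
from .pls import LatentComponentResult, pls_decompose
from .reduction import ReductionModel, transform_reduction
from .utils import column_correlations

log = logging.getLogger(__name__)


@dataclass
class TransferModel:
    """Everything fitted on discovery subjects, frozen for out-of-sample use."""

    reduction: ReductionModel
    x_mean: np.ndarray  # discovery means of reduced imaging columns
    x_sd: np.ndarray
    y_mean: np.ndarray  # discovery means of behavior items
    y_sd: np.ndarray
    U: np.ndarray
    V: np.ndarray
    singular_values: np.ndarray
    item_labels: list[str] = field(default_factory=list)


@dataclass
class TransferScores:
    LX: np.ndarray
    LY: np.ndarray
    lc_correlations: np.ndarray
    behavior_loadings: np.ndarray  # corr(normalized replication items, LY)
    imaging_loadings: np.ndarray  # corr(normalized replication X_pca, LX)
    dropped_items: list[str] = field(default_factory=list)


def fit_transfer(
    reduction: ReductionModel,
    x_pca_discovery: np.ndarray,
    y_discovery: pd.DataFrame | np.ndarray,
) -> TransferModel:
    """Freeze discovery PCA scores' statistics and PLS weights for transfer."""
    item_labels = list(y_discovery.columns) if isinstance(y_discovery, pd.DataFrame) else []
    X = np.asarray(x_pca_discovery, float)
    Y = np.asarray(y_discovery, float)
    res = pls_decompose(X, Y)
    return TransferModel(
        reduction=reduction,
        x_mean=X.mean(0),
        x_sd=X.std(0, ddof=1),
        y_mean=Y.mean(0),
        y_sd=Y.std(0, ddof=1),
        U=res.U,
        V=res.V,
        singular_values=res.singular_values,
        item_labels=item_labels,
    )


def _normalized_transfer_inputs(model, replication_blocks, replication_behavior):
    Xr = transform_reduction(model.reduction, replication_blocks).to_numpy()
    Yr = np.asarray(replication_behavior, float)
    Xn = (Xr - model.x_mean) / model.x_sd
    # items that became invariant in the replication arm are removed from
    # both Y and U, with U columns renormalized to unit length
    invariant = np.where(Yr.std(0) == 0)[0]
    U = model.U
    if invariant.size:
        names = ([model.item_labels[i] for i in invariant]
                 if model.item_labels else invariant.tolist())
        log.info("dropping %d items invariant in replication: %s", invariant.size, names)
        keep = np.setdiff1d(np.arange(Yr.shape[1]), invariant)
        Yr = Yr[:, keep]
        U = model.U[keep]
        U = U / np.linalg.norm(U, axis=0)
        Yn = (Yr - model.y_mean[keep]) / model.y_sd[keep]
        dropped = names
    else:
        Yn = (Yr - model.y_mean) / model.y_sd
        dropped = []
    return Xn, Yn, U, dropped


def transfer_scores(
    model: TransferModel,
    replication_blocks: dict[str, pd.DataFrame],
    replication_behavior: pd.DataFrame | np.ndarray,
) -> TransferScores:
    """Cross-validated composite scores and out-of-sample loadings.

    Replication features are projected with discovery PCA coefficients,
    normalized with discovery means/SDs, and multiplied by the discovery
    singular vectors: LX = X~ V, LY = Y~ U. Out-of-sample loadings are
    correlations of these scores with the normalized replication data.
    """
    Xn, Yn, U, dropped = _normalized_transfer_inputs(
        model, replication_blocks, replication_behavior
    )
    LX = Xn @ model.V
    LY = Yn @ U
    K = min(LX.shape[1], LY.shape[1])
    r = np.array([column_correlations(LX[:, k], LY[:, k])[0, 0] for k in range(K)])
    return TransferScores(
        LX=LX,
        LY=LY,
        lc_correlations=r,
        behavior_loadings=column_correlations(Yn, LY),
        imaging_loadings=column_correlations(Xn, LX),
        dropped_items=dropped,
    )


def transfer_significance(
    model: TransferModel,
    replication_blocks: dict[str, pd.DataFrame],
    replication_behavior: pd.DataFrame | np.ndarray,
    site_labels: np.ndarray,
    n_perm: int = 10_000,
    k_test: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Site-restricted permutation p-values for cross-validated correlations.

    Replication behavior rows are permuted within site; the cross-validated
    per-component correlation is the test statistic. Returns (observed r,
    add-one p, BH-FDR adjusted p) for the first ``k_test`` components.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xn, Yn, U, _ = _normalized_transfer_inputs(model, replication_blocks, replication_behavior)
    LX = Xn @ model.V
    K = min(k_test, model.V.shape[1], U.shape[1])
    LX = LX[:, :K]

    def lc_corr(Ymat):
        LY = Ymat @ U[:, :K]
        return np.array([column_correlations(LX[:, k], LY[:, k])[0, 0] for k in range(K)])

    observed = lc_corr(Yn)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, K))
    for b in range(n_perm):
        null[b] = lc_corr(Yn[permute_within_site(site_labels, rng)])
    p = (1 + (null >= observed).sum(0)) / (1 + n_perm)
    _, q = fdr_bh(p)
    return observed, p, q


def compare_loadings(
    discovery: LatentComponentResult,
    replication: LatentComponentResult,
    loading_blocks: tuple[dict[str, np.ndarray], dict[str, np.ndarray]] | None = None,
    k: int | None = None,
    spins: np.ndarray | None = None,
    cortical_mask_per_block: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Cross-sample correlations of loadings after an independent re-analysis.

    Correlates discovery against replication loadings per component: item
    loadings always, plus any per-modality feature-space loading maps
    supplied as ``(discovery_maps, replication_maps)``. Parcel maps get
    spin-permutation p-values when ``spins`` is given (with an optional
    cortical mask per block); item loadings get a parametric correlation p.
    """
    if k is None:
        k = min(discovery.n_components, replication.n_components)
    rows = []
    for comp in range(k):
        a = discovery.behavior_loadings[:, comp]
        b = replication.behavior_loadings[:, comp]
        r, p = stats.pearsonr(a, b)
        rows.append(("behavior", comp + 1, r, p))
    if loading_blocks is not None:
        disc_maps, repl_maps = loading_blocks
        for name in disc_maps:
            for comp in range(k):
                a = np.asarray(disc_maps[name])[:, comp]
                b = np.asarray(repl_maps[name])[:, comp]
                if spins is not None:
                    mask = (cortical_mask_per_block or {}).get(name)
                    ac = a if mask is None else a[mask]
                    bc = b if mask is None else b[mask]
                    from .spatial import spin_correlation

                    res = spin_correlation(ac, bc, spins)
                    rows.append((name, comp + 1, res.observed_r, res.p_spin))
                else:
                    r, p = stats.pearsonr(a, b)
                    rows.append((name, comp + 1, r, p))
    return pd.DataFrame(rows, columns=["block", "component", "r", "p"])


def heldout_association(
    heldout_block: pd.DataFrame,
    composite_scores: pd.DataFrame,
    site_labels: pd.Series,
    n_boot: int = 1000,
    partition: NetworkPartition | None = None,
    parcel_order: pd.Index | None = None,
    seed: int = 0,
    q: float = 0.05,
):
    """Relate a held-out modality to existing composite scores.

    Works on the subjects shared between the held-out table and the scored
    sample; composite scores are reused, not re-derived. Per-feature
    correlations with each composite get site-restricted bootstrap SDs and
    Z-scores; edge features are block-averaged over the partition first.
    Returns (observed loadings, BootstrapResult).
    """
    overlap = heldout_block.index.intersection(composite_scores.index)
    if len(overlap) == 0:
        raise ValueError("no overlapping subjects between held-out block and scores")
    Xh = heldout_block.loc[overlap].to_numpy(float)
    S = composite_scores.loc[overlap].to_numpy(float)
    sites = np.asarray(site_labels.loc[overlap])

    from .inference import bootstrap_within_site
    from .utils import devectorize_edges
    from .inference import block_average_edges, _unique_blocks

    def loadings_of(idx=None):
        xi = Xh if idx is None else Xh[idx]
        si = S if idx is None else S[idx]
        load = column_correlations(xi, si)
        if partition is not None:
            P = len(partition.labels)
            load = np.column_stack([
                _unique_blocks(block_average_edges(devectorize_edges(load[:, k], P),
                                                   partition, parcel_order))
                for k in range(load.shape[1])
            ])
        return load

    observed = loadings_of()
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot,) + observed.shape)
    for b in range(n_boot):
        draws[b] = loadings_of(bootstrap_within_site(sites, rng))
    sd = draws.std(0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, observed / np.where(sd > 0, sd, 1.0),
                     np.inf * np.sign(observed))
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.where(np.isnan(observed), np.nan, p)
    flat = p.ravel()
    valid = ~np.isnan(flat)
    mask = np.zeros(flat.shape, dtype=bool)
    if valid.any():
        mask[valid], _ = fdr_bh(flat[valid], q)
    return observed, {
        "sd": sd,
        "z": z,
        "p": p,
        "fdr_mask": mask.reshape(observed.shape),
        "ci_low": np.percentile(draws, 2.5, axis=0),
        "ci_high": np.percentile(draws, 97.5, axis=0),
        "n_overlap": len(overlap),
    }


def demographic_posthoc(
    composite_scores: pd.DataFrame,
    covariates: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Sex differences (Welch t) and age/age^2 correlations per composite score.

    All tests are collected into one BH-FDR family at level ``q``. If only
    one sex is present the t-test is skipped with a flag row.
    """
    rows = []
    sex = covariates["sex"].astype(str)
    age = covariates["age"].to_numpy(float)
    age2 = age**2
    groups = pd.unique(sex)
    for col in composite_scores.columns:
        s = composite_scores[col].to_numpy(float)
        if len(groups) >= 2:
            a = s[(sex == groups[0]).to_numpy()]
            b = s[(sex == groups[1]).to_numpy()]
            tstat, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append((col, "sex_t", float(tstat), float(p), ""))
        else:
            rows.append((col, "sex_t", np.nan, np.nan, "only one sex present; skipped"))
        for name, x in (("age_r", age), ("age2_r", age2)):
            r, p = stats.pearsonr(s, x)
            rows.append((col, name, float(r), float(p), ""))
    table = pd.DataFrame(rows, columns=["score", "test", "statistic", "p", "flag"])
    valid = table["p"].notna().to_numpy()
    adj = np.full(len(table), np.nan)
    rej = np.zeros(len(table), dtype=bool)
    if valid.any():
        rej[valid], adj[valid] = fdr_bh(table.loc[valid, "p"].to_numpy(), q)
    table["q"] = adj
    table["significant"] = rej
    return table
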