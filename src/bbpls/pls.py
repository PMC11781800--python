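"""PLS correlation: SVD of the cross-covariance between two z-scored blocks.

Given imaging scores ``X`` (subjects × reduced dimensions) and behavior
``Y`` (subjects × items), both z-scored across subjects, the method computes

    R = Y' X,   R = U S V'

Latent component k is the singular-vector pair (u_k, v_k) with singular
value s_k. Composite scores are the projections ``LX = X V`` and
``LY = Y U``; loadings are Pearson correlations of original variables with
the matching composite score; the covariance explained by component k is
``s_k^2 / sum_j s_j^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reduction import ReducedMatrix
from .utils import column_correlations, zscore


@dataclass
class LatentComponentResult:
    U: np.ndarray  # items × K behavior saliences
    V: np.ndarray  # reduced imaging dims × K imaging saliences
    singular_values: np.ndarray  # K, nonincreasing
    LX: np.ndarray  # subjects × K imaging composite scores
    LY: np.ndarray  # subjects × K behavior composite scores
    covariance_explained: np.ndarray
    behavior_loadings: np.ndarray  # items × K, corr(item, LY_k)
    lc_correlations: np.ndarray  # corr(LX_k, LY_k)
    item_labels: list[str] = field(default_factory=list)
    x_labels: list[str] = field(default_factory=list)
    imaging_loadings: dict[str, np.ndarray] = field(default_factory=dict)
    degenerate_flags: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.singular_values)


def covariance_explained(singular_values: np.ndarray) -> np.ndarray:
    """Fraction of imaging-behavior covariance carried by each component."""
    s = np.asarray(singular_values, dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be nonnegative")
    total = (s**2).sum()
    if total == 0:
        raise ValueError("all singular values are zero")
    return s**2 / total


def pls_decompose(
    X: ReducedMatrix | pd.DataFrame | np.ndarray,
    Y: pd.DataFrame | np.ndarray,
) -> LatentComponentResult:
    """Full PLS correlation of imaging scores against behavior items.

    Both blocks are z-scored (sample SD) across subjects; K = min(items,
    imaging dimensions) components are returned. Per-component sign is fixed
    so the behavior loading of largest magnitude is positive, making symptom
    components read out with a positive general direction.
    """
    x_labels = []
    if isinstance(X, ReducedMatrix):
        x_labels = list(X.scores.columns)
        X = X.scores
    if isinstance(X, pd.DataFrame):
        x_labels = x_labels or list(X.columns)
        X = X.to_numpy(float)
    item_labels = list(Y.columns) if isinstance(Y, pd.DataFrame) else []
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must share subjects")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("X and Y must be finite")

    Xz = zscore(X)
    Yz = zscore(Y)
    R = Yz.T @ Xz
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    LX = Xz @ V
    LY = Yz @ U

    behavior_loadings = _composite_loadings(Y, LY)
    # sign convention: largest-|behavior-loading| item positive, per component
    flags: list[str] = []
    for k in range(len(s)):
        col = behavior_loadings[:, k]
        if not col.any():
            flags.append(f"component {k + 1}: degenerate (zero-variance composite)")
            continue
        if col[np.argmax(np.abs(col))] < 0:
            U[:, k] *= -1
            V[:, k] *= -1
            LX[:, k] *= -1
            LY[:, k] *= -1
            behavior_loadings[:, k] *= -1

    lc_corr = np.array(
        [column_correlations(LX[:, k], LY[:, k])[0, 0] for k in range(len(s))]
    )
    return LatentComponentResult(
        U=U,
        V=V,
        singular_values=s,
        LX=LX,
        LY=LY,
        covariance_explained=covariance_explained(s),
        behavior_loadings=behavior_loadings,
        lc_correlations=lc_corr,
        item_labels=item_labels,
        x_labels=x_labels,
        degenerate_flags=flags,
    )


def _composite_loadings(data: np.ndarray, composites: np.ndarray) -> np.ndarray:
    """corr(variable, composite_k) for every variable/component pair."""
    return column_correlations(data, composites)


def project_loadings_back(
    result: LatentComponentResult,
    blocks: dict[str, pd.DataFrame | np.ndarray],
    composite: str = "LX",
) -> dict[str, np.ndarray]:
    """Loadings of original features (parcel metrics, edges, items) on each LC.

    Each feature's loading is its Pearson correlation with the chosen
    composite score across subjects, giving interpretable maps in the
    original feature space. Stored on ``result.imaging_loadings`` for
    imaging blocks.
    """
    scores = getattr(result, composite)
    out: dict[str, np.ndarray] = {}
    for name, block in blocks.items():
        x = np.asarray(block, dtype=float)
        if x.shape[0] != scores.shape[0]:
            raise ValueError(f"block {name!r} does not share subjects with composite scores")
        out[name] = _composite_loadings(x, scores)
    if composite == "LX":
        result.imaging_loadings.update(out)
    return out


def modality_contribution(
    result: LatentComponentResult,
    X: ReducedMatrix,
    modality: str,
) -> np.ndarray:
    """Correlation between full and single-modality imaging composite scores.

    The modality-specific composite is built by zeroing every salience row
    outside the modality's column range; a correlation of 1 means the
    component is carried entirely by that modality.
    """
    cols = X.columns_for(modality)
    V_mod = np.zeros_like(result.V)
    V_mod[cols] = result.V[cols]
    Xz = zscore(X.to_numpy())
    LX_mod = Xz @ V_mod
    K = result.n_components
    out = np.empty(K)
    for k in range(K):
        if LX_mod[:, k].std() == 0:
            result.degenerate_flags.append(
                f"modality {modality!r} component {k + 1}: zero-variance modality composite"
            )
            out[k] = 0.0
        else:
            out[k] = column_correlations(result.LX[:, k], LX_mod[:, k])[0, 0]
    return out
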