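"""Confound residualization, item filtering, and matched discovery/replication splits."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: confounds regressed from every modality and from behavior
BASE_TERMS = ("age", "age2", "sex", "site", "ethnicity")

_CATEGORICAL = {"sex", "site", "ethnicity"}


def modality_covariates(modality: str, include_motion_for_dwi: bool = False) -> list[str]:
    """Confound term list for one data modality.

    Morphometry gets an anatomical normalizer on top of the demographic
    base terms (total surface area for area; intracranial volume for
    thickness and volume); connectivity additionally gets head-motion
    (mean FD) and image-intensity (mean DVARS) terms.
    """
    base = list(BASE_TERMS)
    if modality == "area":
        return base + ["total_area"]
    if modality in ("thickness", "volume"):
        return base + ["icv"]
    if modality == "rsfc" or modality.startswith("taskfc"):
        return base + ["mean_fd", "mean_dvars"]
    if modality in ("fa", "md"):
        return base + (["mean_fd"] if include_motion_for_dwi else [])
    if modality == "behavior":
        return base
    raise ValueError(f"unknown modality {modality!r}")


def build_design(covariates: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Intercept + dummy-coded design matrix for the requested terms.

    ``age2`` is derived as age squared; categorical terms are dummy-coded
    with a first-level reference. Raises on rank deficiency, naming the
    collinear columns.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(covariates))}
    for t in terms:
        if t == "age2":
            cols["age2"] = covariates["age"].to_numpy(float) ** 2
        elif t in _CATEGORICAL or covariates[t].dtype == object:
            levels = pd.unique(covariates[t])
            for lev in levels[1:]:  # first level is the reference
                cols[f"{t}[{lev}]"] = (covariates[t] == lev).to_numpy(float)
        else:
            cols[t] = covariates[t].to_numpy(float)
    design = pd.DataFrame(cols, index=covariates.index)
    mat = design.to_numpy(float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # locate columns whose R-diagonal collapses
        _, r = np.linalg.qr(mat)
        bad = [design.columns[i] for i in range(mat.shape[1])
               if abs(r[i, i]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    return design


def residualize(
    block: pd.DataFrame | np.ndarray,
    covariates: pd.DataFrame,
    terms: list[str],
) -> pd.DataFrame | np.ndarray:
    """Per-feature OLS residuals after regressing out the requested confounds.

    With ``terms=[]`` this reduces to column centering (intercept-only fit).
    Residuals are exactly uncorrelated with every design column.
    """
    design = build_design(covariates, list(terms)).to_numpy(float)
    x = np.asarray(block, dtype=float)
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coef
    if isinstance(block, pd.DataFrame):
        return pd.DataFrame(resid, index=block.index, columns=block.columns)
    return resid


def residualize_dataset(dataset, include_motion_for_dwi: bool = False):
    """Residualize every modality block and the behavior matrix in place-free style.

    Returns (blocks, behavior) with each table replaced by its confound
    residuals, using the modality-appropriate term list.
    """
    blocks = {
        m: residualize(b, dataset.covariates, modality_covariates(m, include_motion_for_dwi))
        for m, b in dataset.modality_blocks.items()
    }
    behavior = residualize(
        dataset.behavior.astype(float), dataset.covariates, modality_covariates("behavior")
    )
    return blocks, behavior


def drop_invariant_items(
    behavior: pd.DataFrame, idx=None
) -> tuple[pd.DataFrame, list[str]]:
    """Remove items with zero variance within the given subject subset.

    Mirrors the handling of questionnaire items every subject answered
    identically (e.g. an item scored 0 by all discovery-sample children).
    """
    sub = behavior if idx is None else behavior.iloc[np.asarray(idx)]
    variances = sub.to_numpy(float).var(axis=0)
    dropped = [c for c, v in zip(behavior.columns, variances) if v == 0]
    if len(dropped) == behavior.shape[1]:
        raise ValueError("all items are invariant in the requested subset")
    if dropped:
        log.info("dropping %d invariant items: %s", len(dropped), dropped)
    return behavior.drop(columns=dropped), dropped


def overall_psychopathology(behavior: pd.DataFrame) -> pd.Series:
    """First principal-component score of the centered item matrix.

    The sign is fixed so the score correlates positively with the item
    total, making it interpretable as a general symptom-load dimension.
    """
    x = behavior.to_numpy(float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 items")
    xc = x - x.mean(0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    score = xc @ vt[0]
    total = x.sum(1)
    if np.corrcoef(score, total)[0, 1] < 0:
        score = -score
    return pd.Series(score, index=behavior.index, name="overall_psychopathology")


@dataclass
class SplitResult:
    discovery_idx: np.ndarray  # positional indices
    replication_idx: np.ndarray
    balance_report: pd.DataFrame


def _quartile_bin(x: pd.Series) -> pd.Series:
    try:
        return pd.qcut(x, 4, labels=False, duplicates="drop").astype(str)
    except ValueError:
        return pd.Series(["q0"] * len(x), index=x.index)


def matched_split(
    covariates: pd.DataFrame,
    overall_psy: pd.Series,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> SplitResult:
    """Stratified random split matched on site, sex, ethnicity, age, and symptom load.

    Subjects are stratified by site × sex × ethnicity × age quartile ×
    symptom-score quartile; within each cell, ``round(fraction * n)``
    subjects go to discovery. Strata with a single subject are merged
    upward (coarser key) rather than failing.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    keys = pd.DataFrame(
        {
            "site": covariates["site"].astype(str),
            "sex": covariates["sex"].astype(str),
            "ethnicity": covariates["ethnicity"].astype(str)
            if "ethnicity" in covariates
            else "all",
            "age_q": _quartile_bin(covariates["age"]),
            "psy_q": _quartile_bin(overall_psy),
        }
    )
    # progressively coarsen singleton strata
    for depth in range(keys.shape[1], 0, -1):
        strat = keys.iloc[:, :depth].agg("|".join, axis=1)
        sizes = strat.value_counts()
        if depth == 1 or (sizes.min() >= 2):
            if (sizes < 2).any():
                log.info("merged %d singleton strata upward", int((sizes < 2).sum()))
            break
        singletons = strat.isin(sizes.index[sizes < 2])
        if singletons.any():
            log.info("coarsening %d subjects out of singleton strata", int(singletons.sum()))
            keys.iloc[singletons.to_numpy(), depth - 1] = "merged"

    strat = keys.agg("|".join, axis=1)
    disc = np.zeros(len(covariates), dtype=bool)
    for _, members in strat.groupby(strat).groups.items():
        pos = covariates.index.get_indexer(members)
        pos = pos[rng.permutation(len(pos))]
        n_disc = int(round(fraction * len(pos)))
        disc[pos[:n_disc]] = True

    disc_idx = np.where(disc)[0]
    repl_idx = np.where(~disc)[0]
    balance = _balance_report(covariates, overall_psy, disc_idx, repl_idx)
    return SplitResult(disc_idx, repl_idx, balance)


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.sqrt(0.5 * (a.var(ddof=1) + b.var(ddof=1)))
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0


def _balance_report(covariates, overall_psy, disc_idx, repl_idx) -> pd.DataFrame:
    rows = []
    numeric = {"age": covariates["age"].to_numpy(float),
               "overall_psychopathology": overall_psy.to_numpy(float)}
    for name, x in numeric.items():
        rows.append((name, x[disc_idx].mean(), x[repl_idx].mean(),
                     _smd(x[disc_idx], x[repl_idx])))
    for cat in ("sex", "site", "ethnicity"):
        if cat not in covariates:
            continue
        col = covariates[cat].astype(str)
        for lev in pd.unique(col):
            x = (col == lev).to_numpy(float)
            rows.append((f"{cat}[{lev}]", x[disc_idx].mean(), x[repl_idx].mean(),
                         _smd(x[disc_idx], x[repl_idx])))
    return pd.DataFrame(rows, columns=["variable", "discovery_mean", "replication_mean", "smd"])
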