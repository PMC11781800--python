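"""Per-modality PCA with variance-threshold retention and block concatenation.

Each imaging modality is reduced separately so that the block with the most
features (connectivity edges) cannot overpower the others in the subsequent
cross-covariance decomposition; components explaining a fixed fraction of
within-modality variance are retained and concatenated in a canonical
modality order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MODALITY_ORDER


@dataclass
class PCAEntry:
    mean: np.ndarray  # feature means
    sd: np.ndarray | None  # feature SDs when standardization is enabled
    loadings: np.ndarray  # features × retained components
    explained_variance_ratio: np.ndarray  # over the full spectrum
    n_retained: int
    feature_labels: list[str] = field(default_factory=list)


@dataclass
class ReductionModel:
    entries: dict[str, PCAEntry]
    order: list[str]
    variance_threshold: float
    standardize: bool = False

    @property
    def retained_counts(self) -> dict[str, int]:
        return {m: self.entries[m].n_retained for m in self.order}

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "order": self.order,
            "variance_threshold": self.variance_threshold,
            "standardize": self.standardize,
            "entries": {},
        }
        for m, e in self.entries.items():
            meta["entries"][m] = {
                "n_retained": e.n_retained,
                "feature_labels": e.feature_labels,
            }
            np.savez(
                directory / f"pca_{m}.npz",
                mean=e.mean,
                sd=e.sd if e.sd is not None else np.array([]),
                loadings=e.loadings,
                explained_variance_ratio=e.explained_variance_ratio,
            )
        (directory / "reduction.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ReductionModel":
        directory = Path(directory)
        meta = json.loads((directory / "reduction.json").read_text())
        entries = {}
        for m, em in meta["entries"].items():
            z = np.load(directory / f"pca_{m}.npz")
            entries[m] = PCAEntry(
                mean=z["mean"],
                sd=z["sd"] if z["sd"].size else None,
                loadings=z["loadings"],
                explained_variance_ratio=z["explained_variance_ratio"],
                n_retained=em["n_retained"],
                feature_labels=em["feature_labels"],
            )
        return cls(entries=entries, order=meta["order"],
                   variance_threshold=meta["variance_threshold"],
                   standardize=meta["standardize"])


@dataclass
class ReducedMatrix:
    """Subjects × retained-components scores with ``modality:PCk`` labels."""

    scores: pd.DataFrame

    @property
    def modalities(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.scores.columns:
            seen.setdefault(c.split(":", 1)[0], None)
        return list(seen)

    def columns_for(self, modality: str) -> np.ndarray:
        mask = np.array([c.split(":", 1)[0] == modality for c in self.scores.columns])
        if not mask.any():
            raise ValueError(f"modality {modality!r} not present")
        return np.where(mask)[0]

    def to_numpy(self) -> np.ndarray:
        return self.scores.to_numpy(float)


def fit_pca(
    block: pd.DataFrame | np.ndarray,
    variance_threshold: float,
    standardize: bool = False,
) -> PCAEntry:
    """PCA of a column-centered block, retaining the smallest number of
    components whose cumulative explained-variance ratio reaches the threshold.

    Computed by SVD of the centered data. Per-component sign is fixed so the
    largest-magnitude feature loading is positive.
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    labels = list(block.columns) if isinstance(block, pd.DataFrame) else []
    x = np.asarray(block, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need more than one subject")
    mean = x.mean(0)
    xc = x - mean
    sd = None
    if standardize:
        sd = xc.std(0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance feature under standardization")
        xc = xc / sd
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("block has zero variance")
    evr = var / total
    k = int(np.searchsorted(np.cumsum(evr), variance_threshold - 1e-12) + 1)
    k = min(k, len(evr))
    loadings = vt[:k].T
    # deterministic sign: largest-|loading| feature positive
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(k)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    return PCAEntry(mean=mean, sd=sd, loadings=loadings,
                    explained_variance_ratio=evr, n_retained=k,
                    feature_labels=labels)


def transform(entry: PCAEntry, block: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Project (possibly unseen) data onto a fitted PCA basis; no re-fitting."""
    x = np.asarray(block, dtype=float)
    if x.shape[1] != entry.mean.shape[0]:
        raise ValueError(
            f"feature count {x.shape[1]} does not match fitted model ({entry.mean.shape[0]})"
        )
    xc = x - entry.mean
    if entry.sd is not None:
        xc = xc / entry.sd
    return xc @ entry.loadings


def fit_reduction(
    blocks: dict[str, pd.DataFrame],
    variance_threshold: float = 0.5,
    standardize: bool = False,
    order: tuple[str, ...] | None = None,
) -> tuple[ReductionModel, ReducedMatrix]:
    """Fit per-modality PCA and concatenate retained scores."""
    if order is None:
        order = [m for m in MODALITY_ORDER if m in blocks] + [
            m for m in blocks if m not in MODALITY_ORDER
        ]
    model = ReductionModel(
        entries={m: fit_pca(blocks[m], variance_threshold, standardize) for m in order},
        order=list(order),
        variance_threshold=variance_threshold,
        standardize=standardize,
    )
    return model, concatenate(model, {m: transform(model.entries[m], blocks[m]) for m in order},
                              index=next(iter(blocks.values())).index)


def concatenate(
    model: ReductionModel,
    score_blocks: dict[str, np.ndarray],
    index: pd.Index,
) -> ReducedMatrix:
    """Horizontal concatenation of per-modality scores in the model's order."""
    pieces, labels = [], []
    n = len(index)
    for m in model.order:
        s = np.asarray(score_blocks[m])
        if s.shape[0] != n:
            raise ValueError(f"block {m!r} has a different number of subjects ({s.shape[0]} vs {n})")
        pieces.append(s)
        labels.extend(f"{m}:PC{j + 1}" for j in range(s.shape[1]))
    return ReducedMatrix(pd.DataFrame(np.hstack(pieces), index=index, columns=labels))


def transform_reduction(model: ReductionModel, blocks: dict[str, pd.DataFrame],
                        index: pd.Index | None = None) -> ReducedMatrix:
    """Apply a fitted reduction to new data (discovery weights on replication data)."""
    if index is None:
        first = next(iter(blocks.values()))
        index = first.index if isinstance(first, pd.DataFrame) else pd.RangeIndex(len(first))
    return concatenate(model, {m: transform(model.entries[m], blocks[m]) for m in model.order},
                       index=index)
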