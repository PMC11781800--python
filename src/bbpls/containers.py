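"""Core data containers shared across the pipeline.

All subject-level tables are pandas objects indexed by subject ID; all
parcel-level tables are indexed by parcel ID. Blocks inside a
:class:`MultimodalDataset` are guaranteed to share one subject ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical modality order used when concatenating reduced blocks
MODALITY_ORDER = ("area", "thickness", "volume", "rsfc")


@dataclass
class MultimodalDataset:
    """Subjects × features blocks per imaging modality, behavior items, covariates.

    modality_blocks
        Mapping modality name -> DataFrame (subjects × features). Feature
        columns are labelled ``"modality:feature"`` (e.g. ``area:ctx_lh_003``
        or ``rsfc:e000123``).
    behavior
        Subjects × items ordinal DataFrame with values in {0, 1, 2};
        columns ``"item:k"``.
    covariates
        Subjects × covariates: age (years), sex, site, ethnicity, mean_fd,
        mean_dvars, icv, total_area.
    """

    modality_blocks: dict[str, pd.DataFrame]
    behavior: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.behavior.index
        if idx.has_duplicates:
            raise ValueError("duplicate subject IDs")
        for name, block in self.modality_blocks.items():
            if not block.index.equals(idx):
                raise ValueError(f"block {name!r} subject ordering differs from behavior")
            if block.isna().any().any():
                raise ValueError(f"block {name!r} contains missing values")
        if not self.covariates.index.equals(idx):
            raise ValueError("covariates subject ordering differs from behavior")

    @property
    def subject_ids(self) -> pd.Index:
        return self.behavior.index

    @property
    def n_subjects(self) -> int:
        return len(self.behavior)

    def subset(self, idx) -> "MultimodalDataset":
        """Row-subset every table by positional indices or boolean mask."""
        take = lambda df: df.iloc[np.asarray(idx)] if not isinstance(idx, pd.Index) else df.loc[idx]
        return MultimodalDataset(
            modality_blocks={k: take(v) for k, v in self.modality_blocks.items()},
            behavior=take(self.behavior),
            covariates=take(self.covariates),
        )


@dataclass
class NetworkPartition:
    """Assignment of every region (cortical + subcortical) to one network."""

    labels: pd.Series  # index: parcel_id, values: network label (str)

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate parcel IDs in partition")

    @property
    def networks(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.labels:
            seen.setdefault(v, None)
        return list(seen)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def indicator(self, parcel_order: pd.Index | None = None) -> pd.DataFrame:
        """Regions × networks 0/1 indicator matrix in a fixed network order."""
        lab = self.labels if parcel_order is None else self.labels.loc[parcel_order]
        return pd.get_dummies(lab).reindex(columns=self.networks).astype(float)


@dataclass
class ParcelSphereCoords:
    """Unit-sphere centroid per parcel; each hemisphere lives on its own sphere."""

    table: pd.DataFrame  # index parcel_id; columns hemisphere, x, y, z

    def __post_init__(self) -> None:
        xyz = self.table[["x", "y", "z"]].to_numpy(float)
        norms = np.linalg.norm(xyz, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("centroids must be unit-norm")

    @property
    def parcel_ids(self) -> pd.Index:
        return self.table.index

    @property
    def hemisphere(self) -> pd.Series:
        return self.table["hemisphere"]

    def xyz(self, hemisphere: str | None = None) -> np.ndarray:
        t = self.table if hemisphere is None else self.table[self.table["hemisphere"] == hemisphere]
        return t[["x", "y", "z"]].to_numpy(float)

    def cortical(self) -> "ParcelSphereCoords":
        mask = self.table["hemisphere"].isin(["L", "R"])
        return ParcelSphereCoords(self.table[mask])


@dataclass
class SyntheticTruth:
    """Ground truth planted by the synthetic generator.

    behavior_saliences and imaging_saliences have orthonormal columns; they
    are the population singular vectors of the planted brain-behavior
    cross-covariance (imaging saliences expressed in noise-normalized
    feature space, concatenated in :data:`MODALITY_ORDER`).
    """

    behavior_saliences: np.ndarray  # items × n_latent
    imaging_saliences: np.ndarray  # total features × n_latent
    subject_scores: np.ndarray  # subjects × n_latent
    planted_gradient: np.ndarray  # parcel-length, zero mean
    site_assignment: np.ndarray  # subject-length labels
    imaging_feature_labels: list[str] = field(default_factory=list)
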