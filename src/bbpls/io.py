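"""Tab-separated table I/O with validation.

TSV (tab-separated, UTF-8, '.' decimal) is the canonical dialect; CSV is
accepted on read. Subject tables carry ``subject_id`` as the first column;
round-tripping a table through write/read is lossless to full float
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import NetworkPartition, ParcelSphereCoords


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_feature_table(path: str | Path, index_col: str = "subject_id") -> pd.DataFrame:
    """Read a subjects × features table; errors on duplicate IDs or ragged rows."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=index_col)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed rows ({exc})") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate subject IDs {dupes[:5]}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index_label=index_label or df.index.name,
              float_format="%.17g")
    return path


def check_subject_alignment(tables: dict[str, pd.DataFrame]) -> None:
    """Raise listing the offending IDs when tables disagree on subjects."""
    items = list(tables.items())
    ref_name, ref = items[0]
    for name, df in items[1:]:
        missing = ref.index.difference(df.index)
        extra = df.index.difference(ref.index)
        if len(missing) or len(extra):
            raise ValueError(
                f"table {name!r} does not match {ref_name!r}: "
                f"missing {missing.tolist()[:5]}, extra {extra.tolist()[:5]}"
            )


def write_partition(partition: NetworkPartition, path: str | Path) -> Path:
    df = partition.labels.rename("network").to_frame()
    df.index.name = "parcel_id"
    return write_table(df, path)


def read_partition(path: str | Path, known_parcels=None) -> NetworkPartition:
    df = pd.read_csv(Path(path), sep=_sep_for(Path(path)), index_col="parcel_id")
    if known_parcels is not None:
        unknown = df.index.difference(pd.Index(known_parcels))
        if len(unknown):
            raise ValueError(f"partition references unknown parcels: {unknown.tolist()[:5]}")
    return NetworkPartition(df["network"].astype(str))


def write_centroids(coords: ParcelSphereCoords, path: str | Path) -> Path:
    df = coords.table.copy()
    df.index.name = "parcel_id"
    return write_table(df, path)


def read_centroids(path: str | Path) -> ParcelSphereCoords:
    df = pd.read_csv(Path(path), sep=_sep_for(Path(path)), index_col="parcel_id")
    return ParcelSphereCoords(df)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, default=default))
    return path
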