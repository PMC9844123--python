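"""Event-table readers and writers (CSV interchange, optional HDF5).

The interchange dialect is a UTF-8 CSV with '.' decimal separator and
the canonical columns

    id, time_s, label, area_um2, deformation, area_ratio,
    brightness_au, diameter_um

Tables produced by the feature extractor add more columns (perimeter,
raw-contour values, centroids); unknown extra columns are preserved on
read with a logged warning.  Validation enforces the physical
invariants: positive areas, deformation in [0, 1), area ratio >= 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger("acoustosort")

__all__ = ["read_events", "write_events", "read_events_hdf5",
           "write_events_hdf5", "validate_events", "SchemaError"]

#: columns every event table must provide
MANDATORY_COLUMNS = ["area_um2", "deformation", "area_ratio", "brightness_au"]
#: full canonical ordering (known optional columns follow the mandatory ones)
CANONICAL_ORDER = [
    "id", "time_s", "label", "area_um2", "deformation", "area_ratio",
    "brightness_au", "diameter_um", "perimeter_um", "deformation_raw",
    "area_raw_um2", "frame_index", "centroid_row_px", "centroid_col_px",
    "n_frames",
]


class SchemaError(ValueError):
    """An event table violates the interchange schema."""


def validate_events(table: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` on missing columns or invariant violations."""
    for col in MANDATORY_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"event table is missing mandatory column {col!r}")
    if len(table) == 0:
        return
    area = table["area_um2"].to_numpy(dtype=float)
    if np.any(~np.isfinite(area)) or np.any(area <= 0):
        raise SchemaError("area_um2 must be finite and positive")
    d = table["deformation"].to_numpy(dtype=float)
    if np.any(d < 0) or np.any(d >= 1):
        raise SchemaError("deformation must lie in [0, 1)")
    ar = table["area_ratio"].to_numpy(dtype=float)
    if np.any(ar < 1.0 - 1e-9):
        raise SchemaError("area_ratio must be >= 1")


def _canonicalise(table: pd.DataFrame) -> pd.DataFrame:
    known = [c for c in CANONICAL_ORDER if c in table.columns]
    extra = [c for c in table.columns if c not in CANONICAL_ORDER]
    if extra:
        log.warning("event table carries unknown columns %s; preserved as-is", extra)
    return table[known + extra]


def write_events(table: pd.DataFrame, path) -> None:
    """Write a validated event table as CSV (12 significant digits)."""
    validate_events(table)
    _canonicalise(table).to_csv(path, index=False, float_format="%.12g")


def read_events(path) -> pd.DataFrame:
    """Read and validate an event-table CSV."""
    table = pd.read_csv(path)
    validate_events(table)
    return _canonicalise(table)


def write_events_hdf5(table: pd.DataFrame, path, dataset_group: str = "events") -> None:
    """HDF5 container mirroring the CSV columns, one dataset per column."""
    import h5py

    validate_events(table)
    with h5py.File(path, "w") as fh:
        grp = fh.create_group(dataset_group)
        for col in _canonicalise(table).columns:
            values = table[col].to_numpy()
            if values.dtype == object:
                values = values.astype("S")
            grp.create_dataset(col, data=values)


def read_events_hdf5(path, dataset_group: str = "events") -> pd.DataFrame:
    import h5py

    data = {}
    with h5py.File(path, "r") as fh:
        grp = fh[dataset_group]
        for col in grp:
            values = grp[col][()]
            if values.dtype.kind == "S":
                values = values.astype(str)
            data[col] = values
    table = pd.DataFrame(data)
    validate_events(table)
    return _canonicalise(table)
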