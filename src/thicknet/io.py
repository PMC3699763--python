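"""Readers and writers for the delimited-text interchange formats.

The cohort lives in two CSV tables:

* thickness table — header ``subject_id, group, age, gender`` followed by one
  column per ROI, one row per subject;
* atlas table — header ``roi, hemisphere, x, y, z``, one row per ROI, in the
  same order as the thickness ROI columns.

Matrices (correlations, adjacency, efficiency tables) are CSVs with labeled
rows and columns.  Readers validate and fail with specific messages rather
than silently coercing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, ROIAtlas
from .errors import DataError

__all__ = ["read_cohort", "write_cohort", "read_matrix", "write_matrix"]

_THICKNESS_META = ["subject_id", "group", "age", "gender"]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    try:
        return pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise DataError(f"could not parse {path}: {exc}") from exc


def read_cohort(thickness_path, atlas_path) -> Cohort:
    """Read and cross-validate the thickness and atlas tables."""
    thick = _read_table(thickness_path)
    atlas_df = _read_table(atlas_path)

    missing = [c for c in _THICKNESS_META if c not in thick.columns]
    if missing:
        raise DataError(f"thickness table missing columns: {missing}")
    roi_cols = [c for c in thick.columns if c not in _THICKNESS_META]
    if not roi_cols:
        raise DataError("thickness table has no ROI columns")

    atlas = ROIAtlas.from_frame(atlas_df)
    if list(atlas.names) != roi_cols:
        if len(atlas.names) != len(roi_cols):
            raise DataError(
                f"atlas lists {len(atlas.names)} ROIs but thickness table has "
                f"{len(roi_cols)} ROI columns"
            )
        first_bad = next(
            (a, b) for a, b in zip(atlas.names, roi_cols) if a != b
        )
        raise DataError(
            f"ROI order mismatch between atlas and thickness table "
            f"(first difference: atlas {first_bad[0]!r} vs thickness {first_bad[1]!r})"
        )

    for col in ["age", "gender"] + roi_cols:
        vals = pd.to_numeric(thick[col], errors="coerce")
        bad = thick.index[vals.isna()]
        if len(bad):
            raise DataError(
                f"non-numeric or missing value in column {col!r} at row(s) "
                f"{bad.tolist()[:5]}"
            )
        thick[col] = vals

    group = thick["group"].to_numpy()
    labels, counts = np.unique(group, return_counts=True)
    if len(labels) != 2:
        raise DataError(f"expected exactly two group labels, found {labels.tolist()}")
    small = [
        (lab, int(cnt)) for lab, cnt in zip(labels.tolist(), counts.tolist()) if cnt < 3
    ]
    if small:
        raise DataError(f"fewer than 3 subjects in group(s): {small}")

    return Cohort(
        thickness=thick[roi_cols].to_numpy(dtype=float),
        age=thick["age"].to_numpy(dtype=float),
        gender=thick["gender"].to_numpy(dtype=float),
        group=group,
        atlas=atlas,
        subject_ids=tuple(str(s) for s in thick["subject_id"]),
    )


def write_cohort(cohort: Cohort, thickness_path, atlas_path) -> None:
    """Write the two cohort tables; inverse of :func:`read_cohort`."""
    Path(thickness_path).parent.mkdir(parents=True, exist_ok=True)
    cohort.to_frame().to_csv(thickness_path, index=False)
    cohort.atlas.to_frame().to_csv(atlas_path, index=False)


def write_matrix(matrix: np.ndarray, path, labels=None, index_labels=None) -> None:
    """Write a labeled matrix as CSV (rows labeled, header row of columns)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    idx = index_labels if index_labels is not None else labels
    pd.DataFrame(np.asarray(matrix), index=idx, columns=labels).to_csv(path)


def read_matrix(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"matrix file not found: {path}")
    return pd.read_csv(path, index_col=0)
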