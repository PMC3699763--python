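"""Cohort containers: per-subject thickness with covariates, and the ROI atlas.

A :class:`Cohort` holds the subjects × ROIs matrix of mean cortical thickness
together with the per-subject covariates (age in years, gender coded 0/1) and
the two-level group label.  A :class:`ROIAtlas` carries per-node metadata —
name, hemisphere and template-space centroid — whose Z coordinate drives the
dorsal/ventral classification downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["ROIAtlas", "Cohort"]


@dataclass(frozen=True)
class ROIAtlas:
    """Per-ROI metadata; row order matches thickness column order.

    Parameters
    ----------
    names : sequence of str
        Unique ROI names.
    hemisphere : sequence of str
        ``"left"`` or ``"right"`` per ROI.
    centroids : (n_rois, 3) array
        Template-space centre-of-mass coordinates in mm (x, y, z).
    """

    names: tuple[str, ...]
    hemisphere: tuple[str, ...]
    centroids: np.ndarray

    def __post_init__(self) -> None:
        cent = np.asarray(self.centroids, dtype=float)
        object.__setattr__(self, "centroids", cent)
        n = len(self.names)
        if len(set(self.names)) != n:
            raise DataError("ROI names must be unique")
        if len(self.hemisphere) != n or cent.shape != (n, 3):
            raise DataError(
                f"atlas fields inconsistent: {n} names, "
                f"{len(self.hemisphere)} hemisphere labels, centroids {cent.shape}"
            )
        bad = set(self.hemisphere) - {"left", "right"}
        if bad:
            raise DataError(f"hemisphere labels must be left/right, got {sorted(bad)}")
        if not np.isfinite(cent).all():
            raise DataError("atlas centroids contain non-finite values")

    @property
    def n_rois(self) -> int:
        return len(self.names)

    @property
    def z(self) -> np.ndarray:
        """Centroid Z coordinates (superior–inferior axis)."""
        return self.centroids[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": list(self.names),
                "hemisphere": list(self.hemisphere),
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ROIAtlas":
        required = ["roi", "hemisphere", "x", "y", "z"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DataError(f"atlas table missing columns: {missing}")
        return cls(
            names=tuple(str(v) for v in df["roi"]),
            hemisphere=tuple(str(v) for v in df["hemisphere"]),
            centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
        )


@dataclass
class Cohort:
    """Subjects × ROIs thickness with covariates and group labels."""

    thickness: np.ndarray
    age: np.ndarray
    gender: np.ndarray
    group: np.ndarray
    atlas: ROIAtlas
    subject_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.gender = np.asarray(self.gender, dtype=float)
        self.group = np.asarray(self.group)
        s, n = self.thickness.shape
        if not self.subject_ids:
            self.subject_ids = tuple(f"sub{i + 1:03d}" for i in range(s))
        if len(self.age) != s or len(self.gender) != s or len(self.group) != s:
            raise DataError("covariate vectors must match the thickness row count")
        if len(self.subject_ids) != s:
            raise DataError("subject_ids must match the thickness row count")
        if n != self.atlas.n_rois:
            raise DataError(
                f"thickness has {n} ROI columns but atlas describes {self.atlas.n_rois} ROIs"
            )
        if not np.isfinite(self.thickness).all():
            raise DataError("thickness matrix contains missing or non-finite values")
        if (self.thickness <= 0).any():
            raise DataError("thickness values must be strictly positive (mm)")
        if len(self.group_labels) != 2:
            raise DataError(
                f"cohort must contain exactly two groups, found {list(self.group_labels)}"
            )

    @property
    def n_subjects(self) -> int:
        return self.thickness.shape[0]

    @property
    def n_rois(self) -> int:
        return self.thickness.shape[1]

    @property
    def group_labels(self) -> tuple:
        """The two group labels in sorted order (group 1 first)."""
        return tuple(sorted(np.unique(self.group).tolist()))

    def group_sizes(self) -> dict:
        labels, counts = np.unique(self.group, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": list(self.subject_ids),
                "group": self.group,
                "age": self.age,
                "gender": self.gender.astype(int),
            }
        )
        thick = pd.DataFrame(self.thickness, columns=list(self.atlas.names))
        return pd.concat([df, thick], axis=1)
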