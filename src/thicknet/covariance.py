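"""Covariate residualization and inter-regional correlation networks.

Thickness of ROI x across subjects is modelled by one pooled GLM

    c(x) = β0 + β1·age + β2·gender (+ further covariates) + ε,

fit by least squares over all subjects (both groups in a single model).  The
partial correlation between two ROIs is the Pearson correlation of their GLM
residuals, computed per group.  Between-group edge differences use Fisher's
z-transformation with Benjamini–Hochberg FDR control over all N(N−1)/2 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort
from .errors import DataError

__all__ = [
    "ResidualMatrix",
    "CorrelationNetwork",
    "residualize",
    "correlation_network",
    "compare_edges",
    "demographic_ttest",
    "DEFAULT_COVARIATES",
]

#: covariates removed before correlating; "mean_thickness" is each subject's
#: mean ROI thickness (global-thickness nuisance), and the list may be
#: restricted to ("age", "gender") for the covariate-minimal model
DEFAULT_COVARIATES = ("age", "gender", "mean_thickness")

_KNOWN_COVARIATES = ("age", "gender", "mean_thickness")


@dataclass
class ResidualMatrix:
    """Per-ROI GLM residuals with the fitted coefficients.

    ``residuals`` is subjects × ROIs; ``model_coefficients`` is a
    (1 + n_covariates) × ROIs array whose first row is the intercept.
    ``group`` carries the per-row group labels so group-wise correlation can
    select rows downstream.
    """

    residuals: np.ndarray
    model_coefficients: np.ndarray
    covariate_names: tuple[str, ...]
    group: np.ndarray
    roi_names: tuple[str, ...]


@dataclass
class CorrelationNetwork:
    """Symmetric ROI × ROI Pearson correlation matrix for one group."""

    R: np.ndarray
    group: str
    n_subjects: int
    roi_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        r = np.asarray(self.R, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise DataError(f"correlation matrix must be square, got {r.shape}")
        if not np.allclose(r, r.T, atol=1e-12):
            raise DataError("correlation matrix must be symmetric")
        if not np.allclose(np.diagonal(r), 1.0, atol=1e-12):
            raise DataError("correlation matrix diagonal must be 1")
        if (np.abs(r) > 1 + 1e-12).any():
            raise DataError("correlation entries must lie in [-1, 1]")
        self.R = r

    @property
    def n_rois(self) -> int:
        return self.R.shape[0]


def _design_matrix(cohort: Cohort, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(cohort.n_subjects)]
    names = ["intercept"]
    for name in covariates:
        if name not in _KNOWN_COVARIATES:
            raise DataError(
                f"unknown covariate {name!r}; choose from {list(_KNOWN_COVARIATES)}"
            )
        if name == "age":
            cols.append(cohort.age)
        elif name == "gender":
            cols.append(cohort.gender)
        else:
            cols.append(cohort.thickness.mean(axis=1))
        names.append(name)
    return np.column_stack(cols), names


def residualize(cohort: Cohort, covariates: Sequence[str] = DEFAULT_COVARIATES) -> ResidualMatrix:
    """Fit the pooled per-ROI GLM and return thickness residuals.

    With an empty covariate list the model is intercept-only and the
    residuals are the per-ROI demeaned thickness.
    """
    x, names = _design_matrix(cohort, covariates)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        collinear = []
        for j in range(1, x.shape[1]):
            sub = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(names[j])
        raise DataError(
            f"design matrix is rank-deficient (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {collinear or names[1:]}"
        )
    beta, *_ = np.linalg.lstsq(x, cohort.thickness, rcond=None)
    residuals = cohort.thickness - x @ beta
    return ResidualMatrix(
        residuals=residuals,
        model_coefficients=beta,
        covariate_names=tuple(names),
        group=np.asarray(cohort.group),
        roi_names=tuple(cohort.atlas.names),
    )


def correlation_network(res: ResidualMatrix, group) -> CorrelationNetwork:
    """Pearson correlation of residuals over one group's subjects."""
    mask = res.group == group
    rows = res.residuals[mask]
    if rows.shape[0] < 3:
        raise DataError(
            f"group {group!r} has {rows.shape[0]} subjects; at least 3 required"
        )
    sd = rows.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [res.roi_names[i] for i in constant[:5]]
        raise DataError(f"constant residual column(s) for ROI(s) {names}")
    r = np.corrcoef(rows, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationNetwork(
        R=r, group=str(group), n_subjects=int(mask.sum()), roi_names=res.roi_names
    )


def compare_edges(
    netA: CorrelationNetwork, netB: CorrelationNetwork, alpha: float = 0.05
) -> pd.DataFrame:
    """Edge-wise Fisher-z comparison of two correlation networks.

    For every ROI pair, z = (atanh r_A − atanh r_B) / √(1/(n_A−3) + 1/(n_B−3))
    with a two-tailed normal p-value, and Benjamini–Hochberg q-values over
    all N(N−1)/2 pairs.  Returns a table with one row per pair.
    """
    if netA.n_rois != netB.n_rois:
        raise DataError(
            f"networks have different ROI counts ({netA.n_rois} vs {netB.n_rois})"
        )
    if netA.n_subjects < 4 or netB.n_subjects < 4:
        raise DataError("Fisher-z comparison requires at least 4 subjects per group")
    iu, ju = np.triu_indices(netA.n_rois, k=1)
    ra, rb = netA.R[iu, ju], netB.R[iu, ju]
    if (np.abs(ra) >= 1).any() or (np.abs(rb) >= 1).any():
        raise DataError("|r| = 1 encountered; Fisher z-transform is undefined")
    se = np.sqrt(1.0 / (netA.n_subjects - 3) + 1.0 / (netB.n_subjects - 3))
    z = (np.arctanh(ra) - np.arctanh(rb)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    names = netA.roi_names or tuple(str(i) for i in range(netA.n_rois))
    return pd.DataFrame(
        {
            "roi_x": [names[i] for i in iu],
            "roi_y": [names[j] for j in ju],
            "r_a": ra,
            "r_b": rb,
            "z": z,
            "p": p,
            "q": q,
            "significant": reject,
        }
    )


def demographic_ttest(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Pooled-variance two-sample t from group summary statistics.

    t = (mean2 − mean1) / (s_p · √(1/n1 + 1/n2)),
    s_p² = ((n1−1)·sd1² + (n2−1)·sd2²) / (n1 + n2 − 2).
    The sign convention is group 2 minus group 1.
    """
    if n1 < 2 or n2 < 2:
        raise DataError("both groups need at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise DataError("standard deviations must be non-negative")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        if mean1 == mean2:
            return 0.0
        raise DataError("zero pooled variance with unequal means: t is undefined")
    return float((mean2 - mean1) / (np.sqrt(sp2) * np.sqrt(1.0 / n1 + 1.0 / n2)))
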