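"""Permutation-based group inference and the dorsal/ventral disparity summary.

The group comparison shuffles group labels and reruns the analysis —
group-wise correlation, cost binarization, efficiency — for each relabeling,
building an exact null for the group-2 minus group-1 difference.  Because
the covariate GLM is pooled and group-blind, residuals are computed once and
reused across permutations (relabeling cannot change them).  Two-tailed
p-values use the add-one estimator p = (#{|null| ≥ |observed|} + 1)/(B + 1),
which is valid for any B.  Node-level p-values are reported uncorrected.

Nodes are classified dorsal or ventral by their centroid Z relative to the
median Z over all ROIs; the disparity summary splits significant nodes by
sign of the group difference and location.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _scipy_stats

from .cohort import Cohort, ROIAtlas
from .covariance import DEFAULT_COVARIATES, residualize
from .efficiency import (
    EfficiencyProfile,
    local_efficiency_array,
    neighboring_efficiency_vector,
    nodal_efficiency_vector,
)
from .errors import DataError, SpecError
from .graphs import CostGrid, cost_profile_adjacencies

__all__ = [
    "PermutationResult",
    "permutation_test",
    "classify_dorsal_ventral",
    "DisparitySummary",
    "disparity_summary",
    "DegreeEfficiencyModel",
    "degree_efficiency_model",
    "degree_similarity",
]

logger = logging.getLogger(__name__)

STATISTICS = ("E_glob", "E_loc", "E_nodal", "E_nbr")


@dataclass
class PermutationResult:
    """Observed group difference with its permutation null distribution.

    ``observed`` is group 2 minus group 1: a scalar for network-level
    statistics with ``scope="auc_mean"``, a length-C array with
    ``scope="per_cost"``, a length-N array for node-level statistics with
    ``scope="auc_mean"``, or C × N with ``scope="per_cost"``.  ``null`` has
    one leading axis of length B.
    """

    statistic: str
    scope: str
    grid: CostGrid
    observed: np.ndarray
    null: np.ndarray
    p: np.ndarray
    B: int
    seed: int | None

    @property
    def signed_log10_p(self) -> np.ndarray:
        """sign(observed) · (−log10 p); positive means greater in group 2."""
        return np.sign(self.observed) * (-np.log10(self.p))


def _per_cost_statistic(adjs, statistic: str, convention: str) -> np.ndarray:
    if statistic == "E_glob":
        return np.array([nodal_efficiency_vector(a).mean() for a in adjs])
    if statistic == "E_loc":
        return np.array([local_efficiency_array(a, convention) for a in adjs])
    if statistic == "E_nodal":
        return np.array([nodal_efficiency_vector(a) for a in adjs])
    if statistic == "E_nbr":
        return np.array([neighboring_efficiency_vector(a, convention) for a in adjs])
    raise SpecError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")


def _group_difference(
    residuals: np.ndarray,
    labels: np.ndarray,
    g1,
    g2,
    costs,
    statistic: str,
    scope: str,
    convention: str,
) -> np.ndarray:
    vals = []
    for g in (g1, g2):
        rows = residuals[labels == g]
        r = np.corrcoef(rows, rowvar=False)
        np.fill_diagonal(r, 1.0)
        adjs = cost_profile_adjacencies(r, costs)
        vals.append(_per_cost_statistic(adjs, statistic, convention))
    diff = vals[1] - vals[0]
    if scope == "auc_mean":
        return diff.mean(axis=0)
    return diff


def permutation_test(
    cohort: Cohort,
    statistic: str,
    grid: CostGrid,
    B: int = 200,
    seed: int | None = None,
    scope: str = "auc_mean",
    covariates=DEFAULT_COVARIATES,
    nbr_convention: str = "paper",
    alpha: float = 0.05,
) -> PermutationResult:
    """Permutation test of a group difference in an efficiency statistic.

    For each of ``B`` permutations the group labels are shuffled and the
    full correlation → binarization → efficiency chain is recomputed for
    both pseudo-groups.  ``scope="auc_mean"`` compares cost-averaged values;
    ``scope="per_cost"`` tests each cost separately.
    """
    if B < 1:
        raise SpecError("B must be at least 1")
    if scope not in ("auc_mean", "per_cost"):
        raise SpecError(f"unknown scope {scope!r}")
    if 1.0 / (B + 1) > alpha:
        warnings.warn(
            f"B={B} permutations cannot resolve p-values below {1 / (B + 1):.3f}; "
            f"alpha={alpha} is unattainable",
            stacklevel=2,
        )
    res = residualize(cohort, covariates)
    labels = np.asarray(cohort.group)
    g1, g2 = cohort.group_labels
    costs = list(grid)
    observed = _group_difference(
        res.residuals, labels, g1, g2, costs, statistic, scope, nbr_convention
    )
    rng = np.random.default_rng(seed)
    null = np.empty((B,) + np.shape(observed))
    for b in range(B):
        perm = rng.permutation(labels)
        null[b] = _group_difference(
            res.residuals, perm, g1, g2, costs, statistic, scope, nbr_convention
        )
    exceed = (np.abs(null) >= np.abs(observed)).sum(axis=0)
    p = (exceed + 1.0) / (B + 1.0)
    return PermutationResult(
        statistic=statistic,
        scope=scope,
        grid=grid,
        observed=np.asarray(observed),
        null=null,
        p=np.asarray(p),
        B=B,
        seed=seed,
    )


def classify_dorsal_ventral(atlas: ROIAtlas) -> np.ndarray:
    """Label each ROI dorsal or ventral by centroid Z vs the median Z.

    Strictly above the median → dorsal, otherwise ventral.  With an even
    number of distinct Z values this splits the atlas exactly in half.
    """
    z = atlas.z
    if not np.isfinite(z).all():
        raise DataError("atlas centroid Z coordinates contain non-finite values")
    med = np.median(z)
    labels = np.where(z > med, "dorsal", "ventral")
    if (labels == "ventral").all():
        logger.warning(
            "no ROI lies strictly above the median Z; all nodes classified ventral"
        )
    return labels


@dataclass
class DisparitySummary:
    """Counts and proportions of dorsal/ventral nodes among significant nodes."""

    table: pd.DataFrame
    alpha: float
    n_sig_greater: int
    n_greater_dorsal: int
    n_sig_smaller: int
    n_smaller_ventral: int

    @property
    def prop_greater_dorsal(self) -> float:
        """Fraction of significantly-greater nodes that are dorsal (nan if none)."""
        return self.n_greater_dorsal / self.n_sig_greater if self.n_sig_greater else float("nan")

    @property
    def prop_smaller_ventral(self) -> float:
        """Fraction of significantly-smaller nodes that are ventral (nan if none)."""
        return self.n_smaller_ventral / self.n_sig_smaller if self.n_sig_smaller else float("nan")


def disparity_summary(
    perm: PermutationResult, locations: np.ndarray, alpha: float = 0.05
) -> DisparitySummary:
    """Split significant nodes by difference sign and dorsal/ventral location.

    Requires a node-level permutation result with one value per node
    (``scope="auc_mean"`` on E_nodal or E_nbr); p-values are uncorrected.
    """
    obs = np.asarray(perm.observed)
    if obs.ndim != 1 or perm.statistic not in ("E_nodal", "E_nbr"):
        raise SpecError(
            "disparity summary needs a node-level result with one value per "
            f"node (got statistic={perm.statistic!r}, scope={perm.scope!r})"
        )
    locations = np.asarray(locations)
    if locations.shape != obs.shape:
        raise DataError(
            f"{locations.shape[0] if locations.ndim else 0} location labels "
            f"for {obs.shape[0]} nodes"
        )
    sig = perm.p < alpha
    greater = sig & (obs > 0)
    smaller = sig & (obs < 0)
    table = pd.DataFrame(
        {
            "node": np.arange(obs.shape[0]),
            "location": locations,
            "observed_diff": obs,
            "p": perm.p,
            "signed_log10_p": perm.signed_log10_p,
            "significant": sig,
            "direction": np.where(obs > 0, "greater", np.where(obs < 0, "smaller", "equal")),
        }
    )
    return DisparitySummary(
        table=table,
        alpha=alpha,
        n_sig_greater=int(greater.sum()),
        n_greater_dorsal=int((greater & (locations == "dorsal")).sum()),
        n_sig_smaller=int(smaller.sum()),
        n_smaller_ventral=int((smaller & (locations == "ventral")).sum()),
    )


@dataclass
class DegreeEfficiencyModel:
    """OLS fit of mean efficiency on mean degree, group, and their interaction.

    E(i) = β0 + β1·D(i) + β2·G(i) + β3·D(i)·G(i) + ε over the 2N node-level
    observations (both groups), with D optionally log-transformed.  The
    interaction F-test asks whether the efficiency–degree slope differs
    between groups.
    """

    params: np.ndarray          # β0..β3
    bse: np.ndarray             # standard errors
    r_squared: float
    f_interaction: float
    p_interaction: float
    measure: str
    degree_transform: str


def degree_efficiency_model(
    profile1: EfficiencyProfile,
    profile2: EfficiencyProfile,
    measure: str = "E_nodal",
    transform: str = "linear",
) -> DegreeEfficiencyModel:
    """Fit the efficiency-vs-degree interaction model across both groups."""
    if measure == "E_nodal":
        e1, e2 = profile1.mean_e_nodal, profile2.mean_e_nodal
    elif measure == "E_nbr":
        e1, e2 = profile1.mean_e_nbr, profile2.mean_e_nbr
    else:
        raise SpecError(f"measure must be E_nodal or E_nbr, got {measure!r}")
    if profile1.n_nodes != profile2.n_nodes:
        raise DataError("profiles have different node counts")
    d = np.concatenate([profile1.mean_degree, profile2.mean_degree])
    if transform == "log":
        bad = np.flatnonzero(d <= 0)
        if bad.size:
            nodes = (bad % profile1.n_nodes).tolist()[:10]
            raise DataError(
                f"log-degree transform undefined: zero mean degree at nodes {nodes}"
            )
        d = np.log(d)
    elif transform != "linear":
        raise SpecError(f"transform must be linear or log, got {transform!r}")
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.zeros(profile1.n_nodes), np.ones(profile2.n_nodes)])
    x = sm.add_constant(np.column_stack([d, g, d * g]))
    fit = sm.OLS(e, x).fit()
    ftest = fit.f_test(np.array([[0.0, 0.0, 0.0, 1.0]]))
    return DegreeEfficiencyModel(
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        r_squared=float(fit.rsquared),
        f_interaction=float(ftest.fvalue),
        p_interaction=float(ftest.pvalue),
        measure=measure,
        degree_transform=transform,
    )


def degree_similarity(profileA: EfficiencyProfile, profileB: EfficiencyProfile) -> float:
    """Pearson correlation of the two groups' cost-averaged degree vectors."""
    da, db = profileA.mean_degree, profileB.mean_degree
    if da.shape != db.shape:
        raise DataError("profiles have different node counts")
    if da.std() == 0 or db.std() == 0:
        raise DataError("degree vector is constant; correlation undefined")
    return float(_scipy_stats.pearsonr(da, db)[0])
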