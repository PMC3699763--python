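"""End-to-end pipeline: cohort tables in, analysis artifacts out.

``run_pipeline`` executes the full chain — residualization, group
correlation networks, edge comparison, cost binarization, efficiency
profiles, small-world assessment, permutation inference, dorsal/ventral
disparity, and the degree–efficiency model — writing every artifact as
delimited text under one run directory, with the config hash and seed echoed
into the summary so reruns are reproducible.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort
from .config import RunConfig
from .covariance import compare_edges, correlation_network, residualize
from .efficiency import compute_profile, small_world_assessment
from .errors import ThicknetError
from .graphs import build_cost_profile
from .inference import (
    classify_dorsal_ventral,
    degree_efficiency_model,
    degree_similarity,
    disparity_summary,
    permutation_test,
)
from .io import read_cohort, write_matrix

__all__ = ["run_pipeline", "analyze_cohort"]

logger = logging.getLogger(__name__)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage=%s status=ok elapsed=%.2fs", name, dt)
            else:
                logger.error("stage=%s status=failed elapsed=%.2fs error=%s", name, dt, exc)
            return False

    return _Timer()


def _pick_degree_transform(p1, p2, measure):
    """Use log degree when it improves the fit and is defined, else linear."""
    linear = degree_efficiency_model(p1, p2, measure=measure, transform="linear")
    d = np.concatenate([p1.mean_degree, p2.mean_degree])
    if (d <= 0).any():
        return linear
    log = degree_efficiency_model(p1, p2, measure=measure, transform="log")
    return log if log.r_squared > linear.r_squared else linear


def analyze_cohort(cohort: Cohort, config: RunConfig, out: Path) -> dict:
    """Run every analysis stage on an in-memory cohort; returns the summary."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.cost_grid()
    roi = list(cohort.atlas.names)
    g1, g2 = cohort.group_labels
    summary: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_subjects": cohort.n_subjects,
        "n_rois": cohort.n_rois,
        "group_sizes": {str(k): v for k, v in cohort.group_sizes().items()},
    }

    with _stage("residualize"):
        res = residualize(cohort, config.covariates)
        write_matrix(
            res.model_coefficients, out / "glm_coefficients.csv",
            labels=roi, index_labels=list(res.covariate_names),
        )

    with _stage("correlation"):
        nets = {g: correlation_network(res, g) for g in (g1, g2)}
        for g, net in nets.items():
            write_matrix(net.R, out / f"correlation_group{g}.csv", labels=roi)

    with _stage("edge_comparison"):
        edges = compare_edges(nets[g1], nets[g2], alpha=config.alpha)
        edges.to_csv(out / "edge_comparison.csv", index=False)
        summary["edges_significant_fdr"] = int(edges["significant"].sum())
        summary["edges_min_q"] = float(edges["q"].min())

    with _stage("cost_profile"):
        profiles = {}
        binaries = {}
        for g, net in nets.items():
            binaries[g] = build_cost_profile(net, grid)
            profiles[g] = compute_profile(
                binaries[g], grid, convention=config.nbr_convention, group=str(g)
            )
            cost_labels = [f"{c:.2f}" for c in grid]
            prof = profiles[g]
            write_matrix(prof.e_nodal.T, out / f"e_nodal_group{g}.csv",
                         labels=cost_labels, index_labels=roi)
            write_matrix(prof.e_nbr.T, out / f"e_nbr_group{g}.csv",
                         labels=cost_labels, index_labels=roi)
            write_matrix(prof.degree.T, out / f"degree_group{g}.csv",
                         labels=cost_labels, index_labels=roi)
            pd.DataFrame(
                {"cost": list(grid), "e_glob": prof.e_glob, "e_loc": prof.e_loc}
            ).to_csv(out / f"network_efficiency_group{g}.csv", index=False)
            # edge lists (0-based node-index pairs) per cost
            with open(out / f"edges_group{g}.txt", "w") as fh:
                for bn in binaries[g]:
                    pairs = " ".join(f"{i},{j}" for i, j in bn.edge_list())
                    fh.write(f"cost={bn.cost_nominal:.2f} K={bn.n_edges} {pairs}\n")
        summary["mean_e_glob"] = {str(g): profiles[g].mean_e_glob for g in profiles}
        summary["mean_e_loc"] = {str(g): profiles[g].mean_e_loc for g in profiles}

    with _stage("small_world"):
        rng = np.random.default_rng(config.seed)
        sw_rows = []
        for g in (g1, g2):
            sw = small_world_assessment(
                binaries[g], grid, n_null=config.n_null_networks,
                seed=rng, convention=config.nbr_convention,
            )
            for i, c in enumerate(grid):
                sw_rows.append(
                    {
                        "group": g, "cost": c,
                        "e_glob_brain": sw.e_glob_brain[i],
                        "e_glob_random": sw.e_glob_random[i],
                        "e_glob_lattice": sw.e_glob_lattice[i],
                        "e_loc_brain": sw.e_loc_brain[i],
                        "e_loc_random": sw.e_loc_random[i],
                        "e_loc_lattice": sw.e_loc_lattice[i],
                        "glob_sandwich": bool(sw.glob_sandwich[i]),
                        "loc_sandwich": bool(sw.loc_sandwich[i]),
                    }
                )
            summary.setdefault("small_world_fraction", {})[str(g)] = float(
                np.mean(sw.glob_sandwich & sw.loc_sandwich)
            )
        pd.DataFrame(sw_rows).to_csv(out / "small_world.csv", index=False)

    with _stage("permutation"):
        locations = classify_dorsal_ventral(cohort.atlas)
        perm_results = {}
        for statistic in ("E_glob", "E_loc", "E_nodal", "E_nbr"):
            perm_results[statistic] = permutation_test(
                cohort, statistic, grid, B=config.n_permutations,
                seed=config.seed, scope="auc_mean",
                covariates=config.covariates,
                nbr_convention=config.nbr_convention,
                alpha=config.alpha,
            )
        for statistic in ("E_glob", "E_loc"):
            r = perm_results[statistic]
            summary[f"perm_{statistic}"] = {
                "observed_diff": float(r.observed),
                "p": float(r.p),
            }
        node_table = pd.DataFrame(
            {
                "roi": roi,
                "hemisphere": list(cohort.atlas.hemisphere),
                "location": locations,
                "e_nodal_diff": perm_results["E_nodal"].observed,
                "e_nodal_p": perm_results["E_nodal"].p,
                "e_nodal_signed_log10_p": perm_results["E_nodal"].signed_log10_p,
                "e_nbr_diff": perm_results["E_nbr"].observed,
                "e_nbr_p": perm_results["E_nbr"].p,
                "e_nbr_signed_log10_p": perm_results["E_nbr"].signed_log10_p,
            }
        )
        node_table.to_csv(out / "node_results.csv", index=False)

    with _stage("disparity"):
        for statistic in ("E_nodal", "E_nbr"):
            disp = disparity_summary(
                perm_results[statistic], locations, alpha=config.alpha
            )
            summary[f"disparity_{statistic}"] = {
                "n_sig_greater": disp.n_sig_greater,
                "n_greater_dorsal": disp.n_greater_dorsal,
                "n_sig_smaller": disp.n_sig_smaller,
                "n_smaller_ventral": disp.n_smaller_ventral,
                "prop_greater_dorsal": float(disp.prop_greater_dorsal),
                "prop_smaller_ventral": float(disp.prop_smaller_ventral),
            }

    with _stage("degree_model"):
        for measure in ("E_nodal", "E_nbr"):
            model = _pick_degree_transform(profiles[g1], profiles[g2], measure)
            summary[f"degree_model_{measure}"] = {
                "beta": [float(b) for b in model.params],
                "r_squared": model.r_squared,
                "f_interaction": model.f_interaction,
                "p_interaction": model.p_interaction,
                "degree_transform": model.degree_transform,
            }
        summary["degree_correlation"] = degree_similarity(profiles[g1], profiles[g2])

    (out / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=False))
    return summary


def run_pipeline(config: RunConfig) -> Path:
    """Read the cohort named by the config and run every stage.

    Returns the run directory; any stage failure aborts with the stage name
    in the log.  Deterministic given the config seed.
    """
    out = Path(config.output_dir)
    with _stage("read_cohort"):
        if not config.thickness_path or not config.atlas_path:
            raise ThicknetError("config must name thickness_path and atlas_path")
        cohort = read_cohort(config.thickness_path, config.atlas_path)
    analyze_cohort(cohort, config, out)
    return out
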