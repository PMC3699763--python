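"""Permutation inference, dorsal/ventral classification, degree models."""

import dataclasses

import numpy as np
import pytest

import thicknet as tn
from thicknet.errors import DataError, SpecError


def _profile_from_values(e_nodal, degree, group="g"):
    """Single-cost EfficiencyProfile with prescribed node-level values."""
    e_nodal = np.asarray(e_nodal, dtype=float)[None, :]
    degree = np.asarray(degree, dtype=float)[None, :]
    return tn.EfficiencyProfile(
        group=group,
        grid=tn.CostGrid((0.1,)),
        e_glob=e_nodal.mean(axis=1),
        e_loc=e_nodal.mean(axis=1),
        e_nodal=e_nodal,
        e_nbr=e_nodal,
        degree=degree,
    )


class TestPermutationTest:
    def test_duplicate_groups_give_zero_diff_unit_p(self, small_grid):
        """Group 2 an exact copy of group 1: observed diff 0, p = 1."""
        spec = tn.CohortSpec(n_group1=8, n_group2=8, n_rois=10, seed=3)
        base = tn.generate_cohort(spec)
        thick = np.vstack([base.thickness[:8], base.thickness[:8]])
        cohort = tn.Cohort(
            thickness=thick,
            age=np.concatenate([base.age[:8], base.age[:8]]),
            gender=np.concatenate([base.gender[:8], base.gender[:8]]),
            group=np.array([1] * 8 + [2] * 8),
            atlas=base.atlas,
        )
        r = tn.permutation_test(cohort, "E_glob", small_grid, B=30, seed=0)
        assert r.observed == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_seeded_run_is_bitwise_reproducible(self, small_cohort, small_grid):
        a = tn.permutation_test(small_cohort, "E_nodal", small_grid, B=25, seed=9)
        b = tn.permutation_test(small_cohort, "E_nodal", small_grid, B=25, seed=9)
        assert np.array_equal(a.null, b.null)
        assert np.array_equal(a.p, b.p)

    def test_p_invariant_under_group_relabeling(self, small_cohort, small_grid):
        """Swapping group labels flips the sign but not the two-tailed p."""
        swapped = tn.Cohort(
            thickness=small_cohort.thickness,
            age=small_cohort.age,
            gender=small_cohort.gender,
            group=np.where(small_cohort.group == 1, 2, 1),
            atlas=small_cohort.atlas,
        )
        a = tn.permutation_test(small_cohort, "E_nodal", small_grid, B=25, seed=5)
        b = tn.permutation_test(swapped, "E_nodal", small_grid, B=25, seed=5)
        assert np.allclose(a.observed, -b.observed)
        assert np.array_equal(a.p, b.p)

    def test_per_cost_scope_shapes(self, small_cohort, small_grid):
        r = tn.permutation_test(
            small_cohort, "E_nodal", small_grid, B=10, seed=1, scope="per_cost"
        )
        assert r.observed.shape == (len(small_grid), small_cohort.n_rois)
        assert r.null.shape == (10,) + r.observed.shape
        assert r.p.shape == r.observed.shape

    def test_signed_log10_p_sign_matches_observed(self, small_cohort, small_grid):
        r = tn.permutation_test(small_cohort, "E_nodal", small_grid, B=25, seed=2)
        nonzero = r.observed != 0
        assert np.array_equal(
            np.sign(r.signed_log10_p[nonzero]), np.sign(r.observed[nonzero])
        )

    def test_low_b_warns_about_alpha_resolution(self, small_cohort, small_grid):
        with pytest.warns(UserWarning, match="cannot resolve"):
            tn.permutation_test(small_cohort, "E_glob", small_grid, B=5, seed=0)

    def test_invalid_statistic_rejected(self, small_cohort, small_grid):
        with pytest.raises(SpecError, match="unknown statistic"):
            tn.permutation_test(small_cohort, "E_between", small_grid, B=2, seed=0)


class TestClassifyDorsalVentral:
    def _atlas(self, z):
        z = np.asarray(z, dtype=float)
        n = len(z)
        cent = np.column_stack([np.zeros(n), np.zeros(n), z])
        return tn.ROIAtlas(
            names=tuple(f"r{i}" for i in range(n)),
            hemisphere=tuple("left" if i % 2 == 0 else "right" for i in range(n)),
            centroids=cent,
        )

    def test_strictly_above_median_is_dorsal(self):
        labels = tn.classify_dorsal_ventral(self._atlas([1, 2, 3, 4]))
        assert labels.tolist() == ["ventral", "ventral", "dorsal", "dorsal"]

    def test_all_equal_z_classified_ventral(self):
        labels = tn.classify_dorsal_ventral(self._atlas([5, 5, 5, 5]))
        assert (labels == "ventral").all()


class TestDisparitySummary:
    def _perm(self, observed, p):
        observed = np.asarray(observed, dtype=float)
        return tn.PermutationResult(
            statistic="E_nodal", scope="auc_mean", grid=tn.CostGrid((0.1,)),
            observed=observed, null=np.zeros((1,) + observed.shape),
            p=np.asarray(p, dtype=float), B=1, seed=0,
        )

    def test_no_significant_nodes_gives_zero_counts(self):
        perm = self._perm([0.1, -0.1], [0.5, 0.5])
        s = tn.disparity_summary(perm, np.array(["dorsal", "ventral"]))
        assert s.n_sig_greater == 0 and s.n_sig_smaller == 0
        assert np.isnan(s.prop_greater_dorsal)

    def test_counts_split_by_sign_and_location(self):
        perm = self._perm([0.2, 0.3, -0.4, -0.1], [0.01, 0.02, 0.01, 0.5])
        locs = np.array(["dorsal", "ventral", "ventral", "ventral"])
        s = tn.disparity_summary(perm, locs, alpha=0.05)
        assert s.n_sig_greater == 2 and s.n_greater_dorsal == 1
        assert s.n_sig_smaller == 1 and s.n_smaller_ventral == 1
        assert s.prop_smaller_ventral == 1.0

    def test_greater_nodes_have_positive_signed_log_p(self):
        perm = self._perm([0.2, -0.2], [0.01, 0.01])
        s = tn.disparity_summary(perm, np.array(["dorsal", "ventral"]))
        row = s.table.iloc[0]
        assert row["direction"] == "greater" and row["signed_log10_p"] > 0

    def test_network_level_result_rejected(self):
        perm = dataclasses.replace(
            self._perm([0.1], [0.5]), statistic="E_glob",
            observed=np.float64(0.1), p=np.float64(0.5),
        )
        with pytest.raises(SpecError, match="node-level"):
            tn.disparity_summary(perm, np.array(["dorsal"]))


class TestDegreeEfficiencyModel:
    def test_identical_groups_zero_interaction(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(5, 40, 30)
        e = 0.2 + 0.01 * d + rng.normal(0, 0.03, 30)
        p1 = _profile_from_values(e, d, "a")
        p2 = _profile_from_values(e, d, "b")
        m = tn.degree_efficiency_model(p1, p2)
        assert m.params[3] == pytest.approx(0.0, abs=1e-10)
        assert m.f_interaction == pytest.approx(0.0, abs=1e-8)

    def test_exact_linear_relation_gives_unit_r_squared(self):
        rng = np.random.default_rng(1)
        d1, d2 = rng.uniform(5, 40, 25), rng.uniform(5, 40, 25)
        m = tn.degree_efficiency_model(
            _profile_from_values(0.1 + 0.01 * d1, d1),
            _profile_from_values(0.15 + 0.02 * d2, d2),
        )
        assert m.r_squared == pytest.approx(1.0, abs=1e-10)
        assert m.params[3] == pytest.approx(0.01, abs=1e-8)

    def test_known_interaction_recovered_within_two_se(self):
        rng = np.random.default_rng(2)
        n = 148
        d1, d2 = rng.uniform(5, 60, n), rng.uniform(5, 60, n)
        b0, b1, b2, b3 = 0.15, 0.006, 0.03, 0.02
        e1 = b0 + b1 * d1 + rng.normal(0, 0.05, n)
        e2 = b0 + b2 + (b1 + b3) * d2 + rng.normal(0, 0.05, n)
        m = tn.degree_efficiency_model(
            _profile_from_values(e1, d1), _profile_from_values(e2, d2)
        )
        assert abs(m.params[3] - b3) <= 2 * m.bse[3]

    def test_log_transform_rejects_zero_degree(self):
        d = np.array([0.0, 3.0, 4.0])
        p = _profile_from_values([0.1, 0.2, 0.3], d)
        with pytest.raises(DataError, match="log-degree"):
            tn.degree_efficiency_model(p, p, transform="log")


class TestDegreeSimilarity:
    def test_identical_profiles_correlate_to_one(self):
        d = np.array([3.0, 5.0, 9.0, 2.0])
        p = _profile_from_values(d / 10, d)
        assert tn.degree_similarity(p, p) == pytest.approx(1.0)

    def test_independent_profiles_near_zero(self):
        rng = np.random.default_rng(3)
        pa = _profile_from_values(np.zeros(200), rng.uniform(1, 50, 200))
        pb = _profile_from_values(np.zeros(200), rng.uniform(1, 50, 200))
        assert abs(tn.degree_similarity(pa, pb)) < 0.2

    def test_constant_degree_vector_rejected(self):
        p = _profile_from_values([0.1, 0.2], [4.0, 4.0])
        with pytest.raises(DataError, match="constant"):
            tn.degree_similarity(p, p)

    def test_split_halves_of_one_modular_cohort_correlate(self):
        """Two samples of one heterogeneous covariance share a degree pattern.

        Blocks of unequal size create reproducible hubs (large-block nodes
        carry more strong within-block edges), so the cost-averaged degree
        vectors of two independent groups drawn from the same structure
        correlate.
        """
        blocks, start = [], 0
        for size in (4, 6, 8, 10, 12):  # bigger blocks make higher-degree hubs
            blocks.append((tuple(range(start, start + size)), 0.6))
            start += size
        spec = tn.CohortSpec(
            n_group1=60, n_group2=60, n_rois=start + 4, seed=21,
            blocks_group1=tuple(blocks), blocks_group2=tuple(blocks),
        )
        cohort = tn.generate_cohort(spec)
        res = tn.residualize(cohort)
        grid = tn.CostGrid.from_range(0.05, 0.30, 0.05)
        profs = []
        for g in (1, 2):
            net = tn.correlation_network(res, g)
            profs.append(tn.compute_profile(tn.build_cost_profile(net, grid), grid))
        assert tn.degree_similarity(*profs) > 0.4
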