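import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lfcdmap import (
    Cohort,
    ThresholdSpec,
    cluster_filter,
    fdr_bh,
    r_map,
    report_clusters,
    t_contrast,
)
from lfcdmap.groupstats import GridCompatibilityError, pearson_r_vector, two_sample_t

from conftest import make_mask
from oracles import bh_stepup, pearson_r, pooled_t


def cohort_from_values(values_top, values_lower):
    """1-voxel cohort: each subject's 'map' is a single value."""
    n1, n2 = len(values_top), len(values_lower)
    table = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n1 + n2)],
            "group": ["top"] * n1 + ["lower"] * n2,
            "rank_level": list(range(n1 + n2)),
        }
    )
    maps = np.asarray(list(values_top) + list(values_lower), dtype=float).reshape(-1, 1, 1, 1)
    return Cohort(table=table, maps=maps)



def one_voxel_mask():
    return make_mask(np.ones((1, 1, 1), bool))


class TestTContrast:
    def test_hand_computed_pooled_t(self):
        res = t_contrast(cohort_from_values([1, 2, 3], [4, 5, 6]), one_voxel_mask())
        assert res.data[0, 0, 0] == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4

    def test_identical_distributions_give_zero(self):
        res = t_contrast(cohort_from_values([1, 2, 3], [1, 2, 3]), one_voxel_mask())
        assert res.data[0, 0, 0] == pytest.approx(0.0)

    def test_degenerate_voxel_flagged_neutral(self):
        res = t_contrast(cohort_from_values([2, 2, 2], [2, 2, 2]), one_voxel_mask())
        assert res.data[0, 0, 0] == 0.0
        assert res.p[0, 0, 0] == 1.0

    def test_study_sized_cohort_df(self, rng):
        maps = rng.standard_normal((60, 2, 2, 2))
        table = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(60)],
                "group": ["top"] * 26 + ["lower"] * 34,
                "rank_level": rng.uniform(0, 100, 60),
            }
        )
        res = t_contrast(Cohort(table=table, maps=maps), make_mask(np.ones((2, 2, 2), bool)))
        assert res.df == 58

    def test_label_swap_negates_t_exactly(self, rng):
        a, b = rng.standard_normal((5, 50)), rng.standard_normal((7, 50))
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(b, a)
        np.testing.assert_array_equal(t1, -t2)
        np.testing.assert_array_equal(p1, p2)

    def test_matches_closed_form_on_random_samples(self, rng):
        for _ in range(100):
            a = rng.standard_normal(rng.integers(2, 9))
            b = rng.standard_normal(rng.integers(2, 9))
            t, _ = two_sample_t(a[:, None], b[:, None])
            assert t[0] == pytest.approx(pooled_t(a, b), abs=1e-10)

    def test_group_too_small(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            t_contrast(cohort_from_values([1], [2, 3]), one_voxel_mask())


class TestRMap:
    def test_perfect_linear_relation(self):
        table = pd.DataFrame(
            {
                "subject_id": list("abcd"),
                "group": ["top"] * 4,
                "rank_level": [1.0, 2.0, 3.0, 4.0],
            }
        )
        maps = (2.0 * table["rank_level"].to_numpy() + 1).reshape(-1, 1, 1, 1)
        res = r_map(Cohort(table=table, maps=maps), one_voxel_mask())
        assert res.data[0, 0, 0] == pytest.approx(1.0)
        assert res.kind == "pearson_r"

    def test_hand_computed_r(self):
        table = pd.DataFrame(
            {
                "subject_id": list("abcd"),
                "group": ["top"] * 4,
                "rank_level": [2.0, 1.0, 4.0, 3.0],
            }
        )
        maps = np.array([1.0, 2.0, 3.0, 4.0]).reshape(-1, 1, 1, 1)
        res = r_map(Cohort(table=table, maps=maps), one_voxel_mask())
        # covariance table: sum(xc*yc) = 3, sqrt(5*5) = 5 -> r = 0.6
        assert res.data[0, 0, 0] == pytest.approx(0.6, abs=1e-12)

    def test_matches_oracle_on_random_samples(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 15))
            x = rng.standard_normal((n, 1))
            y = rng.standard_normal(n)
            r, _ = pearson_r_vector(x, y)
            assert r[0] == pytest.approx(pearson_r(x[:, 0], y), abs=1e-10)

    def test_p_values_match_t_transform(self, rng):
        n = 12
        x = rng.standard_normal((n, 5))
        y = rng.standard_normal(n)
        r, p = pearson_r_vector(x, y)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        np.testing.assert_allclose(p, 2 * stats.t.sf(np.abs(t), n - 2), atol=1e-12)

    def test_null_r_distribution_matches_analytic(self, rng):
        # permutation oracle: |r| quantiles of value-vs-permuted-covariate
        # match the analytic null (r^2 ~ Beta(1/2, (n-2)/2))
        n, n_perm = 20, 10_000
        x = rng.standard_normal((n, 1))
        y = rng.standard_normal(n)
        rs = np.empty(n_perm)
        for i in range(n_perm):
            rs[i] = pearson_r_vector(x, rng.permutation(y))[0][0]
        for q in (0.5, 0.9, 0.95):
            emp = np.quantile(np.abs(rs), q)
            ana = np.sqrt(stats.beta.ppf(q, 0.5, (n - 2) / 2))
            assert emp == pytest.approx(ana, abs=0.02)

    def test_subset_restriction(self, rng):
        table = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "group": ["top"] * 4 + ["lower"] * 4,
                "rank_level": [1.0, 2.0, 3.0, 4.0, 5.0, 5.0, 5.0, 5.0],
            }
        )
        maps = np.arange(8, dtype=float).reshape(-1, 1, 1, 1)
        res = r_map(Cohort(table=table, maps=maps), one_voxel_mask(), subset="top")
        assert res.df == 2
        with pytest.raises(ValueError, match="constant"):
            r_map(Cohort(table=table, maps=maps), one_voxel_mask(), subset="lower")

    def test_subset_too_small(self):
        table = pd.DataFrame(
            {"subject_id": ["a", "b"], "group": ["top"] * 2, "rank_level": [1.0, 2.0]}
        )
        maps = np.zeros((2, 1, 1, 1))
        with pytest.raises(ValueError, match=">= 3"):
            r_map(Cohort(table=table, maps=maps), one_voxel_mask())


class TestFDR:
    def test_stepup_example(self):
        flags = fdr_bh([0.01, 0.02, 0.03, 0.04, 0.2], q=0.05)
        np.testing.assert_array_equal(flags, [True, True, True, True, False])

    def test_all_tiny_p_rejected(self):
        assert fdr_bh([0.001] * 100, q=0.05).all()

    def test_all_ones_retained(self):
        assert not fdr_bh([1.0] * 10, q=0.05).any()

    def test_empty_input(self):
        assert fdr_bh([], q=0.05).size == 0

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200),
        q=st.floats(min_value=0.01, max_value=0.2),
    )
    def test_matches_stepup_oracle(self, p, q):
        np.testing.assert_array_equal(fdr_bh(p, q), bh_stepup(p, q))

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 201))
            p = rng.random(m) ** rng.uniform(0.5, 3.0)  # varied null/alt mixtures
            np.testing.assert_array_equal(fdr_bh(p, 0.05), bh_stepup(p, 0.05))


class TestClusterFilter:
    def test_isolated_voxel_removed(self):
        sig = np.zeros((10, 10, 10), bool)
        sig[5, 5, 5] = True
        assert cluster_filter(sig, ThresholdSpec()).max() == 0

    def test_extent_threshold_is_strict(self):
        sig = np.zeros((10, 10, 10), bool)
        sig[0:3, 0:3, 0:3] = True  # 27 voxels: survives k > 20
        labels = cluster_filter(sig, ThresholdSpec())
        assert labels.max() == 1
        assert (labels == 1).sum() == 27
        # a 20-voxel blob does not survive the strict k > 20 rule
        sig20 = np.zeros((10, 10, 10), bool)
        sig20[0:4, 0:5, 0] = True
        assert cluster_filter(sig20, ThresholdSpec()).max() == 0
        sig19 = np.zeros((10, 10, 10), bool)
        sig19[0, 0:19, 0] = True
        assert cluster_filter(sig19, ThresholdSpec()).max() == 0

    def test_corner_touching_blobs_depend_on_connectivity(self):
        sig = np.zeros((12, 12, 12), bool)
        sig[0:5, 0:5, 0] = True  # 25 voxels
        sig[5:10, 5:10, 1] = True  # 25 voxels touching only at a cube corner
        assert cluster_filter(sig, ThresholdSpec(cluster_connectivity=26)).max() == 1
        assert cluster_filter(sig, ThresholdSpec(cluster_connectivity=6)).max() == 2

    def test_labels_ordered_by_descending_size(self):
        sig = np.zeros((20, 10, 10), bool)
        sig[0:3, 0:3, 0:3] = True  # 27
        sig[10:14, 0:4, 0:4] = True  # 64
        labels = cluster_filter(sig, ThresholdSpec())
        assert (labels == 1).sum() == 64
        assert (labels == 2).sum() == 27

    def test_union_find_component_count_oracle(self, rng):
        sig = rng.random((8, 8, 8)) > 0.7
        labels = cluster_filter(sig, ThresholdSpec(min_cluster_voxels=0))
        # oracle: union-find over explicit neighbour pairs
        coords = [tuple(c) for c in np.argwhere(sig)]
        parent = {c: c for c in coords}

        def find(c):
            while parent[c] != c:
                parent[c] = parent[parent[c]]
                c = parent[c]
            return c

        for a in coords:
            for da in (-1, 0, 1):
                for db in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if (da, db, dc) == (0, 0, 0):
                            continue
                        b = (a[0] + da, a[1] + db, a[2] + dc)
                        if b in parent:
                            parent[find(a)] = find(b)
        n_components = len({find(c) for c in coords})
        assert labels.max() == n_components


class TestClusterReport:
    def test_empty_report(self, rng):
        stat = t_contrast(cohort_from_values([1, 2], [1, 2]), one_voxel_mask())
        rep = report_clusters(stat, np.zeros((1, 1, 1), int), np.eye(4))
        assert len(rep) == 0

    def _stat_on(self, field):
        from lfcdmap.groupstats import StatMap

        return StatMap(data=np.asarray(field, float), p=np.ones_like(np.asarray(field, float)),
                       df=10, kind="t_two_sample")

    def test_peak_is_max_absolute_statistic(self):
        field = np.zeros((5, 1, 1))
        field[:3, 0, 0] = [2.1, 5.85, 3.0]
        clusters = np.zeros((5, 1, 1), int)
        clusters[:3, 0, 0] = 1
        rep = report_clusters(self._stat_on(field), clusters, np.eye(4))
        assert rep.loc[0, "peak_value"] == pytest.approx(5.85)
        assert rep.loc[0, "voxel_count"] == 3
        np.testing.assert_allclose(
            rep.loc[0, ["peak_x_mm", "peak_y_mm", "peak_z_mm"]].astype(float), [1, 0, 0]
        )

    def test_peak_tie_goes_to_smallest_linear_index(self):
        field = np.zeros((4, 1, 1))
        field[1, 0, 0] = field[3, 0, 0] = -7.0
        clusters = np.ones((4, 1, 1), int)
        rep = report_clusters(self._stat_on(field), clusters, np.eye(4))
        assert rep.loc[0, "peak_x_mm"] == 1.0

    def test_atlas_labels_ordered_by_overlap(self):
        field = np.ones((8, 1, 1))
        clusters = np.ones((8, 1, 1), int)
        atlas = np.zeros((8, 1, 1), int)
        atlas[:3] = 2  # label B: 3 voxels
        atlas[3:8] = 1  # label A: 5 voxels
        rep = report_clusters(
            self._stat_on(field), clusters, np.eye(4), atlas=atlas,
            atlas_names={1: "A", 2: "B"},
        )
        assert rep.loc[0, "region_labels"] == ["A", "B"]

    def test_atlas_grid_mismatch(self):
        field = np.ones((4, 1, 1))
        clusters = np.ones((4, 1, 1), int)
        with pytest.raises(GridCompatibilityError):
            report_clusters(self._stat_on(field), clusters, np.eye(4), atlas=np.zeros((5, 1, 1), int))
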