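"""ISODATA clustering against brute-force and closed-form oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from corallum.isodata import (
    ClusterResult,
    ISODATAParams,
    SectionComparison,
    compare_sections,
    isodata_fit,
    map_clusters_to_sections,
)


def _lloyd(X, centroids, max_iter=100):
    """Reference Lloyd k-means from fixed initial centroids."""
    from scipy.spatial.distance import cdist

    centroids = centroids.copy()
    assign = np.full(len(X), -1)
    for _ in range(max_iter):
        new = np.argmin(cdist(X, centroids), axis=1)
        used = np.unique(new)
        centroids = centroids[used]
        new = np.argmin(cdist(X, centroids), axis=1)
        if np.array_equal(new, assign):
            break
        assign = new
        centroids = np.vstack([X[assign == j].mean(axis=0) for j in range(len(centroids))])
    return assign


def _ari(a, b):
    from sklearn.metrics import adjusted_rand_score

    return adjusted_rand_score(a, b)


def _brute_force_2partition(X):
    """Optimal 2-cluster assignment by exhaustive enumeration of WSS."""
    n = len(X)
    best, best_assign = np.inf, None
    for bits in itertools.product([0, 1], repeat=n - 1):
        assign = np.array((0,) + bits)
        if assign.max() == 0:
            continue
        wss = 0.0
        for j in (0, 1):
            pts = X[assign == j]
            if len(pts) == 0:
                break
            wss += ((pts - pts.mean(axis=0)) ** 2).sum()
        else:
            if wss < best:
                best, best_assign = wss, assign
    return best_assign


class TestISODATAFit:
    def test_separated_1d_points_match_brute_force(self):
        X = np.array([0.0, 0.1, 0.2, 10.0, 10.1])[:, None]
        params = ISODATAParams(
            k_init=2, n_min=1, enable_split=False, enable_merge=False, seed=0
        )
        result = isodata_fit(X, params)
        expected = _brute_force_2partition(X)
        assert result.k_final == 2
        assert _ari(result.assignments, expected) == 1.0

    def test_identical_points_collapse_to_one_cluster(self):
        X = np.zeros((10, 2))
        result = isodata_fit(X, ISODATAParams(k_init=3, n_min=1, seed=1))
        assert result.k_final == 1
        assert result.converged

    def test_four_blobs_recovered_with_split(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], dtype=float)
            X = np.vstack([rng.normal(c, 0.5, size=(50, 2)) for c in centers])
            y = np.repeat(np.arange(4), 50)
            params = ISODATAParams(
                k_init=2, k_desired=4, n_min=5, sigma_split=1.0, d_merge=1.0, seed=seed
            )
            result = isodata_fit(X, params)
            if result.k_final == 4 and _ari(result.assignments, y) == 1.0:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_reduces_to_lloyd_without_split_merge(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(120, 3)) + np.repeat([[0, 0, 0], [4, 4, 0], [0, 4, 4]], 40, axis=0)
        params = ISODATAParams(
            k_init=3, n_min=1, enable_split=False, enable_merge=False, seed=5
        )
        result = isodata_fit(X, params)
        init_idx = np.sort(np.random.default_rng(5).choice(len(X), size=3, replace=False))
        expected = _lloyd(X, X[init_idx].copy())
        assert _ari(result.assignments, expected) == 1.0

    def test_objective_nonincreasing_and_terminates(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 4))
        params = ISODATAParams(k_init=4, n_min=1, enable_split=False, enable_merge=False, seed=3)
        result = isodata_fit(X, params)
        assert len(result.iteration_log) <= params.max_iter
        assert (np.bincount(result.assignments) >= params.n_min).all()

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 0.4, (40, 2)), rng.normal(6, 0.4, (40, 2))])
        perm = rng.permutation(len(X))
        params = ISODATAParams(k_init=2, n_min=1, seed=4)
        a = isodata_fit(X, params)
        b = isodata_fit(X[perm], params)
        # partitions agree up to label names (init differs by row order, but
        # the well-separated optimum is unique)
        assert _ari(a.assignments[perm], b.assignments) == 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="k_init"):
            isodata_fit(np.zeros((2, 2)), ISODATAParams(k_init=5))


class TestSectionMapping:
    @staticmethod
    def _result_and_records(light_sign=1.0):
        rng = np.random.default_rng(0)
        vols = {0: 0.05, 1: 0.4, 2: 0.5, 3: 0.08}  # two small, two large
        xs = {0: -1.0, 1: -1.0, 2: 1.0, 3: 1.0}
        rows, assign = [], []
        for j in range(4):
            for _ in range(30):
                rows.append(
                    {
                        "volume_mm3": vols[j] + rng.normal(0, 0.005),
                        "centroid_x_mm": xs[j] + rng.normal(0, 0.05),
                    }
                )
                assign.append(j)
        result = ClusterResult(
            assignments=np.array(assign), centroids=np.zeros((4, 2)), k_final=4
        )
        return result, pd.DataFrame(rows)

    def test_sections_ordered_by_volume_and_light(self):
        result, records = self._result_and_records()
        mapped = map_clusters_to_sections(result, records)
        by_cluster = mapped.groupby("cluster")["region_id"].first()
        assert by_cluster[0] == 1  # small volume, dark -> low-light mineralization
        assert by_cluster[3] == 4  # small volume, lit -> light mineralization
        assert by_cluster[1] == 2  # large volume, dark -> low-light growth
        assert by_cluster[2] == 3  # large volume, lit -> light growth
        assert sorted(mapped["region_id"].unique()) == [1, 2, 3, 4]

    def test_light_axis_sign_swaps_sections(self):
        result, records = self._result_and_records()
        fwd = map_clusters_to_sections(result, records, light_sign=1.0)
        rev = map_clusters_to_sections(result, records, light_sign=-1.0)
        swap = {1: 4, 4: 1, 2: 3, 3: 2}
        assert (rev["region_id"] == fwd["region_id"].map(swap)).all()

    def test_wrong_cluster_count_rejected(self):
        result, records = self._result_and_records()
        result.k_final = 3
        with pytest.raises(ValueError, match="4 clusters"):
            map_clusters_to_sections(result, records)


def _pooled_t(a, b):
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def _frame(a, b, feature="volume_mm3"):
    return pd.DataFrame(
        {feature: np.concatenate([a, b]), "region_id": [1] * len(a) + [2] * len(b)}
    )


class TestCompareSections:
    def test_worked_example(self):
        cmp = compare_sections(_frame([1, 2, 3], [2, 3, 4]), "volume_mm3", (1, 2))
        assert cmp.t_statistic == pytest.approx(-1.2247, abs=2e-4)
        assert cmp.df == 4
        assert cmp.p_value == pytest.approx(0.2878, abs=2e-3)
        assert not cmp.significant

    def test_identical_groups(self):
        cmp = compare_sections(_frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]), "volume_mm3", (1, 2))
        assert cmp.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value == pytest.approx(1.0, abs=1e-12)

    def test_separated_groups_significant(self):
        cmp = compare_sections(_frame([0, 0, 0.1], [10, 10, 10.1]), "volume_mm3", (1, 2))
        assert cmp.significant and cmp.p_value < 0.05

    def test_matches_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(3, 30))
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(3, 30))
            cmp = compare_sections(_frame(a, b), "volume_mm3", (1, 2))
            t, df, p = _pooled_t(a, b)
            assert cmp.t_statistic == pytest.approx(t, abs=1e-9)
            assert cmp.df == df
            assert cmp.p_value == pytest.approx(p, abs=1e-9)

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.2, 10)
        b = rng.normal(1, 5.0, 40)
        student = compare_sections(_frame(a, b), "volume_mm3", (1, 2), test="student")
        welch = compare_sections(_frame(a, b), "volume_mm3", (1, 2), test="welch")
        assert welch.df != student.df

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_sections(_frame([1.0], [1.0, 2.0]), "volume_mm3", (1, 2))
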