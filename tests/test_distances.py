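"""Lineage distance statistics: combinatorics, ratios, location tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yeastmorph.distances import (InsufficientDataError, cell_volume_from_area,
                                  cross_distance_ratio, euclidean_distance,
                                  group_location_test,
                                  hybrid_midparent_distances,
                                  lineage_edge_distances, midparent_points,
                                  segregant_ratios, strain_pair_distances)
from yeastmorph.pca import build_pca


def _identity_space(dim=4, seed=0):
    """A full-rank space over `dim` pseudo-traits (for score-space tests)."""
    rng = np.random.default_rng(seed)
    z = pd.DataFrame(rng.normal(size=(dim + 15, dim)),
                     columns=[f"t{i}" for i in range(dim)])
    return build_pca(z), z.columns


def _rows(arr, cols):
    return pd.DataFrame(np.atleast_2d(arr), columns=cols)


class TestEuclideanDistance:
    def test_self_distance_zero(self):
        assert euclidean_distance([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_3_4_5_triangle(self):
        assert euclidean_distance([0.0, 0.0], [3.0, 4.0]) == pytest.approx(5.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            euclidean_distance([1.0], [1.0, 2.0])

    def test_full_rank_pc_distance_equals_z_distance(self):
        space, cols = _identity_space(dim=6, seed=3)
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 6))
        d = strain_pair_distances(space, _rows(a, cols), _rows(b, cols),
                                  ccr_threshold=1.0)
        assert d.distances[0] == pytest.approx(
            euclidean_distance(a, b), abs=1e-8)


class TestReplicateCombinatorics:
    def test_five_by_five_gives_25(self):
        space, cols = _identity_space()
        rng = np.random.default_rng(5)
        x = _rows(rng.normal(size=(5, 4)), cols)
        y = _rows(rng.normal(size=(5, 4)), cols)
        d = strain_pair_distances(space, x, y, ccr_threshold=1.0)
        assert d.n_pairs == 25

    def test_3_by_4_gives_12(self):
        space, cols = _identity_space()
        rng = np.random.default_rng(6)
        d = strain_pair_distances(space, _rows(rng.normal(size=(3, 4)), cols),
                                  _rows(rng.normal(size=(4, 4)), cols))
        assert d.n_pairs == 12

    def test_identical_points_mean_and_sd_zero(self):
        space, cols = _identity_space()
        p = np.ones((4, 4))
        d = strain_pair_distances(space, _rows(p, cols), _rows(p, cols))
        assert d.mean == 0.0 and d.sd == 0.0

    def test_empty_replicates_rejected(self):
        space, cols = _identity_space()
        with pytest.raises(InsufficientDataError):
            strain_pair_distances(space, _rows(np.empty((0, 4)), cols),
                                  _rows(np.ones((2, 4)), cols))

    def test_midparent_25_points_and_mean_rule(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(2, 5, 3))
        mids = midparent_points(a, b)
        assert mids.shape == (25, 3)
        assert np.allclose(mids[0], (a[0] + b[0]) / 2)
        single = midparent_points(np.array([[0.0, 0.0]]),
                                  np.array([[2.0, 2.0]]))
        assert np.allclose(single, [[1.0, 1.0]])

    def test_identical_parents_midpoints_at_parent(self):
        p = np.tile([1.0, -2.0], (3, 1))
        assert np.allclose(midparent_points(p, p), [1.0, -2.0])

    def test_hybrid_combinations_125_and_6(self):
        rng = np.random.default_rng(8)
        mids = midparent_points(rng.normal(size=(5, 4)),
                                rng.normal(size=(5, 4)))
        d = hybrid_midparent_distances(rng.normal(size=(5, 4)), mids)
        assert d.n_pairs == 125
        d2 = hybrid_midparent_distances(rng.normal(size=(2, 4)),
                                        rng.normal(size=(3, 4)))
        assert d2.n_pairs == 6

    def test_symmetry_of_pair_distances(self):
        space, cols = _identity_space()
        rng = np.random.default_rng(9)
        x = _rows(rng.normal(size=(3, 4)), cols)
        y = _rows(rng.normal(size=(4, 4)), cols)
        dxy = strain_pair_distances(space, x, y)
        dyx = strain_pair_distances(space, y, x)
        assert np.allclose(np.sort(dxy.distances), np.sort(dyx.distances))


class TestCrossDistanceRatio:
    def test_hybrid_at_midpoint_ratio_zero(self):
        space, cols = _identity_space()
        a = _rows([0.0, 0.0, 0.0, 0.0], cols)
        b = _rows([2.0, 0.0, 0.0, 0.0], cols)
        h = _rows([1.0, 0.0, 0.0, 0.0], cols)
        r = cross_distance_ratio(a, b, h, space, ccr_threshold=1.0)
        assert r.n == 1
        assert r.mean == pytest.approx(0.0, abs=1e-10)

    def test_hybrid_at_parent_ratio_half(self):
        space, cols = _identity_space()
        a = _rows([0.0, 0.0, 0.0, 0.0], cols)
        b = _rows([2.0, 0.0, 0.0, 0.0], cols)
        r = cross_distance_ratio(a, b, a, space, ccr_threshold=1.0)
        assert r.mean == pytest.approx(0.5, abs=1e-10)

    def test_counts_nh_na_nb(self):
        space, cols = _identity_space()
        rng = np.random.default_rng(10)
        r = cross_distance_ratio(
            _rows(rng.normal(size=(5, 4)), cols),
            _rows(rng.normal(size=(5, 4)), cols),
            _rows(rng.normal(size=(5, 4)), cols), space)
        assert r.n == 125

    def test_coincident_parents_rejected(self):
        space, cols = _identity_space()
        p = _rows(np.ones((2, 4)), cols)
        with pytest.raises(ZeroDivisionError):
            cross_distance_ratio(p, p, p, space)

    def test_mean_ratio_monotone_in_deviation(self):
        space, cols = _identity_space()
        rng = np.random.default_rng(11)
        a = rng.normal(size=(5, 4))
        b = rng.normal(size=(5, 4)) + 3.0
        mid = (a.mean(axis=0) + b.mean(axis=0)) / 2
        means = []
        for sigma in (0.1, 1.0, 3.0):
            h = mid + rng.normal(0, sigma, size=(5, 4))
            r = cross_distance_ratio(_rows(a, cols), _rows(b, cols),
                                     _rows(h, cols), space, ccr_threshold=1.0)
            means.append(r.mean)
        assert means[0] < means[1] < means[2]

    def test_scale_equivariance(self):
        """Scaling all scores by λ scales distances by λ, ratios not at all."""
        space, cols = _identity_space()
        rng = np.random.default_rng(12)
        a, b, h = rng.normal(size=(3, 5, 4))
        lam = 3.7
        d1 = hybrid_midparent_distances(h, midparent_points(a, b))
        d2 = hybrid_midparent_distances(lam * h,
                                        midparent_points(lam * a, lam * b))
        assert np.allclose(d2.distances, lam * d1.distances)
        r1 = cross_distance_ratio(_rows(a, cols), _rows(b, cols),
                                  _rows(h, cols), space, ccr_threshold=1.0)
        r2 = cross_distance_ratio(_rows(lam * a, cols), _rows(lam * b, cols),
                                  _rows(lam * h, cols), space,
                                  ccr_threshold=1.0)
        assert np.allclose(r1.ratios, r2.ratios, atol=1e-10)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_triangle_inequality_on_strain_means(seed):
    rng = np.random.default_rng(seed)
    x, y, z = rng.normal(size=(3, 6))
    assert euclidean_distance(x, z) <= (
        euclidean_distance(x, y) + euclidean_distance(y, z) + 1e-12)


class TestGroupLocationTest:
    def test_identical_groups_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = group_location_test(x, x)
        assert p > 0.95

    def test_exact_enumeration_u0_p01(self):
        """{1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 2/20 = 0.1."""
        u, p = group_location_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_power_at_two_sd_shift(self):
        rng = np.random.default_rng(13)
        rejections = 0
        for _ in range(500):
            x = rng.normal(0, 1, 12)
            y = rng.normal(2.0, 1, 15)
            _, p = group_location_test(x, y)
            rejections += (p < 0.05)
        assert rejections / 500 > 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            group_location_test([], [1.0])


class TestCellVolume:
    def test_sphere_identity(self):
        r = 2.5
        area = np.pi * r**2
        assert cell_volume_from_area(area) == pytest.approx(
            4.0 / 3.0 * np.pi * r**3, rel=1e-12)

    def test_doubling_area_multiplies_volume_by_2sqrt2(self):
        v1 = cell_volume_from_area(3.0)
        v2 = cell_volume_from_area(6.0)
        assert v2 / v1 == pytest.approx(2 * np.sqrt(2), rel=1e-12)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            cell_volume_from_area(0.0)

    def test_vectorized(self):
        v = cell_volume_from_area(np.array([1.0, 4.0]))
        assert v.shape == (2,)
        assert v[1] / v[0] == pytest.approx(8.0)


def test_segregant_ratios_zero_when_on_midline():
    a = np.array([[0.0, 0.0]])
    b = np.array([[2.0, 2.0]])
    segs = np.tile([1.0, 1.0], (4, 1))
    assert np.allclose(segregant_ratios(a, b, segs), 0.0)


def test_lineage_edge_distances_reports_all_events(small_cohort):
    from yeastmorph.glm import replicate_z_matrix, strain_z_matrix
    table, lineage, _, _ = small_cohort
    sz = strain_z_matrix(table)
    rz = replicate_z_matrix(table)
    common = [t for t in sz.z.columns if t in set(rz.z.columns)]
    space = build_pca(sz.z[common])
    df = lineage_edge_distances(space, rz.z[common], lineage)
    # spontaneous + mutagen single-parent rows, cross: midparent + 2 parents
    assert set(df["child"]) == {"C", "M", "H"}
    assert len(df[df["child"] == "H"]) == 3
    cross_mid = df[(df["child"] == "H") & (df["comparison"] == "midparent")]
    assert int(cross_mid["n_pairs"].iloc[0]) == 125
    singles = df[df["comparison"] == "parent"]
    assert (singles[singles["child"].isin(["C", "M"])]["n_pairs"] == 25).all()
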