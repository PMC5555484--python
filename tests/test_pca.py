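"""The PCA phenotype space: CCR, projection, isometry, variance ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yeastmorph.pca import (DegenerateSpaceError, SchemaError, build_pca,
                            components_for_ccr, group_traits_by_reference_pca,
                            project, variance_ratio)


def _orthogonal_data(variances, n=32, seed=0):
    """Rows whose sample covariance is exactly diag(variances)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(variances)))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)            # orthonormal columns, mean ~0 kept below
    Q -= Q.mean(axis=0)
    Q, _ = np.linalg.qr(Q)
    X = Q * np.sqrt((n - 1) * np.asarray(variances))
    return pd.DataFrame(X, columns=[f"t{i}" for i in range(len(variances))])


class TestBuildPca:
    def test_exact_variance_shares_4_3_2_1(self):
        z = _orthogonal_data([4.0, 3.0, 2.0, 1.0])
        space = build_pca(z)
        shares = space.explained_variance / space.explained_variance.sum()
        assert np.allclose(shares, [0.4, 0.3, 0.2, 0.1], atol=1e-10)
        assert np.allclose(space.ccr, [0.4, 0.7, 0.9, 1.0], atol=1e-10)

    def test_collinear_rows_have_rank_one(self):
        t = np.linspace(-1, 1, 7)
        z = pd.DataFrame(np.outer(t, [1.0, 2.0, -1.0]),
                         columns=["a", "b", "c"])
        space = build_pca(z)
        assert space.n_components == 1

    def test_identical_rows_rejected(self):
        z = pd.DataFrame(np.ones((4, 3)), columns=list("abc"))
        with pytest.raises(DegenerateSpaceError):
            build_pca(z)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        z = pd.DataFrame(rng.normal(size=(10, 6)))
        L = build_pca(z).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_sign_convention_is_row_order_invariant(self):
        rng = np.random.default_rng(2)
        z = pd.DataFrame(rng.normal(size=(9, 5)))
        s1 = build_pca(z)
        s2 = build_pca(z.iloc[::-1])
        pd.testing.assert_frame_equal(s1.loadings, s2.loadings,
                                      atol=1e-10, rtol=0)

    def test_full_space_isometry(self):
        rng = np.random.default_rng(3)
        z = pd.DataFrame(rng.normal(size=(12, 30)))
        space = build_pca(z)
        scores = project(space, z).to_numpy()
        X = z.to_numpy()
        for i in range(len(z)):
            for j in range(i + 1, len(z)):
                assert np.linalg.norm(scores[i] - scores[j]) == pytest.approx(
                    np.linalg.norm(X[i] - X[j]), abs=1e-8)


class TestComponentsForCcr:
    def test_threshold_one_gives_full_rank(self):
        z = _orthogonal_data([4.0, 3.0, 2.0, 1.0])
        space = build_pca(z)
        assert components_for_ccr(space, 1.0) == 4

    def test_exact_shares_thresholds(self):
        space = build_pca(_orthogonal_data([4.0, 3.0, 2.0, 1.0]))
        assert components_for_ccr(space, 0.6) == 2
        assert components_for_ccr(space, 0.9) == 3
        assert components_for_ccr(space, 0.05) == 1  # below the first share

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0), st.integers(0, 999))
    def test_monotone_in_threshold(self, t1, t2, seed):
        rng = np.random.default_rng(seed)
        space = build_pca(pd.DataFrame(rng.normal(size=(8, 10))))
        lo, hi = sorted((t1, t2))
        assert components_for_ccr(space, lo) <= components_for_ccr(space, hi)


class TestProject:
    def test_training_rows_reproduce_scores(self):
        rng = np.random.default_rng(4)
        z = pd.DataFrame(rng.normal(size=(8, 5)))
        space = build_pca(z)
        s1 = project(space, z)
        s2 = project(space, z)
        pd.testing.assert_frame_equal(s1, s2)

    def test_center_projects_to_origin(self):
        rng = np.random.default_rng(5)
        z = pd.DataFrame(rng.normal(size=(8, 5)),
                         columns=[f"t{i}" for i in range(5)])
        space = build_pca(z)
        center = pd.DataFrame([space.center], columns=z.columns)
        assert np.allclose(project(space, center).to_numpy(), 0.0, atol=1e-10)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(6)
        z = pd.DataFrame(rng.normal(size=(9, 6)),
                         columns=[f"t{i}" for i in range(6)])
        space = build_pca(z)
        scores = project(space, z).to_numpy()
        recon = scores @ space.loadings.to_numpy().T + space.center.to_numpy()
        assert np.allclose(recon, z.to_numpy(), atol=1e-8)

    def test_trait_mismatch_raises(self):
        rng = np.random.default_rng(7)
        z = pd.DataFrame(rng.normal(size=(6, 4)),
                         columns=[f"t{i}" for i in range(4)])
        space = build_pca(z)
        other = z.rename(columns={"t3": "other"})
        with pytest.raises(SchemaError):
            project(space, other)


class TestVarianceRatio:
    def test_identical_populations_ratio_one(self):
        rng = np.random.default_rng(8)
        s = pd.DataFrame(rng.normal(size=(20, 5)))
        ratios, cum = variance_ratio(s, s, upto=5)
        assert np.allclose(ratios, 1.0)
        assert cum == pytest.approx(1.0)

    def test_doubling_scores_quadruples_variance(self):
        rng = np.random.default_rng(9)
        s = pd.DataFrame(rng.normal(size=(20, 5)))
        ratios, cum = variance_ratio(2 * s, s, upto=5)
        assert np.allclose(ratios, 4.0)
        assert cum == pytest.approx(4.0)

    def test_known_per_axis_variances_recovered(self):
        rng = np.random.default_rng(10)
        n = 200
        a = pd.DataFrame(rng.normal(0, [2.0, 1.0, 0.5], size=(n, 3)))
        b = pd.DataFrame(rng.normal(0, [1.0, 1.0, 1.0], size=(n, 3)))
        ratios, _ = variance_ratio(a, b, upto=3)
        assert np.allclose(ratios, [4.0, 1.0, 0.25], rtol=0.35)

    def test_zero_denominator_variance(self):
        a = pd.DataFrame(np.random.default_rng(11).normal(size=(5, 2)))
        b = pd.DataFrame(np.zeros((5, 2)))
        with pytest.raises(ZeroDivisionError):
            variance_ratio(a, b, upto=2)


class TestGroupTraits:
    def test_perfectly_correlated_traits_form_one_group(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=10)
        z = pd.DataFrame({"a": base, "b": 2 * base + 1})
        groups = group_traits_by_reference_pca(z, ["a", "b"])
        assert groups == [["a", "b"]]

    def test_two_orthogonal_blocks_recovered(self):
        rng = np.random.default_rng(13)
        f1, f2 = rng.normal(size=(2, 40))
        z = pd.DataFrame({
            "a1": 3 * f1 + 0.01 * rng.normal(size=40),
            "a2": 3 * f1 + 0.01 * rng.normal(size=40),
            "b1": 3 * f2 + 0.01 * rng.normal(size=40),
            "b2": 3 * f2 + 0.01 * rng.normal(size=40),
        })
        groups = group_traits_by_reference_pca(z, ["a1", "a2", "b1", "b2"])
        as_sets = {frozenset(g) for g in groups}
        assert frozenset({"a1", "a2"}) in as_sets
        assert frozenset({"b1", "b2"}) in as_sets

    def test_single_candidate_is_singleton_group(self):
        rng = np.random.default_rng(14)
        z = pd.DataFrame({"a": rng.normal(size=5)})
        assert group_traits_by_reference_pca(z, ["a"]) == [["a"]]

    def test_too_few_replicates_rejected(self):
        z = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="3 reference replicates"):
            group_traits_by_reference_pca(z, ["a", "b"])
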