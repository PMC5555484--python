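"""GLM fitting, Wald Z-profiles, AIC selection, and the LRT screen."""

import numpy as np
import pandas as pd
import pytest

from yeastmorph.glm import (BETA, GAMMA, GAUSSIAN, DesignError, FitError,
                            bonferroni_wald_screen, fit_trait_glm, lrt_screen,
                            medium_adjusted_z, replicate_z_matrix,
                            select_model_aic, strain_z_matrix, wald_z)
from yeastmorph.io import TraitTable
from tests.conftest import make_catalog


def _two_group_design(n_ref=11, n_s=5):
    return pd.DataFrame({"strain": ["ref"] * n_ref + ["s"] * n_s})


class TestGaussianOracle:
    def test_coefficient_is_difference_of_group_means(self):
        y = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
        design = pd.DataFrame({"strain": ["ref"] * 3 + ["s"] * 3})
        fit = fit_trait_glm(y, design, GAUSSIAN,
                            reference_levels={"strain": "ref"})
        assert fit.coefficients["strain[s]"] == pytest.approx(6.0, abs=1e-10)
        assert fit.coefficients["intercept"] == pytest.approx(2.0, abs=1e-10)

    def test_wald_z_equals_closed_form_ols(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            y = rng.normal(0, 1, 16)
            design = _two_group_design()
            fit = fit_trait_glm(y, design, GAUSSIAN,
                                reference_levels={"strain": "ref"})
            X = np.column_stack([np.ones(16),
                                 np.r_[np.zeros(11), np.ones(5)]])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            rss = float(((y - X @ beta) ** 2).sum())
            se = np.sqrt(np.linalg.inv(X.T @ X)[1, 1] * rss / (16 - 2))
            assert wald_z(fit, "strain[s]") == pytest.approx(
                beta[1] / se, abs=1e-8)

    def test_equal_group_means_give_zero_z(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        design = pd.DataFrame({"strain": ["ref"] * 3 + ["s"] * 3})
        fit = fit_trait_glm(y, design, GAUSSIAN,
                            reference_levels={"strain": "ref"})
        assert fit.coefficients["strain[s]"] == pytest.approx(0.0, abs=1e-12)
        assert wald_z(fit, "strain[s]") == pytest.approx(0.0, abs=1e-12)

    def test_aic_identity(self):
        y = np.random.default_rng(0).normal(0, 1, 16)
        fit = fit_trait_glm(y, _two_group_design(), GAUSSIAN,
                            reference_levels={"strain": "ref"})
        assert fit.aic == pytest.approx(
            -2 * fit.log_likelihood + 2 * fit.n_params, abs=1e-12)


def test_gamma_multiplicative_effect_recovery():
    """exp(beta) = 1.5 simulated at n = 200: estimate within 3 SE of log 1.5."""
    rng = np.random.default_rng(11)
    n = 200
    mu = np.r_[np.full(n // 2, 10.0), np.full(n // 2, 15.0)]
    shape = 25.0
    y = rng.gamma(shape, mu / shape)
    design = pd.DataFrame({"strain": ["ref"] * (n // 2) + ["s"] * (n // 2)})
    fit = fit_trait_glm(y, design, GAMMA, reference_levels={"strain": "ref"})
    b = fit.coefficients["strain[s]"]
    se = fit.standard_errors["strain[s]"]
    assert abs(b - np.log(1.5)) < 3 * se


def test_beta_fit_handles_boundary_values():
    rng = np.random.default_rng(3)
    y = np.r_[rng.beta(8, 12, 14), [0.0, 1.0]]
    design = pd.DataFrame({"strain": ["ref"] * 11 + ["s"] * 5})
    counts = np.full(16, 300)
    fit = fit_trait_glm(y, design, BETA, reference_levels={"strain": "ref"},
                        cell_counts=counts)
    assert np.isfinite(wald_z(fit, "strain[s]"))


def test_singular_design_rejected():
    y = np.arange(6.0)
    design = pd.DataFrame({"strain": ["a"] * 3 + ["b"] * 3,
                           "medium": ["x"] * 3 + ["y"] * 3})  # confounded
    with pytest.raises(DesignError, match="singular"):
        fit_trait_glm(y, design, GAUSSIAN)


class TestAicSelection:
    CANDIDATES = [((), False), (("strain",), False),
                  (("strain", "medium"), False), (("strain", "medium"), True)]

    def _design(self, n):
        rng = np.random.default_rng(5)
        return pd.DataFrame({
            "strain": np.where(np.arange(n) < n // 2, "ref", "s"),
            "medium": rng.choice(["YPD", "SD"], size=n),
        })

    def test_strain_effect_selects_strain_design(self):
        rng = np.random.default_rng(6)
        n = 100
        design = self._design(n)
        wins = 0
        for _ in range(40):
            y = rng.normal(0, 1, n) + np.where(design["strain"] == "s", 2.0, 0)
            (terms, inter), _ = select_model_aic(y, design, self.CANDIDATES,
                                                 GAUSSIAN)
            wins += (set(terms) == {"strain"} and not inter)
        assert wins > 20

    def test_pure_noise_selects_intercept_majority(self):
        rng = np.random.default_rng(8)
        n = 100
        design = self._design(n)
        wins = 0
        for _ in range(40):
            y = rng.normal(0, 1, n)
            (terms, inter), _ = select_model_aic(y, design, self.CANDIDATES,
                                                 GAUSSIAN)
            wins += (terms == ())
        assert wins > 20

    def test_selection_is_lexicographic_min_of_aic_then_params(self):
        rng = np.random.default_rng(9)
        n = 60
        design = self._design(n)
        y = rng.normal(0, 1, n)
        chosen, chosen_fit = select_model_aic(y, design, self.CANDIDATES,
                                              GAUSSIAN)
        fits = {}
        for terms, inter in self.CANDIDATES:
            sub = design[list(terms)] if terms else design.iloc[:, :0]
            fits[(terms, inter)] = fit_trait_glm(y, sub, GAUSSIAN, inter)
        best = min(fits, key=lambda c: (round(fits[c].aic, 9),
                                        fits[c].n_params))
        assert chosen == best
        assert chosen_fit.aic == pytest.approx(fits[best].aic)


class TestLrtScreen:
    def _fits(self, effects: dict[str, float], n=16, seed=0):
        rng = np.random.default_rng(seed)
        design = _two_group_design()
        full, reduced = {}, {}
        for tid, eff in effects.items():
            y = rng.normal(0, 1, n)
            y[11:] += eff
            full[tid] = fit_trait_glm(y, design, GAUSSIAN,
                                      reference_levels={"strain": "ref"},
                                      trait_id=tid)
            reduced[tid] = fit_trait_glm(y, design.iloc[:, :0], GAUSSIAN,
                                         trait_id=tid)
        return full, reduced

    def test_equal_likelihood_fits_give_empty_set(self):
        # an added term with zero likelihood gain: LR statistic 0, never a hit
        import dataclasses
        _, reduced = self._fits({"t0": 0.0, "t1": 0.0}, seed=1)
        full = {
            tid: dataclasses.replace(
                fit,
                coefficients={**fit.coefficients, "strain[s]": 0.0},
                n_params=fit.n_params + 1,
            )
            for tid, fit in reduced.items()
        }
        assert lrt_screen(full, reduced, alpha=0.05) == set()

    def test_huge_effect_among_nulls_is_the_only_hit(self):
        effects = {f"null{i}": 0.0 for i in range(50)}
        effects["hit"] = 8.0
        full, reduced = self._fits(effects, seed=12)
        assert lrt_screen(full, reduced, alpha=0.05) == {"hit"}

    def test_alpha_one_no_correction_returns_all(self):
        effects = {f"t{i}": 0.0 for i in range(5)}
        full, reduced = self._fits(effects, seed=13)
        assert lrt_screen(full, reduced, alpha=1.0, correction="none") == set(
            effects)

    def test_non_nested_designs_rejected(self):
        full, reduced = self._fits({"t0": 0.0})
        with pytest.raises(DesignError, match="nested"):
            lrt_screen(reduced, full)  # swapped: "full" has fewer params


def test_bonferroni_screen_never_exceeds_unadjusted_alpha():
    """A trait flagged at alpha/m always has unadjusted p below alpha."""
    rng = np.random.default_rng(21)
    design = _two_group_design()
    fits = {}
    for i in range(30):
        y = rng.normal(0, 1, 16)
        y[11:] += rng.choice([0.0, 3.0])
        fits[f"t{i}"] = fit_trait_glm(y, design, GAUSSIAN,
                                      reference_levels={"strain": "ref"},
                                      trait_id=f"t{i}")
    alpha = 0.05
    for tid in bonferroni_wald_screen(fits, "strain[s]", alpha):
        assert fits[tid].wald_p("strain[s]") <= alpha


# --------------------------------------------------------------------------
# Z matrices
# --------------------------------------------------------------------------

def _gaussian_only_table(n_media=1, medium_shift=0.0, seed=0):
    cat = make_catalog(3, 0, 0, 0)
    rng = np.random.default_rng(seed)
    rows = []
    media = ["YPD", "SD"][:n_media]
    for strain in ("reference", "s1"):
        strain_media = media if strain == "reference" else media[:1]
        for medium in strain_media:
            for rep in range(6):
                shift = medium_shift if medium == "SD" else 0.0
                vals = rng.normal(0, 1, 3) + shift + \
                    (1.0 if strain == "s1" else 0.0)
                rows.append([strain, f"{medium}-r{rep}", medium, 250, *vals])
    df = pd.DataFrame(rows, columns=["strain", "replicate", "medium",
                                     "cell_count", *cat.trait_ids])
    return TraitTable(df, cat)


def test_strain_z_reference_row_is_zero(small_table):
    z = strain_z_matrix(small_table)
    ref = z.z.loc["reference"]
    assert np.allclose(ref.to_numpy(dtype=float), 0.0)


def test_medium_adjustment_invariant_to_additive_shift():
    """An additive medium shift on a gaussian trait leaves strain Z unchanged."""
    z_plain = medium_adjusted_z(_gaussian_only_table(2, 0.0, seed=5))
    z_shift = medium_adjusted_z(_gaussian_only_table(2, 7.0, seed=5))
    assert np.allclose(z_plain.z.loc["s1"], z_shift.z.loc["s1"], atol=1e-8)


def test_single_medium_adjustment_equals_one_way_fit():
    table = _gaussian_only_table(1, seed=6)
    z1 = strain_z_matrix(table)
    z2 = medium_adjusted_z(table)
    assert np.allclose(z1.z.to_numpy(float), z2.z.to_numpy(float), atol=1e-10)


def test_confounded_medium_raises():
    table = _gaussian_only_table(2, seed=7)
    df = table.data.copy()
    # strip the reference's SD-medium records: SD now lacks reference obs
    df.loc[(df["strain"] == "s1"), "medium"] = "EMM"
    with pytest.raises(DesignError, match="confounded|reference"):
        medium_adjusted_z(TraitTable(df, table.catalog))


def test_replicate_z_invariant_to_replicate_relabeling(small_table):
    z1 = replicate_z_matrix(small_table)
    shuffled = small_table.data.copy()
    rng = np.random.default_rng(0)
    for strain, group in shuffled.groupby("strain"):
        labels = group["replicate"].to_numpy().copy()
        rng.shuffle(labels)
        shuffled.loc[group.index, "replicate"] = labels
    z2 = replicate_z_matrix(TraitTable(shuffled, small_table.catalog))
    # relabeling replicates permutes rows within a strain but leaves the
    # multiset of Z rows unchanged
    for strain in small_table.strains:
        a = np.sort(z1.z.xs(strain, level="strain").to_numpy(float), axis=0)
        b = np.sort(z2.z.xs(strain, level="strain").to_numpy(float), axis=0)
        assert np.allclose(a, b, atol=1e-12)


def test_replicate_z_reference_is_null_calibrated(small_table):
    z = replicate_z_matrix(small_table)
    ref = z.z.xs("reference", level="strain")
    assert abs(float(ref.mean().mean())) < 0.2
    assert 0.5 < float(ref.std().mean()) < 1.5
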