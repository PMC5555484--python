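"""Reproducibility benchmarks: each function recomputes, from scratch, one
of the package's verifiable quantities — the replicate-combinatoric counts
of the distance procedure, the catalog constants, numerical-identity checks
(PC-space isometry, Wald-vs-OLS agreement), and the calibration/power of the
statistical machinery on seeded synthetic cohorts.

Every function takes a seed and derives all of its randomness from it, so a
run is reproducible end to end.  Problem sizes are the package's defaults
(5 replicates per strain, 11 reference replicates, the full 501-trait
panel); cohort counts per benchmark are documented in docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import default_catalog
from .clustering import average_linkage_hca, bootstrap_support
from .distances import (cross_distance_ratio, group_location_test,
                        hybrid_midparent_distances, midparent_points,
                        segregant_ratios, strain_pair_distances)
from .glm import (GAUSSIAN, bonferroni_wald_screen, fit_strain_glms,
                  fit_trait_glm, replicate_z_matrix, strain_z_matrix, wald_z)
from .pca import build_pca, components_for_ccr, project
from .robustness import dunnett_vs_control, pp_by_strain
from .simulate import (BreedingEvent, SyntheticSpec, generate_cohort,
                       generate_segregant_panel, null_spec)


def _derive(seed: int, salt: int) -> int:
    """Independent child seed below 2**31."""
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# combinatorics of the distance procedure
# ---------------------------------------------------------------------------

def combinatoric_counts(seed: int) -> dict[str, int]:
    """Distance-multiset sizes for a 5-replicate cohort.

    Runs the full normalize→PCA→distance path on one synthetic cohort with
    5 replicates per strain and counts the strain-pair distances, mid-parent
    points, and hybrid-to-midpoint distances of one cross.
    """
    spec = SyntheticSpec(seed=_derive(seed, 1))
    table, lineage, _, _ = generate_cohort(spec)
    sz = strain_z_matrix(table)
    rz = replicate_z_matrix(table)
    common = [t for t in sz.z.columns if t in set(rz.z.columns)]
    space = build_pca(sz.z[common])
    rep = lambda s: rz.z[common].xs(s, level="strain")  # noqa: E731
    k = components_for_ccr(space, 0.9)
    pair = strain_pair_distances(space, rep("K601"), rep("K6"), 0.9)
    sa = project(space, rep("K9"), n_components=k).to_numpy()
    sb = project(space, rep("K10"), n_components=k).to_numpy()
    mids = midparent_points(sa, sb)
    sh = project(space, rep("K13"), n_components=k).to_numpy()
    hyb = hybrid_midparent_distances(sh, mids)
    return {
        "n_strain_pair_distances": pair.n_pairs,
        "n_midparent_points": len(mids),
        "n_hybrid_midparent_distances": hyb.n_pairs,
    }


def catalog_constants() -> dict[str, int]:
    cat = default_catalog()
    return {"n_traits": cat.n_traits, "n_noise_traits": cat.n_noise_traits}


# ---------------------------------------------------------------------------
# numerical identities
# ---------------------------------------------------------------------------

def isometry_max_error(seed: int, n_rows: int = 30, n_traits: int = 501) -> float:
    """Max |d_PC − d_Z| over all row pairs, full-rank component space."""
    rng = np.random.default_rng(_derive(seed, 2))
    z = pd.DataFrame(rng.normal(size=(n_rows, n_traits)),
                     columns=[f"t{i}" for i in range(n_traits)])
    space = build_pca(z)
    scores = project(space, z).to_numpy()
    zc = z.to_numpy()
    err = 0.0
    for i in range(n_rows):
        for j in range(i + 1, n_rows):
            d_pc = np.linalg.norm(scores[i] - scores[j])
            d_z = np.linalg.norm(zc[i] - zc[j])
            err = max(err, abs(d_pc - d_z))
    return float(err)


def gaussian_wald_vs_ols(seed: int, n_fixtures: int = 20) -> float:
    """Max |Z_GLM − Z_OLS| over random balanced two-group gaussian fixtures."""
    rng = np.random.default_rng(_derive(seed, 3))
    worst = 0.0
    for _ in range(n_fixtures):
        n_ref, n_s = 11, 5
        y = rng.normal(rng.normal(0, 1), 1.0, n_ref + n_s)
        design = pd.DataFrame({"strain": ["ref"] * n_ref + ["s"] * n_s})
        fit = fit_trait_glm(y, design, GAUSSIAN,
                            reference_levels={"strain": "ref"})
        z_glm = wald_z(fit, "strain[s]")
        X = np.column_stack([np.ones(n_ref + n_s),
                             np.r_[np.zeros(n_ref), np.ones(n_s)]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        rss = float(((y - X @ beta) ** 2).sum())
        cov = np.linalg.inv(X.T @ X) * rss / (len(y) - 2)
        z_ols = beta[1] / np.sqrt(cov[1, 1])
        worst = max(worst, abs(z_glm - z_ols))
    return float(worst)


# ---------------------------------------------------------------------------
# calibration and power on synthetic cohorts
# ---------------------------------------------------------------------------

def bonferroni_family_wise_error(seed: int, n_datasets: int = 200,
                                 alpha: float = 0.05) -> float:
    """Family-wise false-positive rate of the Bonferroni Wald screen.

    Each dataset is a null cohort (one strain with zero effect on all 501
    traits vs the reference); the screen tests the strain contrast on every
    trait at alpha with Bonferroni correction.  Returns the fraction of
    datasets where any trait is flagged.
    """
    base = _derive(seed, 4)
    hits = 0
    for i in range(n_datasets):
        table, *_ = generate_cohort(null_spec(seed=(base + i) % (2**31)))
        fits = fit_strain_glms(table)
        if bonferroni_wald_screen(fits, "strain[S1]", alpha):
            hits += 1
    return hits / n_datasets


def _two_child_spec(seed: int) -> SyntheticSpec:
    events = (
        BreedingEvent("child_spont", ("P",), "spontaneous"),
        BreedingEvent("child_mutagen", ("P",), "mutagen"),
    )
    return SyntheticSpec(founders=("P",), events=events, seed=seed)


def mutagen_vs_spontaneous_rate(seed: int, n_cohorts: int = 100) -> float:
    """How often the mutagen child is farther from the parent than the
    spontaneous child (same per-trait effect size, 50 vs 5 traits shifted),
    parent–child mean distance at CCR 90%."""
    base = _derive(seed, 5)
    wins = 0
    for i in range(n_cohorts):
        table, _, _, _ = generate_cohort(_two_child_spec((base + i) % (2**31)))
        sz = strain_z_matrix(table)
        rz = replicate_z_matrix(table)
        common = [t for t in sz.z.columns if t in set(rz.z.columns)]
        space = build_pca(sz.z[common])
        rep = lambda s: rz.z[common].xs(s, level="strain")  # noqa: E731
        d_mut = strain_pair_distances(space, rep("child_mutagen"), rep("P")).mean
        d_spo = strain_pair_distances(space, rep("child_spont"), rep("P")).mean
        if d_mut > d_spo:
            wins += 1
    return wins / n_cohorts


def pp_dunnett_power(seed: int, n_cohorts: int = 100,
                     inflation: float = 3.0, alpha: float = 0.05) -> float:
    """Power to flag a noise-inflated strain by PP + Dunnett vs control.

    One designated fragile strain (noise traits inflated by ``inflation``)
    among the default lineage; control strain K7.  Returns the fraction of
    cohorts in which exactly the fragile strain's flag fires.
    """
    base = _derive(seed, 6)
    flagged = 0
    for i in range(n_cohorts):
        spec = SyntheticSpec(seed=(base + i) % (2**31),
                             noise_inflation={"K1801": inflation})
        table, *_ = generate_cohort(spec)
        rz = replicate_z_matrix(table)
        pps = pp_by_strain(rz.z, table.catalog)
        results = dunnett_vs_control(pps, control="K7", alpha=alpha)
        if any(r.strain_id == "K1801" and r.flagged_vs_control
               for r in results):
            flagged += 1
    return flagged / n_cohorts


def dunnett_false_flag_rate(seed: int, n_cohorts: int = 100,
                            alpha: float = 0.05) -> float:
    """Fraction of non-inflated strains falsely flagged (higher-PP side)."""
    base = _derive(seed, 9)
    false = total = 0
    for i in range(n_cohorts):
        spec = SyntheticSpec(seed=(base + i) % (2**31))
        table, *_ = generate_cohort(spec)
        rz = replicate_z_matrix(table)
        pps = pp_by_strain(rz.z, table.catalog)
        results = dunnett_vs_control(pps, control="K7", alpha=alpha)
        for r in results:
            if r.strain_id in ("K7", "reference"):
                continue
            total += 1
            if r.flagged_vs_control and r.mean > next(
                x.mean for x in results if x.strain_id == "K7"
            ):
                false += 1
    return false / total if total else 0.0


def cross_vs_segregant_comparison(seed: int, n_segregants: int = 62) -> dict:
    """Inbreeding-deviation hybrids vs a segregant panel, in one cohort.

    The hybrids carry an isotropic inbreeding deviation on top of the
    mid-parent expectation; the segregant panel sits at mid-parent plus a
    deviation matched to the within-strain replicate scatter.  Returns the
    two groups' mean ratios and the Mann–Whitney p-value for the hybrids
    being farther from the additive expectation.
    """
    spec = SyntheticSpec(seed=_derive(seed, 7))
    table, _, _, _ = generate_cohort(spec)
    sz = strain_z_matrix(table)
    rz = replicate_z_matrix(table)
    common = [t for t in sz.z.columns if t in set(rz.z.columns)]
    space = build_pca(sz.z[common])
    rep = lambda s: rz.z[common].xs(s, level="strain")  # noqa: E731
    ratios = cross_distance_ratio(rep("K9"), rep("K10"), rep("K13"), space,
                                  cross=("K9", "K10", "K13"))
    k = ratios_k = components_for_ccr(space, 0.9)
    sa = project(space, rep("K9"), n_components=k).to_numpy()
    sb = project(space, rep("K10"), n_components=k).to_numpy()
    # sigma matched to the parents' own replicate scatter in score space
    sigma = float(np.mean([sa.std(axis=0, ddof=1).mean(),
                           sb.std(axis=0, ddof=1).mean()]))
    seg = generate_segregant_panel(sa, sb, n_segregants, sigma,
                                   seed=_derive(seed, 8))
    seg_r = segregant_ratios(sa, sb, seg)
    _, p = group_location_test(ratios.ratios, seg_r)
    return {
        "hybrid_mean_ratio": ratios.mean,
        "segregant_mean_ratio": float(seg_r.mean()),
        "n_hybrid_ratios": ratios.n,
        "n_segregant_ratios": len(seg_r),
        "mannwhitney_p": p,
        "n_components": ratios_k,
    }


# ---------------------------------------------------------------------------
# clustering checks
# ---------------------------------------------------------------------------

def upgma_hand_check() -> dict:
    """UPGMA on the 3-strain dissimilarity D(a,b)=1, D(a,c)=D(b,c)=4.

    The hand merge sequence joins (a, b) at height 1, then c at height 4.
    """
    D = pd.DataFrame([[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]],
                     index=list("abc"), columns=list("abc"))
    tree = average_linkage_hca(D)
    return {
        "first_merge_height": float(tree.heights[0]),
        "second_merge_height": float(tree.heights[1]),
        "first_clade_is_ab": frozenset({"a", "b"}) in tree.clades(),
    }


def two_group_bootstrap_support(seed: int, n_boot: int = 200,
                                separation: float = 10.0) -> float:
    """Bootstrap support of the two-group split for 10×-separated groups.

    Twelve strains in two groups of six; the groups differ by
    ``separation`` times the within-group SD on a quarter of 100 traits.
    """
    rng = np.random.default_rng(_derive(seed, 10))
    n_traits, n_per = 100, 6
    shift = np.zeros(n_traits)
    shift[rng.choice(n_traits, 25, replace=False)] = separation
    rows, labels = [], []
    for g, offset in enumerate((np.zeros(n_traits), shift)):
        for i in range(n_per):
            rows.append(offset + rng.normal(0, 1.0, n_traits))
            labels.append(f"g{g}s{i}")
    z = pd.DataFrame(rows, index=labels,
                     columns=[f"t{i}" for i in range(n_traits)])
    tree = bootstrap_support(z, n_boot=n_boot, seed=_derive(seed, 11),
                             ccr_threshold=0.6)
    groups = [frozenset(lb for lb in labels if lb.startswith("g0")),
              frozenset(lb for lb in labels if lb.startswith("g1"))]
    # support of the two-group split = support of either group's clade
    return float(max(tree.support.get(g, 0.0) for g in groups))
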