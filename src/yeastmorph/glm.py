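"""Trait-wise GLM normalization to Wald Z-profiles.

Each morphological trait is modeled with a generalized linear model whose
family is fixed by the trait's value domain:

===========  ==================  =============
value domain family              mean link
===========  ==================  =============
unbounded    Gaussian            identity
positive     Gamma               log
proportion   Beta (quasi-        logit
             binomial fallback)
===========  ==================  =============

Strain membership (and, when cultures span two media, the medium) enters the
linear predictor as a categorical term with the reference strain as the base
level, so each strain coefficient is a contrast against the reference.  The
normalized phenotype of a strain on a trait is the Wald statistic
``Z = coefficient / SE`` of that contrast; profiling Z across all traits
turns heterogeneous raw measurements into a common, dimensionless scale.

Two Z resolutions are supported:

* **strain-level** — one Z per strain per trait, from the strain-factor GLM;
* **replicate-level** — one Z per culture, the reference-calibrated score
  ``(g(y) − η̂_ref) / SE`` with the reference linear predictor and dispersion
  estimated from the reference replicates alone and the delta-method
  variance of the linked observation.  For the Gaussian family this equals
  the Wald contrast of a GLM in which every replicate is its own factor
  level.

Wald p-values use a Student-t reference with the residual degrees of freedom
rather than the normal limit, which keeps tail calibration honest at the
small per-trait sample sizes (a handful of replicates per strain) this
pipeline is designed for.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.othermod.betareg import BetaModel

from .catalog import TraitCatalog
from .io import TraitTable

log = logging.getLogger(__name__)

GAUSSIAN = "gaussian-identity"
GAMMA = "gamma-log"
BETA = "beta-logit"
QUASIBINOMIAL = "quasibinomial-logit"

FAMILY_BY_DOMAIN = {"unbounded": GAUSSIAN, "positive": GAMMA, "proportion": BETA}

MAX_ITER = 200
TOL = 1e-8


class FitError(RuntimeError):
    """GLM failed to converge or produced a degenerate fit."""


class DesignError(ValueError):
    """Singular, confounded, or non-nested design."""


@dataclass
class GLMFit:
    """Maximum-likelihood fit of one trait's GLM."""

    trait_id: str
    family: str
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    dispersion: float
    log_likelihood: float
    n_obs: int
    n_params: int          # estimated parameters incl. dispersion/precision
    df_resid: int
    converged: bool = True

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.n_params

    def wald_p(self, term: str) -> float:
        z = wald_z(self, term)
        return 2.0 * float(stats.t.sf(abs(z), df=max(self.df_resid, 1)))


def wald_z(fit: GLMFit, term: str) -> float:
    """Wald statistic of one contrast: coefficient / standard error."""
    if term not in fit.coefficients:
        raise DesignError(f"term {term!r} not in fit of {fit.trait_id!r}")
    se = fit.standard_errors[term]
    if not np.isfinite(se) or se <= 0:
        raise FitError(f"degenerate fit for {fit.trait_id!r}: SE({term}) = {se}")
    return fit.coefficients[term] / se


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(
    design: pd.DataFrame,
    reference_levels: dict[str, str] | None = None,
    include_interaction: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix with named columns.

    Each column of ``design`` is a categorical term; its reference level
    (``reference_levels[term]`` if given, else the lexicographically first
    level) is absorbed into the intercept.  With ``include_interaction`` the
    pairwise products of the dummy columns are appended.
    """
    reference_levels = reference_levels or {}
    n = len(design)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    per_term: list[list[int]] = []
    for term in design.columns:
        values = design[term].astype(str).to_numpy()
        levels = sorted(set(values))
        base = reference_levels.get(term, levels[0])
        if base not in levels:
            raise DesignError(f"reference level {base!r} absent from term {term!r}")
        idxs = []
        for lv in levels:
            if lv == base:
                continue
            cols.append((values == lv).astype(float))
            names.append(f"{term}[{lv}]")
            idxs.append(len(cols) - 1)
        per_term.append(idxs)
    if include_interaction and len(per_term) >= 2:
        for a in range(len(per_term)):
            for b in range(a + 1, len(per_term)):
                for i in per_term[a]:
                    for j in per_term[b]:
                        cols.append(cols[i] * cols[j])
                        names.append(f"{names[i]}:{names[j]}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("singular design matrix (confounded terms)")
    return X, names


# ---------------------------------------------------------------------------
# single-trait fits
# ---------------------------------------------------------------------------

def shrink_boundary(y: np.ndarray, cell_counts: np.ndarray | None) -> np.ndarray:
    """Pull proportion values off the {0, 1} boundary.

    Applies the standard (y·(n−1) + 0.5)/n shrinkage, with n the number of
    cells behind the observation, to boundary values only; interior values
    are untouched.  Keeps the logit finite for beta fitting.
    """
    y = np.asarray(y, dtype=float).copy()
    at_edge = (y <= 0.0) | (y >= 1.0)
    if at_edge.any():
        if cell_counts is None:
            n = np.full(y.shape, 200.0)
        else:
            n = np.asarray(cell_counts, dtype=float)
        y[at_edge] = (y[at_edge] * (n[at_edge] - 1.0) + 0.5) / n[at_edge]
    return y


def fit_trait_glm(
    values,
    design: pd.DataFrame,
    family: str,
    include_interaction: bool = False,
    reference_levels: dict[str, str] | None = None,
    cell_counts=None,
    trait_id: str = "",
) -> GLMFit:
    """Fit one trait's GLM by maximum likelihood.

    Parameters
    ----------
    values:
        Trait observations, one per design row (NaN rows must be dropped by
        the caller).
    design:
        DataFrame of categorical explanatory terms (subset of strain,
        medium, awa_status, ...), aligned with ``values``.
    family:
        One of :data:`GAUSSIAN`, :data:`GAMMA`, :data:`BETA`,
        :data:`QUASIBINOMIAL`.
    """
    y = np.asarray(values, dtype=float)
    if np.isnan(y).any():
        raise ValueError("values contain NaN; drop missing records first")
    X, names = build_design(design, reference_levels, include_interaction)
    if len(y) != X.shape[0]:
        raise DesignError("values and design have different lengths")
    counts = np.bincount(pd.factorize(design.astype(str).agg("|".join, axis=1))[0])
    if X.shape[1] > 1 and (counts < 2).any():
        log.debug("trait %s: some design cells have <2 observations", trait_id)
    try:
        if family == GAUSSIAN:
            return _fit_glm_sm(y, X, names, sm.families.Gaussian(), GAUSSIAN, trait_id)
        if family == GAMMA:
            fam = sm.families.Gamma(link=sm.families.links.Log())
            return _fit_glm_sm(y, X, names, fam, GAMMA, trait_id)
        if family == BETA:
            yb = shrink_boundary(y, cell_counts)
            try:
                return _fit_beta(yb, X, names, trait_id)
            except (FitError, np.linalg.LinAlgError, ValueError):
                log.info("trait %s: beta fit failed, quasi-binomial fallback",
                         trait_id)
                return fit_trait_glm(values, design, QUASIBINOMIAL,
                                     include_interaction, reference_levels,
                                     cell_counts, trait_id)
        if family == QUASIBINOMIAL:
            yb = shrink_boundary(y, cell_counts)
            fam = sm.families.Binomial(link=sm.families.links.Logit())
            return _fit_glm_sm(yb, X, names, fam, QUASIBINOMIAL, trait_id,
                               scale="X2")
    except (FitError, DesignError):
        raise
    except Exception as exc:  # statsmodels raises a zoo of exception types
        raise FitError(f"GLM fit failed for trait {trait_id!r}: {exc}") from exc
    raise ValueError(f"unknown family {family!r}")


def _fit_glm_sm(y, X, names, sm_family, family_label, trait_id,
                scale=None) -> GLMFit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm_family)
        res = model.fit(maxiter=MAX_ITER, tol=TOL, scale=scale)
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise FitError(f"non-finite estimates for trait {trait_id!r}")
    k_mean = X.shape[1]
    if family_label == GAUSSIAN:
        # Gaussian log-likelihood at the ML (not REML-style) variance
        resid = y - res.fittedvalues
        sigma2 = float(resid @ resid) / len(y)
        if sigma2 <= 0:
            llf = np.inf
        else:
            llf = -0.5 * len(y) * (np.log(2 * np.pi * sigma2) + 1.0)
        dispersion = float(res.scale)
    else:
        llf = float(res.llf)
        dispersion = float(res.scale)
    return GLMFit(
        trait_id=trait_id,
        family=family_label,
        coefficients=dict(zip(names, map(float, res.params))),
        standard_errors=dict(zip(names, map(float, res.bse))),
        dispersion=dispersion,
        log_likelihood=float(llf),
        n_obs=len(y),
        n_params=k_mean + 1,  # + dispersion
        df_resid=len(y) - k_mean,
        converged=bool(getattr(res, "converged", True)),
    )


def _fit_beta(y, X, names, trait_id) -> GLMFit:
    if np.any((y <= 0) | (y >= 1)):
        raise FitError("beta response on boundary")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BetaModel(y, X)
        res = model.fit(disp=0, maxiter=MAX_ITER)
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged or not np.all(np.isfinite(res.bse)):
        raise FitError(f"beta fit did not converge for trait {trait_id!r}")
    k_mean = X.shape[1]
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    precision = float(params[-1])
    return GLMFit(
        trait_id=trait_id,
        family=BETA,
        coefficients=dict(zip(names, map(float, params[:k_mean]))),
        standard_errors=dict(zip(names, map(float, bse[:k_mean]))),
        dispersion=precision,
        log_likelihood=float(res.llf),
        n_obs=len(y),
        n_params=len(params),  # mean params + precision
        df_resid=len(y) - k_mean,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# model selection and screening
# ---------------------------------------------------------------------------

def select_model_aic(
    values,
    design: pd.DataFrame,
    candidates: list[tuple[tuple[str, ...], bool]],
    family: str,
    reference_levels: dict[str, str] | None = None,
    cell_counts=None,
    trait_id: str = "",
) -> tuple[tuple[tuple[str, ...], bool], GLMFit]:
    """Pick the candidate design with minimal AIC.

    ``candidates`` is a list of (terms, include_interaction) pairs; the empty
    term tuple is the intercept-only model.  Ties (to within 1e-9) are broken
    toward the design with fewer estimated parameters.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate designs")
    best: tuple | None = None
    for terms, interaction in candidates:
        sub = design[list(terms)] if terms else design.iloc[:, :0]
        try:
            fit = fit_trait_glm(values, sub, family, interaction,
                                reference_levels, cell_counts, trait_id)
        except (FitError, DesignError):
            continue
        key = (fit.aic, fit.n_params)
        if best is None or (key[0] < best[0][0] - 1e-9) or (
            abs(key[0] - best[0][0]) <= 1e-9 and key[1] < best[0][1]
        ):
            best = (key, (terms, interaction), fit)
    if best is None:
        raise FitError(f"no candidate design converged for trait {trait_id!r}")
    return best[1], best[2]


def lrt_screen(
    fits_full: dict[str, GLMFit],
    fits_reduced: dict[str, GLMFit],
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> set[str]:
    """Likelihood-ratio screen of traits, Bonferroni-corrected.

    Returns the traits whose LR statistic 2·(ℓ_full − ℓ_reduced) exceeds the
    χ² critical value at ``alpha / m`` (m = number of traits tested) with the
    difference in estimated parameter counts as degrees of freedom.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    common = sorted(set(fits_full) & set(fits_reduced))
    m = len(common)
    if m == 0:
        return set()
    level = alpha / m if correction == "bonferroni" else alpha
    hits: set[str] = set()
    for tid in common:
        f, r = fits_full[tid], fits_reduced[tid]
        df = f.n_params - r.n_params
        if df <= 0 or not set(r.coefficients) <= set(f.coefficients):
            raise DesignError(f"reduced model not nested in full for {tid!r}")
        stat = 2.0 * (f.log_likelihood - r.log_likelihood)
        p = float(stats.chi2.sf(max(stat, 0.0), df))
        if p < level or level >= 1.0:
            hits.add(tid)
    return hits


def bonferroni_wald_screen(
    fits: dict[str, GLMFit], term: str, alpha: float = 0.05
) -> set[str]:
    """Traits whose Wald contrast is significant after Bonferroni correction."""
    m = len(fits)
    if m == 0:
        return set()
    return {
        tid for tid, fit in fits.items()
        if term in fit.coefficients and fit.wald_p(term) < alpha / m
    }


# ---------------------------------------------------------------------------
# Z-matrix construction
# ---------------------------------------------------------------------------

@dataclass
class ZMatrix:
    """Wald Z-profiles: rows = strains (or strain replicates) × trait columns."""

    z: pd.DataFrame = field(repr=False)
    reference: str = "reference"
    families: pd.Series | None = field(default=None, repr=False)
    failed_traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.z.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise FitError("ZMatrix contains non-finite entries")

    @property
    def trait_ids(self) -> list[str]:
        return list(self.z.columns)

    def rows_for_strain(self, strain: str) -> pd.DataFrame:
        if isinstance(self.z.index, pd.MultiIndex):
            return self.z.xs(strain, level="strain", drop_level=True)
        return self.z.loc[[strain]]


def _family_for(catalog: TraitCatalog, trait_id: str) -> str:
    return FAMILY_BY_DOMAIN[catalog.family_of(trait_id)]


def fit_strain_glms(
    table: TraitTable,
    reference: str = "reference",
    media_adjust: bool = False,
    include_interaction: bool = False,
) -> dict[str, GLMFit]:
    """Per-trait strain-factor GLM fits (optionally with a medium term)."""
    df = table.data
    if reference not in set(df["strain"]):
        raise DesignError(f"reference strain {reference!r} not in table")
    terms = ["strain", "medium"] if media_adjust else ["strain"]
    if media_adjust:
        _check_medium_support(df, reference)
    ref_levels = {"strain": reference}
    if media_adjust:
        ref_levels["medium"] = sorted(set(df.loc[df["strain"] == reference,
                                              "medium"]))[0]
    fits: dict[str, GLMFit] = {}
    for tid in table.catalog.trait_ids:
        col = df[tid]
        keep = col.notna().to_numpy()
        y = col.to_numpy(dtype=float)[keep]
        design = df.loc[keep, terms]
        fam = _family_for(table.catalog, tid)
        try:
            fits[tid] = fit_trait_glm(
                y, design, fam, include_interaction, ref_levels,
                cell_counts=df.loc[keep, "cell_count"].to_numpy(),
                trait_id=tid,
            )
        except (FitError, DesignError) as exc:
            log.warning("trait %s excluded: %s", tid, exc)
    return fits


def _check_medium_support(df: pd.DataFrame, reference: str) -> None:
    ref_media = set(df.loc[df["strain"] == reference, "medium"])
    other = df.loc[df["strain"] != reference]
    orphan = set(other["medium"]) - ref_media
    if orphan:
        raise DesignError(
            f"media {sorted(orphan)} lack reference observations; the medium "
            "effect is confounded with strain"
        )


def strain_z_matrix(
    table: TraitTable,
    reference: str = "reference",
    media_adjust: bool = False,
) -> ZMatrix:
    """One Wald Z per strain per trait, relative to the reference strain."""
    fits = fit_strain_glms(table, reference, media_adjust)
    strains = [s for s in table.strains]
    rows = {s: {} for s in strains}
    failed: list[str] = []
    for tid in table.catalog.trait_ids:
        fit = fits.get(tid)
        if fit is None:
            failed.append(tid)
            continue
        ok = True
        col = {}
        for s in strains:
            if s == reference:
                col[s] = 0.0
                continue
            term = f"strain[{s}]"
            try:
                col[s] = wald_z(fit, term)
            except (FitError, DesignError):
                ok = False
                break
        if not ok or not all(np.isfinite(v) for v in col.values()):
            failed.append(tid)
            continue
        for s in strains:
            rows[s][tid] = col[s]
    kept = [t for t in table.catalog.trait_ids if t not in failed]
    z = pd.DataFrame([[rows[s][t] for t in kept] for s in strains],
                     index=pd.Index(strains, name="strain"), columns=kept)
    fams = table.catalog.families().loc[kept]
    return ZMatrix(z=z, reference=reference, families=fams, failed_traits=failed)


def medium_adjusted_z(table: TraitTable, reference: str = "reference") -> ZMatrix:
    """Strain Z-profiles with the medium effect removed.

    Fits the two-way GLM (strain + medium, no interaction) per trait; the
    returned Z is the strain contrast after the additive medium effect on
    the link scale has been absorbed by the medium term.
    """
    return strain_z_matrix(table, reference, media_adjust=True)


def replicate_z_matrix(
    table: TraitTable,
    reference: str = "reference",
    media_adjust: bool = False,
) -> ZMatrix:
    """Reference-calibrated Wald-type Z per replicate per trait.

    For each trait the reference replicates fix the null linear predictor
    η̂_ref and the dispersion; each culture's Z is its linked observation's
    standardized deviation from η̂_ref (delta-method variance, inflated by
    1 + 1/n_ref for the estimated reference mean).  Includes the reference
    strain's own replicates, whose Z are null-calibrated by construction.
    """
    df = table.data
    if reference not in set(df["strain"]):
        raise DesignError(f"reference strain {reference!r} not in table")
    medium_offsets: dict[str, dict[str, float]] = {}
    if media_adjust:
        fits = fit_strain_glms(table, reference, media_adjust=True)
        base_medium = sorted(set(df.loc[df["strain"] == reference, "medium"]))[0]
        for tid, fit in fits.items():
            medium_offsets[tid] = {
                name[len("medium["):-1]: coef
                for name, coef in fit.coefficients.items()
                if name.startswith("medium[")
            }
            medium_offsets[tid][base_medium] = 0.0
    is_ref = (df["strain"] == reference).to_numpy()
    n_ref_total = int(is_ref.sum())
    if n_ref_total < 2:
        raise DesignError("need >=2 reference replicates")
    index = pd.MultiIndex.from_frame(
        df[["strain", "replicate"]].astype(str), names=["strain", "replicate"]
    )
    out: dict[str, np.ndarray] = {}
    failed: list[str] = []
    for tid in table.catalog.trait_ids:
        fam = _family_for(table.catalog, tid)
        y = df[tid].to_numpy(dtype=float)
        try:
            gy = _linked_values(y, fam, df["cell_count"].to_numpy())
            if tid in medium_offsets:
                offs = df["medium"].map(medium_offsets[tid]).to_numpy(float)
                gy = gy - offs
            zcol = _reference_calibrated_z(gy, y, is_ref, fam)
        except (FitError, ValueError) as exc:
            log.warning("trait %s excluded from replicate Z: %s", tid, exc)
            failed.append(tid)
            continue
        if not np.isfinite(zcol[~np.isnan(y)]).all():
            failed.append(tid)
            continue
        out[tid] = zcol
    z = pd.DataFrame(out, index=index)
    # drop records with any missing Z (missing raw values)
    z = z.dropna(axis=0, how="any")
    kept = list(z.columns)
    fams = table.catalog.families().loc[kept]
    return ZMatrix(z=z, reference=reference, families=fams, failed_traits=failed)


def _linked_values(y: np.ndarray, family: str, cell_counts: np.ndarray) -> np.ndarray:
    gy = np.full(y.shape, np.nan)
    ok = ~np.isnan(y)
    if family == GAUSSIAN:
        gy[ok] = y[ok]
    elif family == GAMMA:
        if np.any(y[ok] <= 0):
            raise ValueError("nonpositive value for a positive-domain trait")
        gy[ok] = np.log(y[ok])
    else:  # proportions
        yb = shrink_boundary(y[ok], cell_counts[ok])
        gy[ok] = np.log(yb / (1.0 - yb))
    return gy


def _reference_calibrated_z(
    gy: np.ndarray, y: np.ndarray, is_ref: np.ndarray, family: str
) -> np.ndarray:
    ok = ~np.isnan(y)
    ref = ok & is_ref
    n_ref = int(ref.sum())
    if n_ref < 2:
        raise FitError("need >=2 non-missing reference replicates")
    eta_ref = float(np.mean(gy[ref]))
    # dispersion of the linked observation, from reference replicates only
    var_link = float(np.var(gy[ref], ddof=1))
    if var_link <= 0:
        raise FitError("zero reference variance on the link scale")
    se = np.sqrt(var_link * (1.0 + 1.0 / n_ref))
    z = np.full(y.shape, np.nan)
    z[ok] = (gy[ok] - eta_ref) / se
    return z
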