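"""The degenerated orthogonal phenotypic space.

PCA over strain Z-profiles rotates the 501 correlated trait axes into
orthogonal components, so that Euclidean geometry in the leading components
is not biased by trait-trait correlation.  Analyses retain the smallest
number of components whose cumulative contribution ratio (CCR, the running
sum of explained-variance shares) reaches a stated threshold — 60% for
clustering, 90% for distance work.

Rows are centered but not rescaled before the SVD: the GLM stage has already
put every trait on the common Wald-Z scale, so further per-trait rescaling
would only amplify traits that barely vary (a flag is available for data not
produced by that stage).  The component sign convention (largest-magnitude
loading positive) makes the decomposition reproducible across runs and
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: singular values below this times the largest are treated as numerical zero
RANK_RTOL = 1e-10


class DegenerateSpaceError(ValueError):
    """All rows identical — no phenotypic variation to decompose."""


class SchemaError(ValueError):
    """Trait sets of space and projected rows disagree."""


@dataclass
class PhenoSpace:
    """PCA basis over Z-profiles.

    Attributes
    ----------
    loadings:
        traits × components orthonormal matrix (DataFrame, trait index).
    explained_variance:
        per-component variances (nonincreasing).
    ccr:
        cumulative contribution ratio per component, ending at 1.
    center:
        per-trait means subtracted before projection.
    """

    loadings: pd.DataFrame = field(repr=False)
    explained_variance: np.ndarray = field(repr=False)
    ccr: np.ndarray = field(repr=False)
    center: pd.Series = field(repr=False)
    n_components: int = 0
    scale: pd.Series | None = field(default=None, repr=False)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.loadings.index)


def build_pca(z: pd.DataFrame, rescale: bool = False) -> PhenoSpace:
    """Centered PCA of a rows × traits Z matrix via SVD.

    Components with singular value below ``RANK_RTOL`` times the largest are
    dropped as numerical rank deficiency.
    """
    X = np.asarray(z, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two rows to build a phenotypic space")
    if not np.isfinite(X).all():
        raise ValueError("Z matrix contains non-finite entries")
    center = X.mean(axis=0)
    Xc = X - center
    scale = np.ones(X.shape[1])
    if rescale:
        scale = Xc.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        Xc = Xc / scale
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 0:
        raise DegenerateSpaceError("all rows are identical")
    keep = s > RANK_RTOL * s[0]
    s, Vt = s[keep], Vt[keep]
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    ev = s**2 / (X.shape[0] - 1)
    ccr = np.cumsum(ev) / ev.sum()
    loadings = pd.DataFrame(Vt.T, index=z.columns,
                            columns=[f"PC{i+1}" for i in range(len(ev))])
    return PhenoSpace(
        loadings=loadings,
        explained_variance=ev,
        ccr=ccr,
        center=pd.Series(center, index=z.columns),
        n_components=len(ev),
        scale=pd.Series(scale, index=z.columns) if rescale else None,
    )


def components_for_ccr(space: PhenoSpace, threshold: float) -> int:
    """Smallest k with CCR(k) ≥ threshold (threshold in (0, 1])."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("CCR threshold must lie in (0, 1]")
    k = int(np.searchsorted(space.ccr, threshold - 1e-12)) + 1
    return min(k, space.n_components)


def project(space: PhenoSpace, z_rows: pd.DataFrame, n_components: int | None = None
            ) -> pd.DataFrame:
    """Scores of Z rows in the space: (z − center) · loadings[:, :k]."""
    if list(z_rows.columns) != space.trait_ids:
        missing = set(space.trait_ids) - set(z_rows.columns)
        if missing:
            raise SchemaError(f"rows lack {len(missing)} space traits")
        z_rows = z_rows[space.trait_ids]
    k = space.n_components if n_components is None else n_components
    if not 1 <= k <= space.n_components:
        raise ValueError(f"n_components must be in [1, {space.n_components}]")
    Xc = np.asarray(z_rows, dtype=float) - space.center.to_numpy()
    if space.scale is not None:
        Xc = Xc / space.scale.to_numpy()
    scores = Xc @ space.loadings.to_numpy()[:, :k]
    return pd.DataFrame(scores, index=z_rows.index,
                        columns=list(space.loadings.columns[:k]))


def variance_ratio(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame, upto: int
) -> tuple[np.ndarray, float]:
    """Component-wise var(A)/var(B) and the cumulative Σvar(A)/Σvar(B).

    Quantifies how broadly one population spreads in phenotype space
    relative to another, per component and cumulatively over the first
    ``upto`` components.
    """
    if len(scores_a) < 2 or len(scores_b) < 2:
        raise ValueError("need >=2 members per population")
    va = np.asarray(scores_a, dtype=float)[:, :upto].var(axis=0, ddof=1)
    vb = np.asarray(scores_b, dtype=float)[:, :upto].var(axis=0, ddof=1)
    if np.any(vb == 0):
        comp = int(np.flatnonzero(vb == 0)[0]) + 1
        raise ZeroDivisionError(f"population B has zero variance on PC{comp}")
    return va / vb, float(va.sum() / vb.sum())


def group_traits_by_reference_pca(
    z_reference_replicates: pd.DataFrame,
    candidate_traits: list[str],
    ccr_threshold: float = 0.9,
) -> list[list[str]]:
    """Group candidate traits by the reference-replicate PCA they co-load on.

    Traits whose Z values across reference replicates covary are redundant
    readouts of a shared morphological feature; PCA on the reference
    replicates restricted to the candidates exposes this, and each trait is
    assigned to the retained component it loads on most strongly.
    Returns the nonempty groups (lists of trait ids).
    """
    if len(z_reference_replicates) < 3:
        raise ValueError("need >=3 reference replicates to group traits")
    if len(candidate_traits) == 0:
        raise ValueError("no candidate traits")
    if len(candidate_traits) == 1:
        return [list(candidate_traits)]
    sub = z_reference_replicates[list(candidate_traits)]
    space = build_pca(sub)
    k = components_for_ccr(space, ccr_threshold)
    L = space.loadings.to_numpy()[:, :k]
    assign = np.argmax(np.abs(L), axis=1)
    groups = []
    for comp in range(k):
        members = [candidate_traits[i] for i in np.flatnonzero(assign == comp)]
        if members:
            groups.append(members)
    return groups
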