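"""Euclidean-distance statistics over the breeding lineage.

The morphological change at a breeding step is measured as the Euclidean
distance d(x, y) = sqrt(Σ_i (x_i − y_i)²) between PC-score profiles in the
degenerated phenotypic space (components retained up to a CCR threshold,
0.90 by default).  Because each strain is phenotyped in several replicate
cultures, every distance is a replicate-combinatoric multiset:

* strain pair — distances over the full Cartesian product of replicate pairs
  (5 × 5 replicates → 25 distances);
* mid-parent points — element-wise averages of every parent-replicate pair
  (5 × 5 → 25 midpoints), the additive expectation for a hybrid;
* hybrid departure — distances from each hybrid replicate to each midpoint
  (5 × 25 → 125 distances);
* cross-distance ratio — hybrid-to-midpoint distances divided by the mean
  parent–parent distance, a scale-free measure of non-additive (heterotic or
  inbreeding) deviation.

Mean ± SD over the multiset is reported throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .io import LineageGraph
from .pca import PhenoSpace, components_for_ccr, project

#: projected-disk sphere constant: a sphere of projected area A = πr² has
#: volume (4/3)πr³ = 4/(3·sqrt(π)) · A^(3/2)
SPHERE_VOLUME_CONSTANT = 4.0 / (3.0 * np.sqrt(np.pi))

DEFAULT_CCR = 0.90


class InsufficientDataError(ValueError):
    """Empty replicate set where at least one replicate is required."""


@dataclass
class DistanceSummary:
    """Multiset of replicate-combinatoric distances for one strain pair."""

    pair: tuple[str, str]
    distances: np.ndarray = field(repr=False)
    n_components_used: int = 0
    ccr_used: float = float("nan")

    @property
    def n_pairs(self) -> int:
        return len(self.distances)

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    @property
    def sd(self) -> float:
        return float(np.std(self.distances, ddof=1)) if len(self.distances) > 1 else 0.0


@dataclass
class RatioSummary:
    """Cross-distance ratios for one (parentA, parentB, hybrid) trio."""

    cross: tuple[str, str, str]
    ratios: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.ratios)

    @property
    def mean(self) -> float:
        return float(np.mean(self.ratios))

    @property
    def sd(self) -> float:
        return float(np.std(self.ratios, ddof=1)) if len(self.ratios) > 1 else 0.0


def euclidean_distance(x, y) -> float:
    """d(x, y) = sqrt(Σ (x_i − y_i)²); near zero for similar morphologies."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.linalg.norm(x - y))


def _pairwise_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All Cartesian-product distances between rows of a and rows of b."""
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).ravel()


def _scores(space: PhenoSpace, reps: pd.DataFrame, ccr_threshold: float
            ) -> tuple[np.ndarray, int]:
    k = components_for_ccr(space, ccr_threshold)
    return project(space, reps, n_components=k).to_numpy(), k


def strain_pair_distances(
    space: PhenoSpace,
    reps_x: pd.DataFrame,
    reps_y: pd.DataFrame,
    ccr_threshold: float = DEFAULT_CCR,
    pair: tuple[str, str] = ("x", "y"),
) -> DistanceSummary:
    """Distances between two strains over all replicate pairs.

    Replicate Z rows are projected onto the leading components at the CCR
    threshold; the multiset holds one distance per (replicate of x,
    replicate of y) pair — n_x · n_y distances in total.
    """
    if len(reps_x) == 0 or len(reps_y) == 0:
        raise InsufficientDataError("empty replicate set")
    sx, k = _scores(space, reps_x, ccr_threshold)
    sy, _ = _scores(space, reps_y, ccr_threshold)
    d = _pairwise_distances(sx, sy)
    return DistanceSummary(pair=pair, distances=d, n_components_used=k,
                           ccr_used=ccr_threshold)


def midparent_points(reps_a: np.ndarray, reps_b: np.ndarray) -> np.ndarray:
    """Element-wise midpoints (a + b)/2 for every parent-replicate pair."""
    a = np.atleast_2d(np.asarray(reps_a, dtype=float))
    b = np.atleast_2d(np.asarray(reps_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("parent score dimensions differ")
    mids = [(ra + rb) / 2.0 for ra, rb in product(a, b)]
    return np.asarray(mids)


def hybrid_midparent_distances(
    hybrid_reps: np.ndarray,
    midpoints: np.ndarray,
    pair: tuple[str, str] = ("hybrid", "midparent"),
) -> DistanceSummary:
    """Distances from each hybrid replicate to each mid-parent point."""
    h = np.atleast_2d(np.asarray(hybrid_reps, dtype=float))
    m = np.atleast_2d(np.asarray(midpoints, dtype=float))
    if h.size == 0 or m.size == 0:
        raise InsufficientDataError("empty hybrid or midpoint set")
    d = _pairwise_distances(h, m)
    return DistanceSummary(pair=pair, distances=d,
                           n_components_used=h.shape[1])


def cross_distance_ratio(
    parent_a_reps: pd.DataFrame,
    parent_b_reps: pd.DataFrame,
    hybrid_reps: pd.DataFrame,
    space: PhenoSpace,
    ccr_threshold: float = DEFAULT_CCR,
    cross: tuple[str, str, str] = ("A", "B", "hybrid"),
    paired_denominator: bool = False,
) -> RatioSummary:
    """Normalized hybrid departure from the additive mid-parent expectation.

    Numerator: the n_h · n_a · n_b hybrid-to-midpoint distances.  Denominator
    (default): the scalar mean of the n_a · n_b parent–parent distances, so a
    5/5/5-replicate cross yields 125 ratio values.  With
    ``paired_denominator`` each hybrid-to-midpoint distance is instead
    divided by the parent–parent distance of the same parent-replicate pair.
    """
    sa, k = _scores(space, parent_a_reps, ccr_threshold)
    sb, _ = _scores(space, parent_b_reps, ccr_threshold)
    sh, _ = _scores(space, hybrid_reps, ccr_threshold)
    if min(len(sa), len(sb), len(sh)) == 0:
        raise InsufficientDataError("empty replicate set in cross")
    parent_d = _pairwise_distances(sa, sb)  # ordered as product(a, b)
    mids = midparent_points(sa, sb)
    hyb_d = _pairwise_distances(sh, mids)   # ordered as product(h, (a, b))
    if paired_denominator:
        if np.any(parent_d == 0):
            raise ZeroDivisionError("a parent replicate pair coincides")
        ratios = (hyb_d.reshape(len(sh), -1) / parent_d[None, :]).ravel()
    else:
        denom = float(parent_d.mean())
        if denom == 0:
            raise ZeroDivisionError("parent strains coincide in score space")
        ratios = hyb_d / denom
    return RatioSummary(cross=cross, ratios=ratios)


def segregant_ratios(
    parent_a_reps: np.ndarray,
    parent_b_reps: np.ndarray,
    segregant_rows: np.ndarray,
) -> np.ndarray:
    """One mid-parent ratio per segregant (already in score space).

    Each segregant's distance to the mean mid-parent point, divided by the
    mean parent–parent distance — the per-progeny analog of
    :func:`cross_distance_ratio` used to benchmark crosses against a
    segregant panel.
    """
    a = np.atleast_2d(parent_a_reps)
    b = np.atleast_2d(parent_b_reps)
    s = np.atleast_2d(segregant_rows)
    denom = float(_pairwise_distances(a, b).mean())
    if denom == 0:
        raise ZeroDivisionError("parents coincide")
    mids = midparent_points(a, b)
    d = _pairwise_distances(s, mids).reshape(len(s), -1).mean(axis=1)
    return d / denom


def group_location_test(values_1, values_2) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney U test between two groups.

    Exact null distribution when both groups have ≤ 20 members and the data
    carry no ties; normal approximation with tie correction otherwise.
    Returns (U statistic of the first group, two-sided p).
    """
    x = np.asarray(values_1, dtype=float)
    y = np.asarray(values_2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError("empty group")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cell_volume_from_area(area) -> np.ndarray | float:
    """Cell volume (fL) from projected area via the 3/2 power law.

    V = c · A^(3/2) with c = 4/(3·sqrt(π)), the constant for which a sphere's
    projected disk area maps back to the sphere volume.  Absolute values are
    convention-dependent; volume ratios between strains are not.
    """
    a = np.asarray(area, dtype=float)
    if np.any(a <= 0):
        raise ValueError("area must be positive")
    v = SPHERE_VOLUME_CONSTANT * a**1.5
    return float(v) if np.isscalar(area) else v


# ---------------------------------------------------------------------------
# lineage-wide summaries
# ---------------------------------------------------------------------------

def lineage_edge_distances(
    space: PhenoSpace,
    replicate_z: pd.DataFrame,
    lineage: LineageGraph,
    ccr_threshold: float = DEFAULT_CCR,
) -> pd.DataFrame:
    """Per breeding event: distance of the child from its parent(s).

    For single-parent events the parent–child replicate distances are
    reported; for crosses both the distance to the mid-parent points and
    (in separate rows per parent) the distance to each parent, since either
    comparison is informative about a hybrid.  ``replicate_z`` must be
    indexed by (strain, replicate).
    """
    rows = []
    strains = set(replicate_z.index.get_level_values("strain"))
    for child, info in lineage.events().items():
        parents = info["parents"]
        btype = info["breeding_type"]
        if child not in strains or any(p not in strains for p in parents):
            continue
        child_reps = replicate_z.xs(child, level="strain")
        if btype in ("cross", "cross_mutagen"):
            sa, k = _scores(space, replicate_z.xs(parents[0], level="strain"),
                            ccr_threshold)
            sb, _ = _scores(space, replicate_z.xs(parents[1], level="strain"),
                            ccr_threshold)
            sh, _ = _scores(space, child_reps, ccr_threshold)
            summ = hybrid_midparent_distances(
                sh, midparent_points(sa, sb), pair=(child, "midparent"))
            rows.append((child, "+".join(parents), btype, "midparent",
                         summ.mean, summ.sd, summ.n_pairs, k))
            for p in parents:
                ds = strain_pair_distances(
                    space, child_reps, replicate_z.xs(p, level="strain"),
                    ccr_threshold, pair=(child, p))
                rows.append((child, p, btype, "parent", ds.mean, ds.sd,
                             ds.n_pairs, ds.n_components_used))
        else:
            ds = strain_pair_distances(
                space, child_reps, replicate_z.xs(parents[0], level="strain"),
                ccr_threshold, pair=(child, parents[0]))
            rows.append((child, parents[0], btype, "parent", ds.mean, ds.sd,
                         ds.n_pairs, ds.n_components_used))
    return pd.DataFrame(
        rows, columns=["child", "parents", "breeding_type", "comparison",
                       "mean_distance", "sd_distance", "n_pairs",
                       "n_components"],
    )
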