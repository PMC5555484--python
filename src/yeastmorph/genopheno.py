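"""Genetic distance versus phenotypic similarity.

Pairs of strains are compared on two axes: genetic distance — the proportion
of co-called biallelic sites whose 0/1/2 diploid genotype codes differ — and
phenotypic similarity — the Pearson correlation of their PC-score vectors
over the components retained at CCR 90%.  The association between the two is
summarized by Kendall's τ-b rank correlation (tie-corrected, two-sided test)
and an ordinary least-squares regression line of similarity on distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix


class UndefinedDistanceError(ValueError):
    """No co-called sites for a strain pair."""


@dataclass
class GenoPhenoResult:
    kendall_tau: float
    p_value: float
    slope: float
    intercept: float
    n_pairs: int


def snp_difference_proportion(genotypes: GenotypeMatrix,
                              strain_x: str, strain_y: str) -> float:
    """Fraction of co-called sites with differing 0/1/2 genotype codes.

    Sites missing in either strain are excluded pairwise.  This is the most
    literal "proportion of SNP differences"; an allele-sharing variant is
    available via :func:`allele_sharing_distance`.
    """
    gx = genotypes.calls.loc[strain_x].to_numpy(dtype=float)
    gy = genotypes.calls.loc[strain_y].to_numpy(dtype=float)
    ok = ~np.isnan(gx) & ~np.isnan(gy)
    if not ok.any():
        raise UndefinedDistanceError(
            f"no co-called sites for {strain_x!r} and {strain_y!r}"
        )
    return float(np.mean(gx[ok] != gy[ok]))


def allele_sharing_distance(genotypes: GenotypeMatrix,
                            strain_x: str, strain_y: str) -> float:
    """Mean |allele-count difference| / 2 over co-called sites (in [0, 1])."""
    gx = genotypes.calls.loc[strain_x].to_numpy(dtype=float)
    gy = genotypes.calls.loc[strain_y].to_numpy(dtype=float)
    ok = ~np.isnan(gx) & ~np.isnan(gy)
    if not ok.any():
        raise UndefinedDistanceError(
            f"no co-called sites for {strain_x!r} and {strain_y!r}"
        )
    return float(np.mean(np.abs(gx[ok] - gy[ok])) / 2.0)


def pairwise_comparisons(
    genotypes: GenotypeMatrix,
    scores: pd.DataFrame,
    distance: str = "difference",
) -> pd.DataFrame:
    """All strain-pair (genetic distance, phenotypic similarity) points.

    ``scores`` is strains × components (the CCR-selected PC scores);
    similarity is the Pearson R between the two strains' score vectors.
    Only strains present in both inputs are compared; n strains yield
    C(n, 2) pairs.
    """
    dist_fn = {"difference": snp_difference_proportion,
               "allele-sharing": allele_sharing_distance}[distance]
    strains = [s for s in scores.index if s in set(genotypes.strains)]
    rows = []
    for a, b in combinations(strains, 2):
        gd = dist_fn(genotypes, a, b)
        sa = scores.loc[a].to_numpy(dtype=float)
        sb = scores.loc[b].to_numpy(dtype=float)
        if sa.std() == 0 or sb.std() == 0:
            raise ValueError(f"constant score vector for {a!r} or {b!r}")
        sim = float(np.corrcoef(sa, sb)[0, 1])
        rows.append((a, b, gd, sim))
    return pd.DataFrame(rows, columns=["strain_x", "strain_y",
                                       "genetic_distance",
                                       "phenotypic_similarity"])


def geno_pheno_correlation(comparisons: pd.DataFrame) -> GenoPhenoResult:
    """Kendall τ-b + OLS line of phenotypic similarity on genetic distance."""
    if len(comparisons) < 3:
        raise ValueError("need >=3 pairs")
    x = comparisons["genetic_distance"].to_numpy(dtype=float)
    y = comparisons["phenotypic_similarity"].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant axis; correlation undefined")
    tau = stats.kendalltau(x, y)
    line = stats.linregress(x, y)
    return GenoPhenoResult(
        kendall_tau=float(tau.statistic),
        p_value=float(tau.pvalue),
        slope=float(line.slope),
        intercept=float(line.intercept),
        n_pairs=len(comparisons),
    )
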