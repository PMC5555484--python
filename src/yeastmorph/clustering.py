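"""Correlation-dissimilarity hierarchical clustering of strains.

Strains with similar morphological profiles have highly correlated PC-score
vectors, so dissimilarity is taken as 1 − R (Pearson) between strain score
vectors over the components retained at CCR 60%, and the strains are merged
by average linkage (UPGMA).  Clade stability is assessed by an ordinary
bootstrap: traits are resampled with replacement, the space and tree are
rebuilt, and each clade's support is the fraction of resampled trees that
recover it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import pca as _pca


class UndefinedCorrelationError(ValueError):
    """A strain's score vector has zero variance — Pearson R undefined."""


@dataclass
class Dendrogram:
    """UPGMA merge tree over strain leaves.

    ``linkage`` is the scipy linkage matrix; ``support`` maps each internal
    clade (frozenset of leaf labels) to a bootstrap proportion when computed.
    """

    linkage: np.ndarray = field(repr=False)
    leaves: list[str]
    support: dict[frozenset, float] | None = None

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def clades(self) -> list[frozenset]:
        """Leaf sets of the internal nodes, in merge order."""
        n = len(self.leaves)
        sets: dict[int, frozenset] = {i: frozenset([self.leaves[i]])
                                      for i in range(n)}
        out = []
        for i, (a, b, _, _) in enumerate(self.linkage):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + i] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths and support as node labels."""
        n = len(self.leaves)
        heights = {i: 0.0 for i in range(n)}
        names: dict[int, str] = {i: self.leaves[i] for i in range(n)}
        sets: dict[int, frozenset] = {i: frozenset([self.leaves[i]])
                                      for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            node = n + i
            sets[node] = sets[a] | sets[b]
            label = ""
            if self.support is not None:
                sup = self.support.get(sets[node])
                if sup is not None:
                    label = f"{sup:.3f}"
            la = h - heights[a]
            lb = h - heights[b]
            names[node] = f"({names[a]}:{la:.10g},{names[b]}:{lb:.10g}){label}"
            heights[node] = h
        return names[n + len(self.linkage) - 1] + ";"


def correlation_dissimilarity(scores: pd.DataFrame) -> pd.DataFrame:
    """D = 1 − Pearson R between strain score vectors; D ∈ [0, 2]."""
    X = scores.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need >=2 components for a correlation")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        strain = scores.index[int(np.flatnonzero(sd == 0)[0])]
        raise UndefinedCorrelationError(
            f"strain {strain!r} has a constant score vector"
        )
    R = np.corrcoef(X)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, 2.0)
    return pd.DataFrame(D, index=scores.index, columns=scores.index)


def average_linkage_hca(D: pd.DataFrame) -> Dendrogram:
    """UPGMA dendrogram from a symmetric zero-diagonal dissimilarity matrix.

    Leaves are ordered lexicographically before linkage so ties resolve the
    same way on any input ordering.
    """
    A = D.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("dissimilarity matrix is not symmetric")
    if not np.allclose(np.diag(A), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix has a nonzero diagonal")
    order = np.argsort(D.index.astype(str))
    labels = [str(D.index[i]) for i in order]
    A = A[np.ix_(order, order)]
    Z = hierarchy.linkage(squareform(A, checks=False), method="average")
    return Dendrogram(linkage=Z, leaves=labels)


def cluster_strains(
    strain_z: pd.DataFrame,
    ccr_threshold: float = 0.60,
) -> Dendrogram:
    """Build the space from strain Z rows and cluster at the CCR threshold."""
    space = _pca.build_pca(strain_z)
    k = max(2, _pca.components_for_ccr(space, ccr_threshold))
    scores = _pca.project(space, strain_z, n_components=k)
    return average_linkage_hca(correlation_dissimilarity(scores))


def bootstrap_support(
    strain_z: pd.DataFrame,
    n_boot: int = 100,
    seed: int = 0,
    ccr_threshold: float = 0.60,
) -> Dendrogram:
    """Trait-resampling bootstrap support for every clade of the tree.

    Rebuilds the space and tree from traits resampled with replacement,
    ``n_boot`` times; support of a clade is the fraction of resampled trees
    containing it.  (Ordinary bootstrap proportions, not multiscale/AU
    p-values.)
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    base = cluster_strains(strain_z, ccr_threshold)
    clades = [c for c in base.clades() if len(c) < len(base.leaves)]
    counts = {c: 0 for c in clades}
    rng = np.random.default_rng(seed)
    n_traits = strain_z.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_traits, size=n_traits)
        zb = strain_z.iloc[:, cols]
        zb.columns = [f"t{j}" for j in range(n_traits)]
        try:
            tree = cluster_strains(zb, ccr_threshold)
        except (UndefinedCorrelationError, _pca.DegenerateSpaceError):
            continue
        found = set(tree.clades())
        for c in clades:
            if c in found:
                counts[c] += 1
    support = {c: counts[c] / n_boot for c in clades}
    support[frozenset(base.leaves)] = 1.0
    return Dendrogram(linkage=base.linkage, leaves=base.leaves, support=support)


def parse_newick_topology(newick: str) -> set[frozenset]:
    """Clade sets of a Newick string (topology only; for round-trip checks)."""
    clades: set[frozenset] = set()

    def parse(s: str, i: int) -> tuple[frozenset, int]:
        if s[i] == "(":
            members: set = set()
            i += 1
            while True:
                sub, i = parse(s, i)
                members |= sub
                if s[i] == ",":
                    i += 1
                    continue
                assert s[i] == ")"
                i += 1
                break
            # skip label / branch length
            while i < len(s) and s[i] not in ",();":
                i += 1
            clade = frozenset(members)
            clades.add(clade)
            return clade, i
        j = i
        while s[j] not in ",();:":
            j += 1
        name = s[i:j]
        while j < len(s) and s[j] not in ",();":
            j += 1
        return frozenset([name]), j

    parse(newick.strip(), 0)
    return clades
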