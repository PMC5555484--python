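"""Morphological trait catalog.

CalMorph-style phenotyping reduces each cell population to a fixed panel of
501 numeric traits describing cell, actin and nuclear-DNA morphology.  Every
downstream stage of the pipeline keys on two per-trait annotations only:

* ``family_class`` — the value domain, which fixes the GLM family used to
  normalize the trait (``unbounded`` → Gaussian/identity, ``positive`` →
  Gamma/log, ``proportion`` → Beta/logit);
* ``is_noise`` — whether the trait quantifies cell-to-cell variability
  (a coefficient of variation) rather than a population mean; the 220 noise
  traits feed the phenotypic-potential robustness score.

The packaged default catalog is generated deterministically with SCMD-style
identifiers (``C…``/``A…``/``D…`` prefixes for cell-wall, actin and nuclear
traits; ``CCV``/``ACV``/``DCV`` prefixes for their cell-to-cell variation
counterparts).  Users holding the real trait definitions can supply their own
catalog file with explicit family assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

FAMILIES = ("unbounded", "positive", "proportion")

#: canonical panel size of the diploid trait set
N_TRAITS = 501
#: number of cell-to-cell variability ("noise") traits in the panel
N_NOISE_TRAITS = 220


class CatalogError(ValueError):
    """Raised when a trait catalog violates its invariants."""


@dataclass(frozen=True)
class TraitCatalog:
    """Panel of morphological traits with family and noise annotations.

    Parameters
    ----------
    table:
        DataFrame indexed by ``trait_id`` with columns ``family_class``
        (one of :data:`FAMILIES`), ``is_noise`` (bool) and ``description``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"family_class", "is_noise", "description"}
        missing = required - set(t.columns)
        if missing:
            raise CatalogError(f"catalog missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].tolist()
            raise CatalogError(f"duplicate trait ids: {dups[:5]}")
        bad = set(t["family_class"]) - set(FAMILIES)
        if bad:
            raise CatalogError(f"unknown family_class values: {sorted(bad)}")

    # -- accessors ---------------------------------------------------------
    @property
    def trait_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_traits(self) -> int:
        return len(self.table)

    @property
    def noise_trait_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_noise"]])

    @property
    def n_noise_traits(self) -> int:
        return int(self.table["is_noise"].sum())

    def family_of(self, trait_id: str) -> str:
        return str(self.table.at[trait_id, "family_class"])

    def families(self) -> pd.Series:
        """family_class per trait, indexed by trait_id."""
        return self.table["family_class"]

    def validate_panel(self) -> None:
        """Assert the canonical 501-trait / 220-noise panel sizes."""
        if self.n_traits != N_TRAITS:
            raise CatalogError(
                f"expected {N_TRAITS} traits, catalog has {self.n_traits}"
            )
        if self.n_noise_traits != N_NOISE_TRAITS:
            raise CatalogError(
                f"expected {N_NOISE_TRAITS} noise traits, catalog has "
                f"{self.n_noise_traits}"
            )


# organelle channels: (mean-trait prefix, CV-trait prefix, human label,
#  n mean traits, n CV traits, per-channel family split of the mean traits
#  as (n_proportion, n_positive, n_unbounded))
_CHANNELS = (
    ("C", "CCV", "cell wall", 115, 90, (40, 50, 25)),
    ("A", "ACV", "actin", 85, 70, (30, 35, 20)),
    ("D", "DCV", "nuclear DNA", 81, 60, (25, 36, 20)),
)

_MEAN_KIND = {
    "proportion": "ratio",
    "positive": "size",
    "unbounded": "shape deviation",
}


def default_catalog() -> TraitCatalog:
    """Deterministically generated 501-trait diploid panel.

    The panel mirrors the structure of the CalMorph diploid trait set: three
    staining channels (cell wall, actin, nuclear DNA), each contributing
    population-mean traits in the three value domains plus coefficient-of-
    variation noise traits.  Counts per channel sum to 501 traits of which
    exactly 220 are noise traits.
    """
    rows = []
    for prefix, cv_prefix, label, n_mean, n_cv, (n_prop, n_pos, n_unb) in _CHANNELS:
        fams = (
            ["proportion"] * n_prop + ["positive"] * n_pos + ["unbounded"] * n_unb
        )
        assert len(fams) == n_mean
        for i, fam in enumerate(fams, start=101):
            rows.append(
                (
                    f"{prefix}{i}_A",
                    fam,
                    False,
                    f"{label} {_MEAN_KIND[fam]} trait {i}",
                )
            )
        # CV (cell-to-cell variability) traits are strictly positive
        for i in range(101, 101 + n_cv):
            rows.append(
                (
                    f"{cv_prefix}{i}_A",
                    "positive",
                    True,
                    f"{label} cell-to-cell variation (CV) trait {i}",
                )
            )
    table = pd.DataFrame(
        rows, columns=["trait_id", "family_class", "is_noise", "description"]
    ).set_index("trait_id")
    cat = TraitCatalog(table)
    cat.validate_panel()
    return cat


def read_catalog(path, strict_panel: bool = False) -> TraitCatalog:
    """Read a user-supplied catalog (TSV/CSV with explicit columns).

    Expected columns: ``trait_id``, ``family_class``, ``is_noise``,
    optionally ``description``.  With ``strict_panel=True`` the canonical
    501/220 counts are enforced.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if "trait_id" not in df.columns:
        raise CatalogError("catalog file lacks a 'trait_id' column")
    if "description" not in df.columns:
        df["description"] = ""
    df["is_noise"] = df["is_noise"].astype(bool)
    cat = TraitCatalog(df.set_index("trait_id")[
        ["family_class", "is_noise", "description"]
    ])
    if strict_panel:
        cat.validate_panel()
    return cat


def write_catalog(catalog: TraitCatalog, path) -> None:
    catalog.table.reset_index().to_csv(path, sep="\t", index=False)


def _sniff_sep(path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","
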