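"""Shared fixtures: a reduced trait catalog and small synthetic cohorts.

Unit tests run on a 45-trait catalog (20 noise traits) so that per-test GLM
work stays in the sub-second range; the acceptance tests use the full
501-trait panel.
"""

from __future__ import annotations

import pandas as pd
import pytest

from yeastmorph.catalog import TraitCatalog
from yeastmorph.simulate import BreedingEvent, SyntheticSpec, generate_cohort


def make_catalog(n_unbounded: int = 10, n_positive: int = 10,
                 n_proportion: int = 10, n_noise: int = 15) -> TraitCatalog:
    """A reduced but structurally faithful catalog (noise traits are CVs)."""
    rows = []
    for i in range(n_unbounded):
        rows.append((f"u{i}", "unbounded", False, "shape deviation"))
    for i in range(n_positive):
        rows.append((f"p{i}", "positive", False, "size"))
    for i in range(n_proportion):
        rows.append((f"q{i}", "proportion", False, "ratio"))
    for i in range(n_noise):
        rows.append((f"cv{i}", "positive", True, "cell-to-cell variation"))
    table = pd.DataFrame(
        rows, columns=["trait_id", "family_class", "is_noise", "description"]
    ).set_index("trait_id")
    return TraitCatalog(table)


@pytest.fixture(scope="session")
def small_catalog() -> TraitCatalog:
    return make_catalog()


@pytest.fixture(scope="session")
def small_cohort(small_catalog):
    """Cohort over a 4-strain lineage exercising all breeding modes."""
    spec = SyntheticSpec(
        founders=("A", "B"),
        events=(
            BreedingEvent("C", ("A",), "spontaneous"),
            BreedingEvent("M", ("A",), "mutagen"),
            BreedingEvent("H", ("A", "B"), "cross"),
        ),
        catalog=small_catalog,
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def small_lineage(small_cohort):
    return small_cohort[1]


@pytest.fixture(scope="session")
def small_genotypes(small_cohort):
    return small_cohort[2]
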