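"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a replicate-level morphological phenotyping study of
a breeding lineage: every strain has a latent per-trait linear predictor on
the GLM link scale (identity / log / logit by trait family), breeding events
derive child predictors from their parents, and replicate cultures add
family-appropriate link-scale noise before transforming back to the natural
scale — so proportions stay in [0, 1] and positive traits stay positive by
construction.

Breeding events mirror the three breeding modes:

* ``spontaneous`` — a small number of traits shifted (an isolate carrying a
  driver mutation and little else);
* ``mutagen``      — many traits shifted (off-target mutation load);
* ``cross``        — the mid-parent predictor plus an isotropic inbreeding
  deviation on every trait (``cross_mutagen`` adds a mutagen-style shift).

Genotypes evolve along the same lineage: founders carry their own mutation
sets relative to a common reference genome, each breeding step adds a
Poisson number of new SNPs, and crosses draw one allele per parent per site,
so genetic distance tracks lineage depth.  Effects are injected on the link
scale, which makes the expected Wald Z of a shifted trait approximately
(effect / replicate SD) regardless of family, and every injected effect is
recorded in the returned ground-truth record.

All randomness flows from the single ``seed``; equal seeds give identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import TraitCatalog, default_catalog
from .io import BREEDING_TYPES, GenotypeMatrix, LineageGraph, TraitTable

REFERENCE_STRAIN = "reference"

#: link-scale replicate noise SD per trait family
DEFAULT_REPLICATE_SD = {"unbounded": 0.20, "positive": 0.20, "proportion": 0.20}
#: link-scale SD of founder strain effects around the reference baseline
DEFAULT_FOUNDER_SD = 0.5
#: link-scale magnitude of one injected trait shift
DEFAULT_EFFECT = 0.8
#: traits shifted by a spontaneous isolate / a mutagen-induced isolate
K_SPONTANEOUS = 5
K_MUTAGEN = 50
#: link-scale SD of the isotropic inbreeding deviation added by a cross
DEFAULT_CROSS_DEVIATION = 0.3


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class BreedingEvent:
    """One step of the breeding scenario."""

    child: str
    parents: tuple[str, ...]
    breeding_type: str
    n_traits_shifted: int | None = None   # default: 5 spontaneous / 50 mutagen
    effect: float = DEFAULT_EFFECT
    deviation: float = DEFAULT_CROSS_DEVIATION

    def __post_init__(self) -> None:
        if self.breeding_type not in BREEDING_TYPES:
            raise SpecError(f"unknown breeding type {self.breeding_type!r}")
        need_two = self.breeding_type in ("cross", "cross_mutagen")
        if need_two != (len(self.parents) == 2):
            raise SpecError(
                f"{self.breeding_type} event for {self.child!r} has "
                f"{len(self.parents)} parent(s)"
            )
        if self.effect < 0 or self.deviation < 0:
            raise SpecError("effect and deviation must be >= 0")

    @property
    def k_shifted(self) -> int:
        if self.n_traits_shifted is not None:
            return self.n_traits_shifted
        if self.breeding_type == "spontaneous":
            return K_SPONTANEOUS
        if self.breeding_type in ("mutagen", "cross_mutagen"):
            return K_MUTAGEN
        return 0


def default_events() -> tuple[BreedingEvent, ...]:
    """A small lineage exercising all three breeding modes."""
    return (
        BreedingEvent("K601", ("K6",), "spontaneous"),
        BreedingEvent("K701", ("K7",), "spontaneous"),
        BreedingEvent("K1701", ("K7",), "mutagen"),
        BreedingEvent("K13", ("K9", "K10"), "cross"),
        BreedingEvent("K1601", ("K7", "K9"), "cross"),
        BreedingEvent("K1801", ("K7", "K10"), "cross_mutagen"),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Study design of a synthetic cohort.

    Defaults reproduce the study conditions the pipeline targets: 5
    replicate cultures per strain, 11 reference replicates, the full
    501-trait catalog, a single rich medium.
    """

    founders: tuple[str, ...] = ("K6", "K7", "K9", "K10")
    events: tuple[BreedingEvent, ...] = field(default_factory=default_events)
    n_replicates: int = 5
    n_reference_replicates: int = 11
    catalog: TraitCatalog | None = None
    replicate_sd: dict = field(default_factory=lambda: dict(DEFAULT_REPLICATE_SD))
    founder_sd: float = DEFAULT_FOUNDER_SD
    media: tuple[str, ...] = ("YPD",)
    medium_sd: float = 0.3
    noise_inflation: dict = field(default_factory=dict)  # strain -> factor
    n_sites: int = 1000
    founder_mutations: float = 150.0   # Poisson mean per founder
    edge_mutations: float = 25.0       # Poisson mean per breeding event
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_reference_replicates < 2:
            raise SpecError("replicate counts must be positive")
        if any(sd < 0 for sd in self.replicate_sd.values()):
            raise SpecError("replicate SDs must be >= 0")
        if any(f < 0 for f in self.noise_inflation.values()):
            raise SpecError("noise inflation must be >= 0")
        if len(self.media) < 1:
            raise SpecError("need at least one medium")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


# link / inverse-link per family ------------------------------------------

def _inverse_link(eta: np.ndarray, family: str) -> np.ndarray:
    if family == "unbounded":
        return eta
    if family == "positive":
        return np.exp(eta)
    return 1.0 / (1.0 + np.exp(-eta))   # proportion


_BASELINE = {"unbounded": (0.0, 1.0), "positive": (3.0, 0.5),
             "proportion": (-0.5, 0.5)}


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[TraitTable, LineageGraph, GenotypeMatrix, dict]:
    """Draw one cohort: trait table, lineage, genotypes, ground truth."""
    rng = np.random.default_rng(spec.seed)
    catalog = spec.catalog if spec.catalog is not None else default_catalog()
    fams = catalog.families().to_numpy()
    is_noise = catalog.table["is_noise"].to_numpy()
    n_traits = catalog.n_traits
    trait_ids = catalog.trait_ids

    # latent linear predictors -------------------------------------------
    # Strain effects live on the mean traits; the noise (CV) traits carry a
    # strain signal only through noise_inflation, so an unperturbed strain's
    # phenotypic potential stays at its nominal calibration.
    baseline = np.empty(n_traits)
    for fam, (mu, sd) in _BASELINE.items():
        mask = fams == fam
        baseline[mask] = rng.normal(mu, sd, mask.sum())
    mean_idx = np.flatnonzero(~is_noise)
    eta: dict[str, np.ndarray] = {REFERENCE_STRAIN: baseline}
    for f in spec.founders:
        e = baseline.copy()
        e[mean_idx] += rng.normal(0.0, spec.founder_sd, len(mean_idx))
        eta[f] = e

    truth: dict = {"shifted_traits": {}, "cross_deviation": {},
                   "noise_inflation": dict(spec.noise_inflation),
                   "events": [], "medium_effects": {}}
    g = nx.DiGraph()
    for ev in spec.events:
        for p in ev.parents:
            if p not in eta:
                raise SpecError(f"event parent {p!r} not yet defined")
            g.add_edge(p, ev.child, breeding_type=ev.breeding_type)
        if ev.breeding_type in ("cross", "cross_mutagen"):
            child_eta = np.mean([eta[p] for p in ev.parents], axis=0)
            child_eta[mean_idx] += rng.normal(0.0, ev.deviation, len(mean_idx))
            truth["cross_deviation"][ev.child] = ev.deviation
        else:
            child_eta = eta[ev.parents[0]].copy()
        k = ev.k_shifted
        shifted: list[str] = []
        if k > 0:
            idx = rng.choice(mean_idx, size=min(k, len(mean_idx)),
                             replace=False)
            signs = rng.choice([-1.0, 1.0], size=len(idx))
            child_eta[idx] += ev.effect * signs
            shifted = [trait_ids[i] for i in idx]
        eta[ev.child] = child_eta
        truth["shifted_traits"][ev.child] = shifted
        truth["events"].append(
            {"child": ev.child, "parents": list(ev.parents),
             "breeding_type": ev.breeding_type, "k_shifted": k,
             "effect": ev.effect}
        )
    lineage = LineageGraph(g)

    # medium effects (link scale), first medium is the base ---------------
    medium_effect = {spec.media[0]: np.zeros(n_traits)}
    for m in spec.media[1:]:
        medium_effect[m] = rng.normal(0.0, spec.medium_sd, n_traits)
        truth["medium_effects"][m] = medium_effect[m].tolist()

    # replicate observations ----------------------------------------------
    sd_by_trait = np.array([spec.replicate_sd[f] for f in fams])
    records = []
    strain_order = [REFERENCE_STRAIN] + [s for s in eta if s != REFERENCE_STRAIN]
    for si, strain in enumerate(strain_order):
        n_reps = (spec.n_reference_replicates if strain == REFERENCE_STRAIN
                  else spec.n_replicates)
        # the reference is cultured in every medium; each other strain in one
        media = spec.media if strain == REFERENCE_STRAIN else \
            (spec.media[si % len(spec.media)],)
        sd = sd_by_trait.copy()
        strain_eta = eta[strain]
        infl = spec.noise_inflation.get(strain, 1.0)
        if infl != 1.0:
            # a fragile strain has elevated cell-to-cell variability: its CV
            # readouts scale by the factor (a log-scale shift for the
            # positive-family CV traits) and fluctuate more between cultures
            sd = np.where(is_noise, sd * infl, sd)
            strain_eta = strain_eta.copy()
            pos_noise = is_noise & (fams == "positive")
            strain_eta[pos_noise] += np.log(infl)
            other_noise = is_noise & ~pos_noise
            strain_eta[other_noise] += (infl - 1.0) * sd_by_trait[other_noise]
        rep_i = 0
        for medium in media:
            for _ in range(n_reps):
                rep_i += 1
                eta_obs = strain_eta + medium_effect[medium] + \
                    rng.normal(0.0, sd)
                values = np.empty(n_traits)
                for fam in _BASELINE:
                    mask = fams == fam
                    values[mask] = _inverse_link(eta_obs[mask], fam)
                records.append(
                    [strain, f"r{rep_i}", medium,
                     int(rng.integers(200, 401)), *values]
                )
    table = pd.DataFrame(records,
                         columns=["strain", "replicate", "medium",
                                  "cell_count", *trait_ids])
    trait_table = TraitTable(table, catalog)

    genotypes = _generate_genotypes(spec, strain_order, rng)
    truth["eta"] = {s: e.tolist() for s, e in eta.items()}
    return trait_table, lineage, genotypes, truth


def _generate_genotypes(spec: SyntheticSpec, strain_order: list[str],
                        rng: np.random.Generator) -> GenotypeMatrix:
    n = spec.n_sites
    calls: dict[str, np.ndarray] = {REFERENCE_STRAIN: np.zeros(n)}
    for s in spec.founders:
        geno = np.zeros(n)
        k = min(int(rng.poisson(spec.founder_mutations)), n)
        idx = rng.choice(n, size=k, replace=False)
        geno[idx] = rng.choice([1.0, 2.0], size=k, p=[0.2, 0.8])
        calls[s] = geno
    for ev in spec.events:
        if ev.breeding_type in ("cross", "cross_mutagen"):
            pa, pb = (calls[p] for p in ev.parents)
            ha = rng.binomial(1, pa / 2.0)
            hb = rng.binomial(1, pb / 2.0)
            geno = (ha + hb).astype(float)
        else:
            geno = calls[ev.parents[0]].copy()
        k = min(int(rng.poisson(spec.edge_mutations)), n)
        idx = rng.choice(n, size=k, replace=False)
        geno[idx] = rng.choice([1.0, 2.0], size=k)
        calls[ev.child] = geno
    df = pd.DataFrame(
        np.vstack([calls[s] for s in strain_order]),
        index=pd.Index(strain_order, name="strain"),
        columns=[f"site{i}" for i in range(n)],
    )
    return GenotypeMatrix(df)


def generate_segregant_panel(
    parent_a_scores: np.ndarray,
    parent_b_scores: np.ndarray,
    n_segregants: int,
    deviation: float,
    seed: int = 0,
) -> np.ndarray:
    """Segregant score rows: mid-parent mean plus isotropic deviation.

    A stand-in for a published segregant panel from a wide cross: each of
    the ``n_segregants`` rows sits at the mean mid-parent point plus
    N(0, deviation²) on every component.
    """
    if n_segregants < 1:
        raise SpecError("n_segregants must be >= 1")
    a = np.atleast_2d(np.asarray(parent_a_scores, dtype=float)).mean(axis=0)
    b = np.atleast_2d(np.asarray(parent_b_scores, dtype=float)).mean(axis=0)
    mid = (a + b) / 2.0
    rng = np.random.default_rng(seed)
    return mid[None, :] + rng.normal(0.0, deviation,
                                     size=(n_segregants, len(mid)))


def null_spec(seed: int = 0, n_strains: int = 1,
              catalog: TraitCatalog | None = None) -> SyntheticSpec:
    """Cohort with no strain effects at all: founders clamped to baseline.

    Used for calibration work (type-I error of screens): every strain's
    expected Z is 0 on every trait.
    """
    founders = tuple(f"S{i+1}" for i in range(n_strains))
    return SyntheticSpec(founders=founders, events=(), founder_sd=0.0,
                         catalog=catalog, seed=seed)
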