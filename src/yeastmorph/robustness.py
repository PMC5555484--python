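"""Phenotypic potential: a scalar robustness score from the noise traits.

Phenotypic noise — trait variability among isogenic cells in a common
environment — indicates how well buffered a cell system is.  The 220 noise
traits of the panel quantify exactly that cell-to-cell variability, and the
phenotypic potential (PP) collapses a replicate's noise-trait Z-profile into
one number in [0, 1]: the fraction of noise traits whose Z falls outside the
reference population's two-sided 95% envelope.  A reference-like replicate
scores near the nominal 0.05 exceedance; a strain whose population is
morphologically heterogeneous (e.g. from an impaired network hub) scores
high on many noise traits at once and its PP rises toward 1.

Strains are compared to a control strain by Dunnett's many-to-one procedure
(multivariate-t adjusted p-values, via scipy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import TraitCatalog

DEFAULT_ENVELOPE_QUANTILE = 0.95
#: a replicate must cover at least this fraction of the noise traits
MIN_NOISE_COVERAGE = 0.90


class InsufficientDataError(ValueError):
    pass


@dataclass
class PPResult:
    """Per-strain phenotypic potential with control comparison."""

    strain_id: str
    pp_per_replicate: np.ndarray = field(repr=False)
    adjusted_p: float = float("nan")
    flagged_vs_control: bool = False

    @property
    def mean(self) -> float:
        return float(np.mean(self.pp_per_replicate))

    @property
    def sd(self) -> float:
        return (float(np.std(self.pp_per_replicate, ddof=1))
                if len(self.pp_per_replicate) > 1 else 0.0)


@dataclass
class NoiseEnvelope:
    """Per-trait two-sided envelope of the reference noise-Z distribution."""

    lower: pd.Series = field(repr=False)
    upper: pd.Series = field(repr=False)
    quantile: float = DEFAULT_ENVELOPE_QUANTILE
    definition: str = "gaussian"

    @property
    def trait_ids(self) -> list[str]:
        return list(self.lower.index)


def reference_noise_envelope(
    reference_noise_z: pd.DataFrame,
    quantile: float = DEFAULT_ENVELOPE_QUANTILE,
    definition: str = "gaussian",
) -> NoiseEnvelope:
    """Estimate the reference envelope from ≥10 reference replicates.

    ``definition='gaussian'`` (default) uses mean ± z_(1+q)/2 · SD per trait,
    which is stable at the typical 10–30 reference replicates;
    ``'empirical'`` uses the raw per-trait quantiles.
    """
    if len(reference_noise_z) < 10:
        raise InsufficientDataError(
            f"need >=10 reference replicates, got {len(reference_noise_z)}"
        )
    if definition == "gaussian":
        mu = reference_noise_z.mean(axis=0)
        sd = reference_noise_z.std(axis=0, ddof=1)
        zq = float(stats.norm.ppf(0.5 + quantile / 2.0))
        lower, upper = mu - zq * sd, mu + zq * sd
    elif definition == "empirical":
        lo_q, hi_q = (1.0 - quantile) / 2.0, (1.0 + quantile) / 2.0
        lower = reference_noise_z.quantile(lo_q, axis=0)
        upper = reference_noise_z.quantile(hi_q, axis=0)
    else:
        raise ValueError(f"unknown envelope definition {definition!r}")
    return NoiseEnvelope(lower=lower, upper=upper, quantile=quantile,
                         definition=definition)


def phenotypic_potential(
    replicate_noise_z: pd.Series,
    envelope: NoiseEnvelope,
    definition: str = "exceedance",
) -> float:
    """PP of one replicate: a scalar in [0, 1] from its noise-trait Z values.

    ``'exceedance'`` (default): fraction of noise traits outside the
    reference envelope.  ``'mean-abs-z'``: mean |Z| over noise traits mapped
    through 1 − exp(−|Z̄|) to stay in [0, 1] (an alternative definition for
    sensitivity analyses; outputs record which was used).
    """
    z = replicate_noise_z.reindex(envelope.trait_ids)
    avail = z.notna()
    if avail.sum() < MIN_NOISE_COVERAGE * len(envelope.trait_ids):
        raise InsufficientDataError(
            f"only {int(avail.sum())}/{len(envelope.trait_ids)} noise traits "
            "available"
        )
    z = z[avail]
    if definition == "exceedance":
        out = (z < envelope.lower[avail]) | (z > envelope.upper[avail])
        return float(out.mean())
    if definition == "mean-abs-z":
        return float(1.0 - np.exp(-np.abs(z).mean()))
    raise ValueError(f"unknown PP definition {definition!r}")


def pp_by_strain(
    replicate_z: pd.DataFrame,
    catalog: TraitCatalog,
    reference: str = "reference",
    quantile: float = DEFAULT_ENVELOPE_QUANTILE,
    definition: str = "exceedance",
    envelope_definition: str = "gaussian",
) -> dict[str, np.ndarray]:
    """Replicate PPs per strain from a (strain, replicate)-indexed Z matrix."""
    noise_ids = [t for t in catalog.noise_trait_ids if t in replicate_z.columns]
    if len(noise_ids) < MIN_NOISE_COVERAGE * catalog.n_noise_traits:
        raise InsufficientDataError(
            f"only {len(noise_ids)}/{catalog.n_noise_traits} noise traits in Z"
        )
    noise_z = replicate_z[noise_ids]
    ref_rows = noise_z.xs(reference, level="strain")
    envelope = reference_noise_envelope(ref_rows, quantile, envelope_definition)
    out: dict[str, np.ndarray] = {}
    for strain in noise_z.index.get_level_values("strain").unique():
        rows = noise_z.xs(strain, level="strain")
        out[str(strain)] = np.array([
            phenotypic_potential(rows.iloc[i], envelope, definition)
            for i in range(len(rows))
        ])
    return out


def dunnett_vs_control(
    pp_by_strain_: dict[str, np.ndarray],
    control: str,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[PPResult]:
    """Dunnett's many-to-one comparison of strain PPs against a control.

    Multiplicity-adjusted p-values come from the multivariate-t reference
    distribution (scipy.stats.dunnett, whose CDF evaluation is Monte-Carlo —
    hence the seed); a strain is flagged when its adjusted p falls below
    ``alpha``.
    """
    if control not in pp_by_strain_:
        raise ValueError(f"control strain {control!r} has no PP values")
    others = sorted(s for s in pp_by_strain_ if s != control)
    if not others:
        raise ValueError("need at least one non-control strain")
    for s, v in pp_by_strain_.items():
        if len(v) < 2:
            raise InsufficientDataError(f"strain {s!r} has <2 replicates")
    res = stats.dunnett(*(np.asarray(pp_by_strain_[s], float) for s in others),
                        control=np.asarray(pp_by_strain_[control], float),
                        random_state=np.random.default_rng(seed))
    results = [PPResult(strain_id=control,
                        pp_per_replicate=np.asarray(pp_by_strain_[control]))]
    for s, p in zip(others, res.pvalue):
        results.append(PPResult(
            strain_id=s,
            pp_per_replicate=np.asarray(pp_by_strain_[s]),
            adjusted_p=float(p),
            flagged_vs_control=bool(p < alpha),
        ))
    return results
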