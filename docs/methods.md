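# Methods

This note documents the statistical model behind `yeastmorph`, the choices
that were genuinely open, and what the synthetic-data tests do and do not
establish about real data.

## Trait panel

The pipeline is built around a CalMorph-style panel of 501 replicate-level
morphological traits, 220 of which quantify cell-to-cell variability
(coefficients of variation) within an isogenic culture. The published trait
definitions are not redistributed here; the packaged catalog
(`yeastmorph.catalog.default_catalog`) is a deterministic stand-in with
SCMD-style identifiers that preserves everything downstream code consumes:
the counts (501/220), the three value-domain families, and the noise flags.
Its family composition — 65 unbounded, 341 positive (including all 220 CV
traits), 95 proportion — is this package's own choice of a realistic mix;
users holding the real catalog supply it as a TSV with explicit
`family_class` and `is_noise` columns (explicit columns were preferred over
inferring the family from identifier patterns, which is not reliable for
arbitrary user ids). Catalog counts are asserted at load time.

## GLM normalization

Each trait is fitted by maximum likelihood with a family fixed by its value
domain:

| domain     | family   | mean link | engine |
|------------|----------|-----------|--------|
| unbounded  | Gaussian | identity  | statsmodels GLM |
| positive   | Gamma    | log       | statsmodels GLM |
| proportion | Beta     | logit     | statsmodels BetaModel; quasi-binomial GLM fallback |

Proportion values exactly 0 or 1 are shrunk by (y·(n−1)+0.5)/n with n the
culture's cell count, keeping the logit finite. Convergence is IRLS/ML with
at most 200 iterations at relative tolerance 1e-8; a trait whose fit fails
is reported and excluded, never imputed. The reference strain (default name
`reference`) is the base level, so each strain coefficient is a contrast
against it and the **strain-level Z** is the Wald statistic β̂/SE.

Two consequential numerical choices:

* **Student-t Wald p-values.** Per-trait sample sizes are small (5 replicates
  per strain, ~11 for the reference), so Wald p-values use a t reference
  with the residual degrees of freedom instead of the normal limit, for all
  families. With normal-limit p-values the Bonferroni screen's family-wise
  error at 501 traits would be an order of magnitude above nominal at these
  sample sizes; with the t reference it sits at nominal (measured by the
  acceptance benchmark).
* **Replicate-level Z.** Distance combinatorics and phenotypic potential
  need one Z per culture. It is computed as a reference-calibrated Wald-type
  score: Z = (g(y) − η̂_ref)/SE, where g is the family's link, η̂_ref the mean
  linked reference observation, and SE the linked reference sample SD
  inflated by √(1 + 1/n_ref). For the Gaussian family this is exactly the
  Wald contrast of the GLM in which every replicate is its own factor level
  with reference-pooled dispersion; for the other families it is the
  delta-method analog. Estimating the null scale from the reference alone
  keeps one strain's perturbation from deflating every other strain's Z.

Model selection uses AIC recomputed as −2ℓ + 2k with k counting the
dispersion/precision parameter, so Gaussian, Gamma and Beta fits are
compared on the same footing; ties break toward fewer parameters. The
likelihood-ratio screen tests 2(ℓ_full − ℓ_reduced) against χ² with the
difference in parameter counts as degrees of freedom, Bonferroni-corrected
across traits. Media effects, when cultures span two media, enter as an
additive term on the link scale (two-way model without interaction); a
medium with no reference observations is rejected as confounded.

## Phenotypic space

PCA is computed by SVD of the row-centered Z matrix. Columns are **not**
rescaled — the GLM stage already put every trait on the Z scale, and
rescaling would amplify traits that barely vary (a `rescale` flag exists for
data that did not pass through the GLM stage). Components with singular
value below 1e-10 of the largest are dropped as numerical rank deficiency,
and each component's sign is fixed by making its largest-magnitude loading
positive, so the decomposition is identical across runs and platforms.
Analyses retain the smallest k whose cumulative contribution ratio reaches
the stage's threshold: 0.90 for distances and genotype–phenotype work, 0.60
for clustering. Full-rank projection is an isometry (checked to 1e-8), so
truncation at a CCR threshold is the only source of distance distortion.

When two populations are compared (variance ratios per component), the PCA
is fitted on the pooled rows, and population spread is the ratio of
per-component score variances plus their cumulative ratio.

## Distances over the lineage

All distance statistics are replicate-combinatoric multisets reported as
mean ± SD: n_x·n_y parent–child distances, n_a·n_b mid-parent points,
n_h·n_a·n_b hybrid-to-midpoint distances (5 replicates everywhere → 25, 25,
125). The cross-distance ratio divides each hybrid-to-midpoint distance by
the **mean** of the parent–parent distances — a single scalar denominator,
which reproduces the 125-combination count per cross; a variant pairing each
numerator with its own parent-replicate denominator is available behind a
flag. For crosses, the per-event report includes both the distance to the
mid-parent points and the distance to each parent, since either comparison
is informative about a hybrid.

Group location differences use the Wilcoxon–Mann–Whitney U test, exact when
both groups have ≤ 20 members and no ties, otherwise the tie-corrected
normal approximation.

Cell volume is derived from projected area as V = 4/(3√π)·A^{3/2}, the
constant for which a sphere's projected disk maps back to the sphere volume.
Absolute femtoliter values are convention-dependent; between-strain volume
ratios are not.

## Phenotypic potential

PP of a replicate is the fraction of the 220 noise traits whose Z lies
outside the reference strain's two-sided 95% envelope. The published PP
formula is defined in work this package does not reproduce; the envelope-
exceedance fraction was chosen as the default because it is a scalar in
[0, 1] computed from the 220 noise parameters whose null calibration
(≈ 0.05 for a reference-like replicate) brackets the low end of PP values
reported for real strains. The envelope is Gaussian (mean ± 1.96 SD per
trait) by default — stable at 10–30 reference replicates, where raw
2.5%/97.5% empirical quantiles are order statistics of the sample extremes —
with an `empirical` option, and a `mean-abs-z` PP definition is available
for sensitivity analyses; outputs record which definition produced them.
Strains are compared to a control by Dunnett's many-to-one procedure via
`scipy.stats.dunnett` (multivariate-t adjusted p-values; the CDF evaluation
is Monte-Carlo, so it is seeded for reproducibility).

## Clustering and genotype–phenotype

Strain dissimilarity is 1 − Pearson R between PC-score vectors over the
CCR-60% components (mean-strain scores by default), clustered by average
linkage (UPGMA, scipy) with leaves pre-sorted lexicographically so ties
resolve identically on any input ordering. Clade stability is an ordinary
bootstrap: traits are resampled with replacement, the space and tree
rebuilt, and each clade's support is its recovery fraction — a deliberate
replacement for approximately-unbiased multiscale-bootstrap p-values, whose
machinery is out of proportion to the role support values play here; the
substitution is recorded in output metadata.

Pairwise genetic distance is the proportion of co-called biallelic sites
whose 0/1/2 diploid codes differ (missing sites excluded pairwise) — the
most literal reading of "proportion of SNP differences"; an allele-sharing
variant is a flag. Association with PC-score similarity is Kendall's τ-b
with tie correction plus an OLS line of similarity on distance.

## Synthetic cohorts

The generator (`yeastmorph.simulate`) draws, per trait, a latent linear
predictor on the GLM link scale and transforms replicate draws back through
the inverse link, so proportions stay in [0, 1] and positive traits stay
positive by construction. Defaults are the study conditions the pipeline
targets: 5 replicates per strain, 11 reference replicates, the 501-trait
panel, one rich medium. Breeding events derive child predictors from
parents: spontaneous isolates shift 5 traits, mutagen isolates 50 (both by
±0.8 on the link scale — 4× the 0.2 replicate SD, a clearly detectable
single-trait effect), and crosses take the mid-parent plus an isotropic
inbreeding deviation of SD 0.3 on every mean trait. Founder strains spread
around the reference with SD 0.5. These magnitudes are this package's own
choice of a realistic regime: per-trait Wald Z values of a few units, as
seen in strain-vs-reference comparisons of real morphological data.

Two structural choices matter for interpretation:

* **Strain effects live on the mean traits only.** The 220 noise traits
  carry strain signal solely through the `noise_inflation` factor, which
  scales a fragile strain's CV readouts (a log-scale shift for the
  positive-family CV traits) and their between-culture scatter. This keeps
  an unperturbed strain's PP at its nominal calibration, mirroring the
  biology the noise traits are meant to isolate; it also means synthetic
  cohorts cannot probe correlations between mean shifts and noise shifts.
* **Genotypes mutate along the pedigree** (founder mutation sets, Poisson
  new SNPs per event, allele draws at crosses), so genetic distance tracks
  lineage depth — the monotone structure the genotype–phenotype analysis
  presumes, not a population-genetic simulation.

The generator produces no trait–trait correlation beyond what the lineage
induces, no per-cell data, and no realistic cell-cycle structure. Passing
tests therefore establish that the machinery is correct and calibrated under
the stated design — not that real morphological data satisfy the GLM family
assignments or that real strains separate as cleanly.

## Problem sizes and benchmarks

`scripts/acceptance.py` (and the end-to-end test suite) measure: the
25/25/125 combinatoric counts on one default cohort; the 501/220 catalog
constants; PC-space isometry on a random 30×501 matrix (≤ 1e-8); Wald-vs-OLS
agreement on 20 Gaussian fixtures (≤ 1e-8); the family-wise error of the
Bonferroni Wald screen over 200 null cohorts of 501 traits (bounded by
nominal + 3 Monte-Carlo SE); mutagen > spontaneous distance ordering over
100 cohorts (≥ 95%); PP/Dunnett power at 3× noise inflation over 100 cohorts
(> 0.9); the hybrid-vs-segregant Mann–Whitney comparison at one 62-segregant
panel (p < 0.01); a hand-computed 3-leaf UPGMA merge sequence; and bootstrap
support > 0.95 for a 10×-separated two-group simulation. Cohort counts
(200/100) were sized to estimate rates with Monte-Carlo SE of a few percent
while keeping a full run in the minutes range on one CPU.

## Known limitations

* The per-trait family assignment is a value-domain heuristic; the published
  per-trait PDF/link table is honored when supplied via a user catalog, but
  family misassignment on real data is not detected beyond fit diagnostics.
* Beta-regression Wald inference at n ≈ 16 relies on the t-referenced
  small-sample correction; its tail calibration is validated only in
  aggregate (through the family-wise error benchmark).
* PP values are definition-dependent; published PP numbers are reproducible
  only with the original data and formula.
* No random-effects or hierarchical models, no empirical-Bayes shrinkage of
  Z, no Mahalanobis distances, no AU cluster p-values.
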