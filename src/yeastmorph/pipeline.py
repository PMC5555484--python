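"""End-to-end orchestration: normalize → space → distances / PP / tree / geno-pheno.

``run_pipeline`` is a pure function of (input files, config, seed): it reads
the trait table, lineage and optional genotypes, builds strain- and
replicate-level Z-profiles, the PCA space, the per-edge distance table, the
phenotypic-potential table, the UPGMA tree with bootstrap support and the
genotype–phenotype pair table, and writes everything plus a machine-readable
run manifest into the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import TraitCatalog, default_catalog, read_catalog
from .clustering import bootstrap_support
from .distances import lineage_edge_distances
from .genopheno import geno_pheno_correlation, pairwise_comparisons
from .glm import ZMatrix, replicate_z_matrix, strain_z_matrix
from .io import read_genotypes, read_lineage, read_trait_table
from .pca import PhenoSpace, build_pca, components_for_ccr, project
from .robustness import dunnett_vs_control, pp_by_strain

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Configuration of a full run (flat YAML/JSON-serializable)."""

    table: str = ""
    lineage: str = ""
    genotypes: str | None = None
    catalog: str | None = None          # None → packaged default catalog
    reference: str = "reference"
    control: str | None = None          # PP control strain; None → reference
    ccr_distance: float = 0.90
    ccr_cluster: float = 0.60
    ccr_genopheno: float = 0.90
    alpha: float = 0.05
    media_adjust: bool = False
    n_boot: int = 100
    seed: int = 0
    out: str = "pipeline_out"

    def __post_init__(self) -> None:
        for name in ("ccr_distance", "ccr_cluster", "ccr_genopheno"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def load_catalog(config: PipelineConfig) -> TraitCatalog:
    if config.catalog:
        return read_catalog(config.catalog)
    return default_catalog()


def write_z(z: ZMatrix, path: Path) -> None:
    df = z.z.copy()
    if isinstance(df.index, pd.MultiIndex):
        df = df.reset_index()
    else:
        df = df.reset_index()
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "reference": z.reference,
        "families": {} if z.families is None else
        {t: str(f) for t, f in z.families.items()},
        "failed_traits": list(z.failed_traits),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def write_space(space: PhenoSpace, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    space.loadings.to_csv(out_dir / "loadings.tsv", sep="\t")
    pd.DataFrame({
        "explained_variance": space.explained_variance,
        "ccr": space.ccr,
    }, index=space.loadings.columns).to_csv(out_dir / "variance.tsv", sep="\t")
    space.center.to_csv(out_dir / "center.tsv", sep="\t", header=["center"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "yeastmorph_version": __version__,
        "config": asdict(config),
        "outputs": {},
        "warnings": [],
    }

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    catalog = stage("catalog", load_catalog, config)
    table = stage("read_table", read_trait_table, config.table, catalog)
    lineage = stage("read_lineage", read_lineage, config.lineage)

    # --- normalize -------------------------------------------------------
    strain_z = stage("normalize", strain_z_matrix, table, config.reference,
                     media_adjust=config.media_adjust)
    rep_z = stage("normalize", replicate_z_matrix, table, config.reference,
                  media_adjust=config.media_adjust)
    common = [t for t in strain_z.z.columns if t in set(rep_z.z.columns)]
    strain_df = strain_z.z[common]
    rep_df = rep_z.z[common]
    write_z(strain_z, out / "z_strain.tsv")
    write_z(rep_z, out / "z_replicate.tsv")
    manifest["outputs"]["z_strain"] = "z_strain.tsv"
    manifest["outputs"]["z_replicate"] = "z_replicate.tsv"
    if strain_z.failed_traits:
        manifest["warnings"].append(
            f"{len(strain_z.failed_traits)} trait(s) excluded from strain Z"
        )

    # --- phenotypic space -------------------------------------------------
    space = stage("pca", build_pca, strain_df)
    write_space(space, out / "space")
    manifest["outputs"]["space"] = "space/"
    manifest["ccr_components"] = {
        str(thr): components_for_ccr(space, thr)
        for thr in (0.6, 0.7, 0.8, 0.9)
    }

    # --- lineage distances -------------------------------------------------
    dist = stage("distances", lineage_edge_distances, space, rep_df, lineage,
                 ccr_threshold=config.ccr_distance)
    dist.to_csv(out / "distances.tsv", sep="\t", index=False)
    manifest["outputs"]["distances"] = "distances.tsv"

    # --- phenotypic potential ---------------------------------------------
    control = config.control or config.reference
    pps = stage("pp", pp_by_strain, rep_df, catalog,
                reference=config.reference)
    results = stage("pp", dunnett_vs_control, pps, control=control,
                    alpha=config.alpha)
    pp_df = pd.DataFrame([
        {"strain": r.strain_id, "pp_mean": r.mean, "pp_sd": r.sd,
         "adjusted_p": r.adjusted_p, "flagged": r.flagged_vs_control,
         "n_replicates": len(r.pp_per_replicate)}
        for r in results
    ])
    pp_df.to_csv(out / "pp.tsv", sep="\t", index=False)
    manifest["outputs"]["pp"] = "pp.tsv"
    manifest["pp_definition"] = "exceedance/gaussian-envelope-0.95"

    # --- clustering --------------------------------------------------------
    tree = stage("cluster", bootstrap_support, strain_df, n_boot=config.n_boot,
                 seed=config.seed, ccr_threshold=config.ccr_cluster)
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    manifest["outputs"]["tree"] = "tree.nwk"
    manifest["bootstrap"] = {"n_boot": config.n_boot, "seed": config.seed,
                             "support": "ordinary trait-resampling bootstrap"}

    # --- genotype / phenotype ----------------------------------------------
    if config.genotypes:
        geno = stage("genopheno", read_genotypes, config.genotypes)
        k = components_for_ccr(space, config.ccr_genopheno)
        scores = project(space, strain_df, n_components=max(k, 2))
        scores = scores.loc[[s for s in scores.index if s != config.reference]]
        pairs = stage("genopheno", pairwise_comparisons, geno, scores)
        pairs.to_csv(out / "genopheno.tsv", sep="\t", index=False)
        gp = stage("genopheno", geno_pheno_correlation, pairs)
        manifest["outputs"]["genopheno"] = "genopheno.tsv"
        manifest["genopheno"] = {
            "kendall_tau": gp.kendall_tau, "p_value": gp.p_value,
            "slope": gp.slope, "intercept": gp.intercept,
            "n_pairs": gp.n_pairs,
        }

    manifest["errors"] = []
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
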