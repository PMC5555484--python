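#!/usr/bin/env python
"""Normalize raw trait values to Wald Z-profiles against the reference.

Fits each trait's GLM (Gaussian/Gamma/Beta by value domain) with strain as
the explanatory factor and writes two Z matrices under results/: one Z per
strain (for building the phenotype space and clustering) and one Z per
replicate culture (for the distance combinatorics and phenotypic potential).
"""

import argparse
from pathlib import Path

from yeastmorph.catalog import read_catalog
from yeastmorph.glm import replicate_z_matrix, strain_z_matrix
from yeastmorph.io import read_trait_table
from yeastmorph.pipeline import write_z

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

catalog = read_catalog(args.cohort / "catalog.tsv")
table = read_trait_table(args.cohort / "traits.tsv", catalog)

strain_z = strain_z_matrix(table)
rep_z = replicate_z_matrix(table)
args.out.mkdir(parents=True, exist_ok=True)
write_z(strain_z, args.out / "z_strain.tsv")
write_z(rep_z, args.out / "z_replicate.tsv")

absz = strain_z.z.abs()
print(f"strain Z matrix: {strain_z.z.shape[0]} strains x "
      f"{strain_z.z.shape[1]} traits "
      f"({len(strain_z.failed_traits)} traits failed to fit)")
print(f"replicate Z matrix: {rep_z.z.shape[0]} rows")
print(f"median |Z| per strain (vs {strain_z.reference}):")
for strain, med in absz.median(axis=1).sort_values().items():
    print(f"  {strain:<10} {med:6.2f}")
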