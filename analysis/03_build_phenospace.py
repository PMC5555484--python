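#!/usr/bin/env python
"""Build the degenerated orthogonal phenotypic space from strain Z-profiles.

PCA over the per-strain Wald Z matrix; reports how many components the
standard CCR thresholds (60/70/80/90%) retain, writes the space
(loadings, variances, center) under results/space/, and compares the
phenotypic variance of the mutation-bred versus cross-bred strains
per component.
"""

import argparse
from pathlib import Path

import pandas as pd

from yeastmorph.pca import build_pca, components_for_ccr, project, variance_ratio
from yeastmorph.pipeline import write_space

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

z = pd.read_csv(args.results / "z_strain.tsv", sep="\t").set_index("strain")
space = build_pca(z)
write_space(space, args.results / "space")

print(f"phenotypic space: {space.n_components} components over "
      f"{len(space.trait_ids)} traits")
for thr in (0.6, 0.7, 0.8, 0.9):
    print(f"  CCR {thr:.0%} reached by the first "
          f"{components_for_ccr(space, thr)} PC(s)")
shares = space.explained_variance / space.explained_variance.sum()
print("  leading shares:", ", ".join(f"PC{i+1} {s:.0%}"
                                     for i, s in enumerate(shares[:4])))

scores = project(space, z)
crosses = [s for s in ("K13", "K1601", "K1801") if s in scores.index]
mutants = [s for s in ("K601", "K701", "K1701") if s in scores.index]
if len(crosses) >= 2 and len(mutants) >= 2:
    k = components_for_ccr(space, 0.9)
    ratios, cum = variance_ratio(scores.loc[crosses], scores.loc[mutants],
                                 upto=k)
    print(f"variance of cross-bred vs mutation-bred strains over {k} PCs: "
          f"cumulative ratio {cum:.2f}")
    print("  per-component ratios:",
          ", ".join(f"{r:.2f}" for r in ratios))
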