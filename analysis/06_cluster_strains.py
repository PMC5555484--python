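#!/usr/bin/env python
"""Cluster strains by morphological similarity.

Dissimilarity is 1 − R between strain PC-score vectors (components at CCR
60%); the tree is UPGMA with trait-resampling bootstrap support.  Writes
results/tree.nwk.
"""

import argparse
from pathlib import Path

import pandas as pd

from yeastmorph.clustering import bootstrap_support

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--results", type=Path, default=Path("results"))
parser.add_argument("--boot", type=int, default=200)
parser.add_argument("--seed", type=int, default=7)
args = parser.parse_args()

z = pd.read_csv(args.results / "z_strain.tsv", sep="\t").set_index("strain")
tree = bootstrap_support(z, n_boot=args.boot, seed=args.seed,
                         ccr_threshold=0.6)
(args.results / "tree.nwk").write_text(tree.to_newick() + "\n")

print(f"UPGMA tree over {len(tree.leaves)} strains "
      f"({args.boot} bootstrap resamples):")
for clade in tree.clades():
    if 1 < len(clade) < len(tree.leaves):
        members = ",".join(sorted(clade))
        print(f"  support {tree.support[clade]:.2f}  {{{members}}}")
print(f"tree written to {args.results / 'tree.nwk'}")
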