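#!/usr/bin/env python
"""Morphological change at every breeding step, as Euclidean distances.

Projects replicate Z rows onto the components at CCR 90% and computes, per
breeding event, the replicate-combinatoric distance summaries (25 distances
per strain pair, 25 mid-parent points and 125 hybrid-to-midpoint distances
per cross).  Also benchmarks the crosses' mid-parent departure ratios
against a 62-segregant panel whose scatter is matched to the replicate
noise, mirroring the comparison of inbred crosses with a wide-cross
segregant population.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from yeastmorph.distances import (cross_distance_ratio, group_location_test,
                                  lineage_edge_distances, segregant_ratios)
from yeastmorph.io import read_lineage
from yeastmorph.pca import build_pca, components_for_ccr, project
from yeastmorph.simulate import generate_segregant_panel

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--results", type=Path, default=Path("results"))
parser.add_argument("--seed", type=int, default=7)
args = parser.parse_args()

strain_z = pd.read_csv(args.results / "z_strain.tsv",
                       sep="\t").set_index("strain")
rep_z = pd.read_csv(args.results / "z_replicate.tsv",
                    sep="\t").set_index(["strain", "replicate"])
lineage = read_lineage(args.cohort / "lineage.txt")
common = [t for t in strain_z.columns if t in set(rep_z.columns)]
space = build_pca(strain_z[common])
rep_z = rep_z[common]

dist = lineage_edge_distances(space, rep_z, lineage, ccr_threshold=0.9)
dist.to_csv(args.results / "distances.tsv", sep="\t", index=False)
print("parent-child distances (CCR 90%):")
print(dist.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

single = dist[dist["comparison"] == "parent"
              ].set_index("child")["mean_distance"]
if {"K1701", "K601"} <= set(single.index):
    print(f"\nmutagen-bred K1701 moved {single['K1701']:.2f} from its parent "
          f"vs {single['K601']:.2f} for spontaneous K601")

# cross ratios vs a segregant panel
k = components_for_ccr(space, 0.9)
rep = lambda s: rep_z.xs(s, level="strain")  # noqa: E731
ratios = cross_distance_ratio(rep("K9"), rep("K10"), rep("K13"), space,
                              cross=("K9", "K10", "K13"))
sa = project(space, rep("K9"), n_components=k).to_numpy()
sb = project(space, rep("K10"), n_components=k).to_numpy()
sigma = float(np.mean([sa.std(axis=0, ddof=1).mean(),
                       sb.std(axis=0, ddof=1).mean()]))
segs = generate_segregant_panel(sa, sb, 62, sigma, seed=args.seed)
seg_r = segregant_ratios(sa, sb, segs)
_, p = group_location_test(ratios.ratios, seg_r)
pd.DataFrame({
    "group": ["K13 hybrid"] * ratios.n + ["segregant panel"] * len(seg_r),
    "ratio": np.r_[ratios.ratios, seg_r],
}).to_csv(args.results / "cross_ratios.tsv", sep="\t", index=False)
print(f"\ncross-distance ratio of K13: {ratios.mean:.2f} +/- {ratios.sd:.2f} "
      f"(n = {ratios.n})")
print(f"segregant panel ratio:       {seg_r.mean():.2f} +/- "
      f"{seg_r.std(ddof=1):.2f} (n = {len(seg_r)})")
print(f"Mann-Whitney two-sided p = {p:.2e} "
      f"({'hybrid departs farther' if ratios.mean > seg_r.mean() else 'no'})")
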